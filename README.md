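# affectvar

Affect-variability indices and relative-importance analysis for intensive
longitudinal emotion data.

## The problem

In repeated-measures studies of emotion (experience sampling, lab tasks with
session-by-session self-reports), each occasion's ratings locate a person on
the affect circumplex: valence (pleasant–unpleasant) on one axis, activation
(arousal) on the other. From a person's trajectory over occasions one can
score both *mean levels* of emotion in the four circumplex quadrants —
positive activating (PA), positive deactivating (PD), negative activating
(NA), negative deactivating (ND) — and *affect variability*:

- **Spin** — the circular standard deviation of the occasion angles,
  `spin = sqrt(-2 ln R̄)`, where `R̄ = |Σ_t u_t| / n` is the mean resultant
  length of the per-occasion unit vectors
  `u_t = (valence_t, activation_t) / ||(valence_t, activation_t)||`.
  `R̄ = 1` means no angular dispersion (spin 0); `R̄ → 0` means maximal
  dispersion (spin → ∞).
- **Pulse** — the within-person SD of the vector magnitudes
  `sqrt(valence_t² + activation_t²)`: fluctuation in emotional intensity
  regardless of direction.
- **Flux** (×4) — the within-person SD of each quadrant's occasion scores.

Because mean levels and variability indices are substantially correlated,
asking "does variability matter beyond mean emotion?" requires methods built
for correlated predictors. The package implements the two standard
R²-decomposition approaches and their diagnostics:

- **Johnson relative weights (RWI)** via the symmetric square root of the
  predictor correlation matrix `Rxx = PΔP'`, `Λ = PΔ^{1/2}P'`,
  `β* = Λ⁻¹ r_xy`, `RWI_j = Σ_k Λ²_{jk} β*_k²`; the weights are non-negative
  and sum to R². An a-priori importance threshold (default RWI ≥ 0.02, i.e.
  2% of outcome variance) flags important predictors.
- **Exhaustive dominance analysis** over all 2^p predictor subsets:
  complete, conditional, and general dominance with the conventional
  0 / 0.5 / 1 pairwise coding; general dominance is each predictor's Shapley
  share of R².
- **Suppression diagnostics** — per-predictor unique/common variance
  partition (`common_i = r_i² − U_i`) and the incremental-variance-by-model-
  size trajectory; a suppressor shows negative common variance and a rising
  trajectory.
- **Mediation** — indirect effects `a·b` with bias-corrected bootstrap
  confidence intervals and covariate control.

It targets the canonical design of its field: ~253 participants, 14
measurement sessions of a complex computer task (two games per session,
scored `(kills/(kills+deaths) + rank)·100`), an unannounced difficulty
change after session 7 splitting outcomes into pre-change (acquisition) and
post-change (adaptation) phases, 16 emotion adjectives per session on a
9-point scale, and 5 off-task-attention items on a 7-point scale. Careless
responders are screened by long-string analysis before any scoring. A seeded
synthetic-data generator emulates the whole design — calibrated to the
published descriptive statistics of that literature — so the pipeline is
testable end-to-end without any data download.

## Worked example

```python
import affectvar as av
from affectvar.synthetic_data import GeneratorConfig, simulate_study

study = simulate_study(GeneratorConfig(), seed=42)   # 253 participants
report = av.run_analysis(study.ratings, study.attention, study.games)
print(report.counts)

bundle = report.bundles["pre_ota"]   # pre-change off-task attention
print(bundle.weights.table.round(3))
print("total R2:", round(bundle.weights.total_r2, 3))
```

prints

```
{'input': 253, 'after_screening': 236, 'with_profiles': 236, 'analysis_rows': 236}
  label   beta   rwi  rwi_percent
   spin  0.141 0.015        4.174
  pulse  0.031 0.006        1.569
flux_nd  0.146 0.047       12.846
flux_na -0.116 0.004        1.103
flux_pd  0.099 0.017        4.492
flux_pa -0.012 0.001        0.296
mean_nd  0.430 0.171       46.356
mean_na  0.118 0.075       20.361
mean_pd  0.095 0.006        1.500
mean_pa -0.098 0.027        7.303
total R2: 0.369
```

17 of 253 simulated participants were injected as constant-string careless
responders and all 17 are caught by screening. Of the ten predictors, mean
ND carries the largest relative weight (RWI = 0.171, 46% of the model's
R² = 0.369) and attains *complete* dominance — a larger incremental R² than
every other predictor in every one of the 256 submodels that can accompany
each pairwise comparison — which is exactly the structure the default
generator encodes (mean ND is its strongest off-task-attention coefficient).
ND flux clears the 0.02 importance threshold; spin and pulse do not.

A mediation query on the same dataset:

```python
from affectvar.mediation import MediationSpec, bootstrap_indirect
spec = MediationSpec(x="flux_nd", mediator="pre_ota", y="pre_performance",
                     covariates=["mean_nd"], n_bootstrap=10_000,
                     confidence=0.99, seed=42)
res = bootstrap_indirect(report.dataset, spec)
print(f"indirect={res.indirect:.3f}  99% BC CI [{res.ci_lower:.3f}, {res.ci_upper:.3f}]")
```

prints `indirect=0.961  99% BC CI [-0.257, 3.213]` — the interval covers
zero, so ND flux shows no indirect effect through off-task attention on
performance in this simulated dataset (its outcome link here runs through
its correlation with mean ND, which is controlled).

The same pipeline is available from the shell:

```sh
affectvar simulate --seed 42 --out data/
affectvar analyze --in data/ --out results/
affectvar mediate --dataset results/analysis_dataset.csv \
    --x flux_nd --y pre_performance --covariate mean_nd --out mediation.json
```

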