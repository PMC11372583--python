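"""Seeded generator for study-shaped synthetic datasets.

The generator emulates the repeated-measures design the analysis assumes:
~253 participants, 14 sessions (two games each, task change after session
7), 16 emotion items per session on a 9-point scale, 5 attention items on
a 7-point scale, and per-game kill/death/rank records. It is calibrated to
the published descriptive statistics of the original sample: person-level
quadrant means are drawn from a multivariate normal with the reported
means/SDs and sign-matched correlation structure, within-person SDs
(flux) are log-normal with medians at the reported flux means, and phase
outcomes are linear functions of the *observed* standardized predictors
plus Gaussian noise, rescaled to the reported outcome means/SDs.

The default outcome model loads most heavily on mean ND for off-task
attention and on mean PA for performance — the qualitative dominance
pattern the analysis is meant to detect. A configurable fraction of
participants is replaced by careless (constant-string) responders for the
screening stage to catch.

Everything is deterministic given (config, seed). Sessions are
independent draws (no temporal autocorrelation); spin and pulse are not
direct parameters but emerge from the means, within-person SDs and
correlation structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circumplex import build_profiles
from .core_data import (
    EMOTION_ITEMS,
    ITEM_QUADRANTS,
    N_ATTENTION_ITEMS,
    N_SESSIONS,
    PREDICTOR_COLUMNS,
    PRE_CHANGE_SESSIONS,
    score_session_affect,
)

__all__ = [
    "GeneratorConfig",
    "SimulatedStudy",
    "generate_participants",
    "generate_ratings",
    "generate_outcomes",
    "inject_careless",
    "simulate_study",
]

QUADRANT_ORDER = ("nd", "na", "pd", "pa")

#: Person-mean calibration: (location, SD) per quadrant on the 1-9 scale.
DEFAULT_MEAN_PARAMS = {
    "nd": (3.80, 1.59),
    "na": (3.44, 1.68),
    "pd": (4.11, 1.77),
    "pa": (3.78, 1.80),
}

#: Correlations among person-level quadrant means (order: nd, na, pd, pa).
DEFAULT_MEAN_CORR = (
    (1.00, 0.78, -0.34, -0.52),
    (0.78, 1.00, -0.52, -0.35),
    (-0.34, -0.52, 1.00, 0.52),
    (-0.52, -0.35, 0.52, 1.00),
)

#: Median within-person SD (flux) per quadrant.
DEFAULT_FLUX_MEDIAN = {"nd": 1.13, "na": 1.08, "pd": 1.25, "pa": 1.28}

#: Phase-level (location, SD) of the outcome instruments.
DEFAULT_OTA_SCALE = {"pre": (2.15, 1.10), "post": (2.66, 1.44)}
DEFAULT_PERF_SCALE = {"pre": (37.51, 18.48), "post": (30.11, 16.45)}

#: Standardized generating coefficients on the observed predictors.
DEFAULT_OTA_COEF = {"mean_nd": 0.45, "mean_na": 0.10, "mean_pa": -0.15, "flux_nd": 0.15}
DEFAULT_PERF_COEF = {"mean_pa": 0.40, "mean_na": -0.20, "mean_nd": -0.10, "flux_na": -0.10}


@dataclass
class GeneratorConfig:
    """All knobs of the study emulation, with calibrated defaults."""

    n_participants: int = 253
    n_sessions: int = N_SESSIONS
    mean_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_PARAMS)
    )
    mean_corr: tuple = DEFAULT_MEAN_CORR
    flux_median: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FLUX_MEDIAN))
    flux_log_sd: float = 0.45
    item_noise_sd: float = 0.75
    careless_fraction: float = 17 / 253
    ota_coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OTA_COEF))
    ota_noise_sd: float = 0.8
    perf_coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PERF_COEF))
    perf_noise_sd: float = 0.8
    ota_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OTA_SCALE)
    )
    perf_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PERF_SCALE)
    )
    #: session-to-session scatter of outcomes around the phase target
    ota_session_sd: float = 0.6
    perf_session_sd: float = 8.0
    games_per_session: int = 2

    def __post_init__(self) -> None:
        corr = np.asarray(self.mean_corr, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("mean_corr must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValueError("mean_corr must be positive definite")
        for q, (_, sd) in self.mean_params.items():
            if sd <= 0:
                raise ValueError(f"mean SD for quadrant {q!r} must be > 0")
        if self.flux_log_sd <= 0 or any(m <= 0 for m in self.flux_median.values()):
            raise ValueError("flux distribution parameters must be > 0")
        if not 0.0 <= self.careless_fraction < 1.0:
            raise ValueError("careless_fraction must lie in [0, 1)")
        bad = [
            k
            for coef in (self.ota_coefficients, self.perf_coefficients)
            for k in coef
            if k not in PREDICTOR_COLUMNS
        ]
        if bad:
            raise ValueError(f"unknown predictor labels in outcome model: {bad}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["mean_corr"] = np.asarray(self.mean_corr, dtype=float).tolist()
        return d


def _participant_ids(n: int) -> np.ndarray:
    return np.array([f"p{i:04d}" for i in range(1, n + 1)])


def generate_participants(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-participant true means and within-person SDs.

    Person means come from the configured multivariate normal and are
    truncated to the 1-9 response scale by resampling out-of-range rows
    (no boundary point mass). Within-person SDs are log-normal per
    quadrant. Returns the truth table with one row per participant.
    """
    n = config.n_participants
    order = list(QUADRANT_ORDER)
    loc = np.array([config.mean_params[q][0] for q in order])
    sd = np.array([config.mean_params[q][1] for q in order])
    corr = np.asarray(config.mean_corr, dtype=float)
    cov = corr * np.outer(sd, sd)

    means = np.empty((0, 4))
    while len(means) < n:
        draw = rng.multivariate_normal(loc, cov, size=n, method="cholesky")
        ok = ((draw >= 1.0) & (draw <= 9.0)).all(axis=1)
        means = np.vstack([means, draw[ok]])
    means = means[:n]

    truth = pd.DataFrame({"participant_id": _participant_ids(n)})
    for k, q in enumerate(order):
        truth[f"true_mean_{q}"] = means[:, k]
        truth[f"true_sd_{q}"] = rng.lognormal(
            mean=np.log(config.flux_median[q]), sigma=config.flux_log_sd, size=n
        )
    truth["careless"] = False
    return truth


def generate_ratings(
    truth: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit the long-format emotion-ratings table.

    Session quadrant score = true mean + true within-person SD x N(0, 1);
    each item adds N(0, item_noise_sd) measurement noise and is rounded
    and clipped to the 1-9 integer scale.
    """
    n = len(truth)
    t = config.n_sessions
    frames = []
    for q in QUADRANT_ORDER:
        items = [it for it in EMOTION_ITEMS if ITEM_QUADRANTS[it] == q]
        base = (
            truth[f"true_mean_{q}"].to_numpy()[:, None]
            + truth[f"true_sd_{q}"].to_numpy()[:, None] * rng.standard_normal((n, t))
        )  # (n, t) session quadrant scores
        noise = rng.normal(0.0, config.item_noise_sd, size=(n, t, len(items)))
        ratings = np.clip(np.rint(base[:, :, None] + noise), 1, 9).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(
                        truth["participant_id"].to_numpy(), t * len(items)
                    ),
                    "session": np.tile(np.repeat(np.arange(1, t + 1), len(items)), n),
                    "item": np.tile(items, n * t),
                    "rating": ratings.reshape(-1),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "session"], kind="stable").reset_index(
        drop=True
    )


def inject_careless(
    ratings: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace a fraction of participants with constant-string responders.

    Each selected participant's every administration becomes 16 identical
    responses (one uniform value per administration). Truth flags are
    updated; with fraction 0 the inputs are returned unchanged.
    """
    n_careless = int(round(config.careless_fraction * len(truth)))
    if n_careless == 0:
        return ratings, truth
    ids = rng.choice(truth["participant_id"].to_numpy(), size=n_careless, replace=False)
    ratings = ratings.copy()
    truth = truth.copy()
    for pid in ids:
        mask = ratings["participant_id"] == pid
        sessions = ratings.loc[mask, "session"].to_numpy()
        values = {s: rng.integers(1, 10) for s in np.unique(sessions)}
        ratings.loc[mask, "rating"] = [values[s] for s in sessions]
    truth.loc[truth["participant_id"].isin(ids), "careless"] = True
    return ratings, truth


def _linear_outcome(
    z: pd.DataFrame, coef: dict[str, float], noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    latent = np.zeros(len(z))
    for name, b in coef.items():
        latent += b * z[name].to_numpy()
    latent += rng.normal(0.0, noise_sd, size=len(z))
    return (latent - latent.mean()) / latent.std(ddof=1)


def _ota_items(target: np.ndarray, config, rng) -> np.ndarray:
    """Integer attention items (n_rows, 5) whose mean tracks the target."""
    v = np.clip(target + rng.normal(0.0, config.ota_session_sd, size=target.shape), 1, 7)
    totals = np.rint(v * N_ATTENTION_ITEMS).astype(int)
    base, rem = np.divmod(totals, N_ATTENTION_ITEMS)
    items = base[:, None] + (np.arange(N_ATTENTION_ITEMS)[None, :] < rem[:, None])
    return np.clip(items, 1, 7)


def generate_outcomes(
    truth: pd.DataFrame,
    profiles: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate attention items and game records from observed profiles.

    Phase targets are linear combinations of the standardized observed
    predictors plus Gaussian noise, rescaled to the configured instrument
    location/scale and clipped into range. Session-level records are then
    reverse-engineered so that downstream scoring (item means; game score
    pairs averaged into sessions, then phases) recovers the targets up to
    discretization noise.

    Returns ``(attention, games, targets)``; ``targets`` holds the exact
    phase values per participant for recovery scoring.
    """
    prof = profiles.set_index("participant_id")
    ids = prof.index.to_numpy()
    z = prof[list(PREDICTOR_COLUMNS)].astype(float)
    z = (z - z.mean()) / z.std(ddof=1)

    targets = pd.DataFrame({"participant_id": ids})
    phase_sessions = {
        "pre": np.asarray(PRE_CHANGE_SESSIONS),
        "post": np.asarray(range(PRE_CHANGE_SESSIONS[-1] + 1, config.n_sessions + 1)),
    }

    att_frames, game_frames = [], []
    n_clipped = 0
    for phase in ("pre", "post"):
        sess = phase_sessions[phase]
        ota_z = _linear_outcome(z, config.ota_coefficients, config.ota_noise_sd, rng)
        loc, scale = config.ota_scale[phase]
        ota_target = loc + scale * ota_z
        clipped = np.clip(ota_target, 1, 7)
        n_clipped += int((clipped != ota_target).sum())
        targets[f"{phase}_ota_target"] = clipped

        perf_z = _linear_outcome(z, config.perf_coefficients, config.perf_noise_sd, rng)
        loc, scale = config.perf_scale[phase]
        perf_target = loc + scale * perf_z
        pclipped = np.clip(perf_target, 0, 200)
        n_clipped += int((pclipped != perf_target).sum())
        targets[f"{phase}_performance_target"] = pclipped

        for s in sess:
            items = _ota_items(clipped, config, rng)
            att_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(ids, N_ATTENTION_ITEMS),
                        "session": s,
                        "item_index": np.tile(
                            np.arange(1, N_ATTENTION_ITEMS + 1), len(ids)
                        ),
                        "rating": items.reshape(-1),
                    }
                )
            )
            for g_off in range(config.games_per_session):
                game_no = (s - 1) * config.games_per_session + g_off + 1
                g = np.clip(
                    pclipped + rng.normal(0.0, config.perf_session_sd, size=len(ids)),
                    0,
                    200,
                )
                rank = np.clip(g / 200.0 + rng.uniform(-0.15, 0.15, size=len(ids)), 0, 1)
                ratio = np.clip(g / 100.0 - rank, 0, 1)
                total = rng.poisson(10, size=len(ids)) + 2
                kills = np.rint(ratio * total).astype(int)
                game_frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": ids,
                            "game": game_no,
                            "kills": kills,
                            "deaths": total - kills,
                            "rank_score": rank,
                        }
                    )
                )
    attention = pd.concat(att_frames, ignore_index=True).sort_values(
        ["participant_id", "session", "item_index"], kind="stable"
    ).reset_index(drop=True)
    games = pd.concat(game_frames, ignore_index=True).sort_values(
        ["participant_id", "game"], kind="stable"
    ).reset_index(drop=True)
    targets.attrs["n_clipped"] = n_clipped
    return attention, games, targets


@dataclass
class SimulatedStudy:
    """All artefacts of one simulation run."""

    ratings: pd.DataFrame
    attention: pd.DataFrame
    games: pd.DataFrame
    truth: pd.DataFrame
    targets: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (
            ("ratings.csv", self.ratings),
            ("attention.csv", self.attention),
            ("games.csv", self.games),
            ("truth.csv", self.truth),
        ):
            path = outdir / name
            frame.to_csv(path, index=False)
            paths.append(path)
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2))
        paths.append(manifest_path)
        return paths


def simulate_study(config: GeneratorConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Run the full generator chain deterministically from one seed.

    Outcomes are generated from profiles scored on the *clean* ratings
    (predictor-outcome links refer to observable scores); careless
    responders are injected into the emitted ratings afterwards, so the
    screening stage has something real to catch.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    truth = generate_participants(config, rng)
    clean_ratings = generate_ratings(truth, config, rng)
    session_affect = score_session_affect(clean_ratings)
    profiles = build_profiles(session_affect, min_sessions=config.n_sessions)
    attention, games, targets = generate_outcomes(truth, profiles, config, rng)
    ratings, truth = inject_careless(clean_ratings, truth, config, rng)
    manifest = {
        "seed": seed,
        "config": config.to_manifest(),
        "n_participants": config.n_participants,
        "schema_version": 1,
        "files": ["ratings.csv", "attention.csv", "games.csv", "truth.csv"],
    }
    return SimulatedStudy(
        ratings=ratings,
        attention=attention,
        games=games,
        truth=truth,
        targets=targets,
        manifest=manifest,
    )
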