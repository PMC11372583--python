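"""Relative weight analysis and exhaustive dominance analysis.

Both methods apportion a regression model's R-squared among correlated
predictors, answering "which variables matter most" where standardized
betas mislead under collinearity.

Relative weights (Johnson's epsilon)
    The predictors are transformed into their closest orthogonal
    counterparts via the symmetric square root of the predictor correlation
    matrix: with ``Rxx = P D P'``, set ``Lambda = P D^(1/2) P'``. The
    outcome is regressed on the orthogonal variables (``beta* =
    Lambda^{-1} rxy``) and each original predictor's weight is
    ``rwi_j = sum_k Lambda[j,k]^2 * beta*_k^2``. The weights are
    non-negative and sum to the full-model R-squared.

Dominance analysis
    R-squared is computed for all 2^p predictor subsets. Predictor i
    *completely* dominates j if its incremental R-squared exceeds j's for
    every subset excluding both; *conditionally* dominates if its average
    increment is at least j's at every model size (strictly at one);
    *generally* dominates if its overall average increment (its Shapley
    share of R-squared) is larger. Complete implies conditional implies
    general. Pairwise outcomes are coded 1 (row dominates column), 0
    (column dominates row), 0.5 (undetermined/tied).

All computations run on the correlation scale: predictors and outcome are
z-scored (n-1 SDs) so that R-squared of any subset is
``rxy' Rxx^{-1} rxy`` over the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "RegressionProblem",
    "standardize",
    "r_squared_from_correlations",
    "all_subsets_r2",
    "conditional_dominance",
    "general_dominance",
    "pairwise_dominance",
    "dominance_analysis",
    "relative_weights",
    "RelativeWeights",
    "DominanceResult",
    "flag_importance",
    "run_relative_importance",
    "ImportanceBundle",
    "RWI_THRESHOLD",
]

#: A-priori relative-weight importance threshold (share of outcome variance).
RWI_THRESHOLD = 0.02

MAX_SUBSET_PREDICTORS = 20


@dataclass
class RegressionProblem:
    """Standardized predictors/outcome plus their correlation summaries."""

    labels: list[str]
    X: np.ndarray  # n x p, z-scored
    y: np.ndarray  # n, z-scored
    Rxx: np.ndarray  # p x p predictor correlations
    rxy: np.ndarray  # p predictor-outcome correlations
    n: int

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, predictors: list[str]
    ) -> "RegressionProblem":
        cols = [*predictors, outcome]
        frame = data[cols].dropna()
        n = len(frame)
        if n <= len(predictors) + 1:
            raise ValueError(
                f"need n > p + 1 (n={n}, p={len(predictors)}) for outcome {outcome!r}"
            )
        X = standardize(frame[predictors].to_numpy(dtype=float))
        y = standardize(frame[outcome].to_numpy(dtype=float))
        Rxx = (X.T @ X) / (n - 1)
        rxy = (X.T @ y) / (n - 1)
        # symmetrize and pin the diagonal against rounding
        Rxx = (Rxx + Rxx.T) / 2
        np.fill_diagonal(Rxx, 1.0)
        min_eig = float(np.linalg.eigvalsh(Rxx)[0])
        if min_eig < 1e-10:
            raise ValueError(
                f"predictor correlation matrix is not positive definite "
                f"(min eigenvalue {min_eig:.2e}); drop collinear columns"
            )
        return cls(labels=list(predictors), X=X, y=y, Rxx=Rxx, rxy=rxy, n=n)


def standardize(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column z-scores with sample (n-1) SDs; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero-variance column cannot be standardized")
    return (x - mean) / sd


def r_squared_from_correlations(Rxx_subset: np.ndarray, rxy_subset: np.ndarray) -> float:
    """R-squared of a standardized OLS model from correlation blocks.

    ``R^2 = rxy' Rxx^{-1} rxy`` — identical to direct least squares on the
    z-scored data. Raises on a singular subset matrix.
    """
    Rxx_subset = np.atleast_2d(np.asarray(Rxx_subset, dtype=float))
    rxy_subset = np.atleast_1d(np.asarray(rxy_subset, dtype=float))
    if rxy_subset.size == 0:
        return 0.0
    try:
        beta = np.linalg.solve(Rxx_subset, rxy_subset)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular predictor subset correlation matrix: {exc}") from exc
    return float(rxy_subset @ beta)


def all_subsets_r2(problem: RegressionProblem) -> dict[frozenset[int], float]:
    """R-squared for every subset of predictor indices (2^p entries).

    Guarded at p <= 20; beyond that, pre-select predictors before the
    exhaustive decomposition.
    """
    p = len(problem.labels)
    if p > MAX_SUBSET_PREDICTORS:
        raise ValueError(
            f"p={p} exceeds the enumeration guard ({MAX_SUBSET_PREDICTORS}); "
            "pre-select predictors first"
        )
    out: dict[frozenset[int], float] = {frozenset(): 0.0}
    for k in range(1, p + 1):
        for subset in combinations(range(p), k):
            idx = list(subset)
            out[frozenset(subset)] = r_squared_from_correlations(
                problem.Rxx[np.ix_(idx, idx)], problem.rxy[idx]
            )
    return out


def conditional_dominance(
    subsets_r2: dict[frozenset[int], float], p: int
) -> np.ndarray:
    """Average incremental R-squared per predictor at each model size.

    Entry ``[i, k]`` is the mean of ``R2(S + i) - R2(S)`` over all subsets
    S of size k that exclude i, for k = 0 .. p-1.
    """
    sums = np.zeros((p, p))
    counts = np.zeros((p, p))
    for subset, r2 in subsets_r2.items():
        k = len(subset)
        for i in range(p):
            if i in subset:
                continue
            inc = subsets_r2[subset | {i}] - r2
            sums[i, k] += inc
            counts[i, k] += 1
    return sums / counts


def general_dominance(conditional: np.ndarray) -> np.ndarray:
    """General dominance weights: the unweighted mean over model sizes.

    This is each predictor's Shapley share of R-squared; the values sum to
    the full-model R-squared.
    """
    return conditional.mean(axis=1)


def pairwise_dominance(
    subsets_r2: dict[frozenset[int], float],
    conditional: np.ndarray,
    general: np.ndarray,
    tol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """Pairwise 0 / 0.5 / 1 dominance matrices at all three levels.

    ``complete[i, j] = 1`` iff i's increment strictly beats j's over every
    subset excluding both; ``conditional`` requires >= at every size with >
    at one; ``general`` compares the scalar weights. 0.5 marks undetermined
    or exactly tied pairs; diagonal entries are 0.5 by convention.
    """
    p = conditional.shape[0]
    complete = np.full((p, p), 0.5)
    cond = np.full((p, p), 0.5)
    gen = np.full((p, p), 0.5)
    for i, j in combinations(range(p), 2):
        # complete: compare increments over all S excluding both
        others = [k for k in range(p) if k not in (i, j)]
        i_wins = j_wins = ties = 0
        for size in range(len(others) + 1):
            for sub in combinations(others, size):
                s = frozenset(sub)
                di = subsets_r2[s | {i}] - subsets_r2[s]
                dj = subsets_r2[s | {j}] - subsets_r2[s]
                if di > dj + tol:
                    i_wins += 1
                elif dj > di + tol:
                    j_wins += 1
                else:
                    ties += 1
        if i_wins and not j_wins and not ties:
            complete[i, j], complete[j, i] = 1.0, 0.0
        elif j_wins and not i_wins and not ties:
            complete[i, j], complete[j, i] = 0.0, 1.0

        ci, cj = conditional[i], conditional[j]
        if np.all(ci >= cj - tol) and np.any(ci > cj + tol):
            cond[i, j], cond[j, i] = 1.0, 0.0
        elif np.all(cj >= ci - tol) and np.any(cj > ci + tol):
            cond[i, j], cond[j, i] = 0.0, 1.0

        if general[i] > general[j] + tol:
            gen[i, j], gen[j, i] = 1.0, 0.0
        elif general[j] > general[i] + tol:
            gen[i, j], gen[j, i] = 0.0, 1.0
    return {"complete": complete, "conditional": cond, "general": gen}


@dataclass
class DominanceResult:
    """All-subsets incremental R-squared decomposition."""

    labels: list[str]
    subsets_r2: dict[frozenset[int], float] = field(repr=False)
    conditional: pd.DataFrame  # predictors x model sizes 0..p-1
    general: pd.Series
    matrices: dict[str, pd.DataFrame]  # complete / conditional / general
    full_r2: float

    def pairwise_table(self) -> pd.DataFrame:
        """Long-format pairwise table mirroring the published layout:
        one row per ordered pair, columns complete/conditional/general."""
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i >= j:
                    continue
                rows.append(
                    {
                        "pair": f"{a} > {b}",
                        "complete": self.matrices["complete"].iloc[i, j],
                        "conditional": self.matrices["conditional"].iloc[i, j],
                        "general": self.matrices["general"].iloc[i, j],
                    }
                )
        return pd.DataFrame(rows)


def dominance_analysis(problem: RegressionProblem) -> DominanceResult:
    """Full dominance analysis of a regression problem."""
    p = len(problem.labels)
    subsets = all_subsets_r2(problem)
    cond = conditional_dominance(subsets, p)
    gen = general_dominance(cond)
    mats = pairwise_dominance(subsets, cond, gen)
    labels = problem.labels
    return DominanceResult(
        labels=labels,
        subsets_r2=subsets,
        conditional=pd.DataFrame(cond, index=labels, columns=range(p)),
        general=pd.Series(gen, index=labels, name="general_dominance"),
        matrices={
            k: pd.DataFrame(v, index=labels, columns=labels) for k, v in mats.items()
        },
        full_r2=subsets[frozenset(range(p))],
    )


@dataclass
class RelativeWeights:
    """Johnson relative weights with full-model standardized betas."""

    table: pd.DataFrame  # label, beta, rwi, rwi_percent
    total_r2: float


def relative_weights(problem: RegressionProblem) -> RelativeWeights:
    """Relative weight analysis via the symmetric-square-root
    orthogonalization (see module docstring for the algebra)."""
    eigval, eigvec = np.linalg.eigh(problem.Rxx)
    if eigval[0] < 1e-10:
        raise ValueError(
            "predictor correlation matrix not positive definite; "
            "drop collinear columns"
        )
    lam = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T
    beta_star = np.linalg.solve(lam, problem.rxy)
    rwi = (lam**2) @ (beta_star**2)
    total_r2 = float(problem.rxy @ np.linalg.solve(problem.Rxx, problem.rxy))
    beta = np.linalg.solve(problem.Rxx, problem.rxy)
    table = pd.DataFrame(
        {
            "label": problem.labels,
            "beta": beta,
            "rwi": rwi,
            "rwi_percent": rwi / total_r2 * 100.0,
        }
    )
    return RelativeWeights(table=table, total_r2=total_r2)


def flag_importance(
    weights: RelativeWeights, threshold: float = RWI_THRESHOLD
) -> pd.DataFrame:
    """Mark predictors whose RWI meets the a-priori threshold (inclusive)."""
    out = weights.table[["label", "rwi"]].copy()
    out["important"] = out["rwi"] >= threshold
    out.attrs["threshold"] = threshold
    return out


@dataclass
class ImportanceBundle:
    """Everything the relative-importance stage reports for one outcome."""

    outcome: str
    weights: RelativeWeights
    dominance: DominanceResult
    flags: pd.DataFrame
    n: int


def run_relative_importance(
    dataset: pd.DataFrame,
    outcome: str,
    predictors: list[str] | None = None,
    rwi_threshold: float = RWI_THRESHOLD,
) -> ImportanceBundle:
    """Relative weights + dominance + importance flags for one outcome."""
    from .core_data import OUTCOME_COLUMNS, PREDICTOR_COLUMNS

    if predictors is None:
        predictors = list(PREDICTOR_COLUMNS)
    if outcome not in dataset.columns:
        raise ValueError(
            f"unknown outcome {outcome!r}; expected one of {list(OUTCOME_COLUMNS)}"
        )
    problem = RegressionProblem.from_dataframe(dataset, outcome, predictors)
    weights = relative_weights(problem)
    dom = dominance_analysis(problem)
    flags = flag_importance(weights, threshold=rwi_threshold)
    return ImportanceBundle(
        outcome=outcome, weights=weights, dominance=dom, flags=flags, n=problem.n
    )
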