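"""Commonality-based suppression diagnostics.

A predictor's squared zero-order validity splits into a unique part
``U_i = R2(full) - R2(full without i)`` and a common part
``common_i = r_i^2 - U_i``. A classical suppressor correlates near zero
with the outcome yet raises the variance other predictors explain; it
shows up as *negative* common variance together with a full-model beta
much larger than its validity, and its average incremental R-squared
*grows* with model size instead of shrinking. These diagnostics are
ancillary to the relative-importance analysis and share its all-subsets
machinery: the incremental-variance trajectory of a predictor IS its
conditional-dominance vector, not a second computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relative_importance import (
    DominanceResult,
    RegressionProblem,
    dominance_analysis,
    r_squared_from_correlations,
)

__all__ = [
    "commonality",
    "incremental_trajectory",
    "paired_model_comparison",
    "suppression_report",
    "SizeTrajectory",
]

#: Default bounds for the suppressor flag: near-zero validity, non-trivial beta.
NEAR_ZERO_R = 0.10
BETA_BOUND = 0.10


def commonality(
    problem: RegressionProblem,
    near_zero_r: float = NEAR_ZERO_R,
    beta_bound: float = BETA_BOUND,
) -> pd.DataFrame:
    """Per-predictor unique/common variance partition with suppressor flags.

    Returns columns ``label, r, r_squared, unique, common, beta,
    suppressor_flag``; the flag is true when common < 0, |r| < near_zero_r
    and |beta| > beta_bound.
    """
    p = len(problem.labels)
    full_idx = list(range(p))
    full_r2 = r_squared_from_correlations(problem.Rxx, problem.rxy)
    beta = np.linalg.solve(problem.Rxx, problem.rxy)
    rows = []
    for i, label in enumerate(problem.labels):
        rest = [k for k in full_idx if k != i]
        r2_without = r_squared_from_correlations(
            problem.Rxx[np.ix_(rest, rest)], problem.rxy[rest]
        )
        unique = full_r2 - r2_without
        r = float(problem.rxy[i])
        common = r**2 - unique
        rows.append(
            {
                "label": label,
                "r": r,
                "r_squared": r**2,
                "unique": unique,
                "common": common,
                "beta": float(beta[i]),
                "suppressor_flag": bool(
                    common < 0 and abs(r) < near_zero_r and abs(beta[i]) > beta_bound
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["full_r2"] = full_r2
    return out


@dataclass
class SizeTrajectory:
    """Average incremental R-squared of one predictor by model size."""

    label: str
    by_size: np.ndarray  # sizes 0 .. p-1
    #: increment when added to the average single-companion model (size 1)
    first: float
    #: unique increment over the full model of all other predictors
    last: float
    rising: bool  # suppression-consistent direction: last > first

    @property
    def direction(self) -> str:
        return "rising" if self.rising else "non-rising"


def incremental_trajectory(dominance: DominanceResult, predictor: str) -> SizeTrajectory:
    """Incremental-variance-by-model-size trajectory of one predictor.

    Reads the conditional-dominance vector straight off a
    :class:`DominanceResult` (shared computation, asserted identical in
    tests). A trajectory whose full-model endpoint exceeds its
    one-companion endpoint is reported as suppression-consistent.
    """
    if predictor not in dominance.labels:
        raise ValueError(f"unknown predictor {predictor!r}")
    by_size = dominance.conditional.loc[predictor].to_numpy(dtype=float)
    # size-1 companion average vs. full-model unique contribution; with only
    # two predictors those coincide, so the trajectory starts at size 0
    first = float(by_size[1]) if by_size.size > 2 else float(by_size[0])
    last = float(by_size[-1])
    return SizeTrajectory(
        label=predictor, by_size=by_size, first=first, last=last, rising=last > first
    )


def paired_model_comparison(
    problem: RegressionProblem, target: str, candidate: str
) -> dict[str, float]:
    """R-squared with and without a candidate suppressor.

    Returns ``{"r2_target": R2(target alone), "r2_with_candidate":
    R2(target + candidate), "gain": difference}``.
    """
    for name in (target, candidate):
        if name not in problem.labels:
            raise ValueError(f"unknown predictor {name!r}")
    i = problem.labels.index(target)
    j = problem.labels.index(candidate)
    r2_t = r_squared_from_correlations(
        problem.Rxx[np.ix_([i], [i])], problem.rxy[[i]]
    )
    r2_tc = r_squared_from_correlations(
        problem.Rxx[np.ix_([i, j], [i, j])], problem.rxy[[i, j]]
    )
    return {"r2_target": r2_t, "r2_with_candidate": r2_tc, "gain": r2_tc - r2_t}


def suppression_report(
    problem: RegressionProblem,
    dominance: DominanceResult | None = None,
    near_zero_r: float = NEAR_ZERO_R,
    beta_bound: float = BETA_BOUND,
) -> pd.DataFrame:
    """Combined suppression table: commonality partition plus trajectory
    direction per predictor."""
    if dominance is None:
        dominance = dominance_analysis(problem)
    table = commonality(problem, near_zero_r=near_zero_r, beta_bound=beta_bound)
    directions = [
        incremental_trajectory(dominance, label).direction for label in table["label"]
    ]
    table["trajectory"] = directions
    return table
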