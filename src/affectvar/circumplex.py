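"""Mean levels and affect-variability indices: spin, pulse, and flux.

Each session maps to a point on the affect circumplex via its (valence,
activation) pair. From a participant's sequence of sessions we compute:

spin
    The circular standard deviation of the session angles,
    ``sqrt(-2 * ln(Rbar))``, where ``Rbar`` is the mean resultant length of
    the per-session unit vectors. Rbar = 1 means all sessions point in the
    same direction (spin 0); Rbar -> 0 means maximal angular dispersion
    (spin -> infinity). Sessions at the exact origin (valence = activation
    = 0) have no angle and are excluded from the resultant, with a count
    kept for auditing.
pulse
    The within-person sample standard deviation of the circumplex vector
    magnitudes ``sqrt(valence^2 + activation^2)`` — fluctuation in
    emotional intensity regardless of direction. Origin sessions contribute
    magnitude 0.
flux (x4)
    The within-person sample standard deviation of each quadrant's session
    scores (PA, PD, NA, ND separately).

All standard deviations use the n-1 denominator by default (person-level
estimates from sampled occasions); pass ``ddof=0`` for the population form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import PREDICTOR_COLUMNS, QUADRANTS

__all__ = [
    "unit_vectors",
    "mean_resultant_length",
    "ResultantSummary",
    "spin",
    "pulse",
    "flux",
    "mean_levels",
    "build_profiles",
    "PROFILE_COLUMNS",
]

_EPS = 1e-12

PROFILE_COLUMNS = (
    "participant_id",
    *PREDICTOR_COLUMNS,
    "valence_mean",
    "activation_mean",
    "valence_sd",
    "activation_sd",
    "n_sessions_used",
    "n_zero_magnitude",
    "spin_infinite",
)


def unit_vectors(valence, activation):
    """Per-session unit vectors on the circumplex.

    Returns ``(cos, sin, usable)`` arrays where ``usable`` marks sessions
    with nonzero magnitude; cos/sin are NaN for unusable sessions.

    Raises ``ValueError`` if every session sits at the origin (no angle is
    defined anywhere, so spin is undefined for this participant).
    """
    v = np.asarray(valence, dtype=float)
    a = np.asarray(activation, dtype=float)
    m = np.hypot(v, a)
    usable = m > _EPS
    if not usable.any():
        raise ValueError("all sessions have zero magnitude; angles undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(usable, v / m, np.nan)
        s = np.where(usable, a / m, np.nan)
    return c, s, usable


@dataclass
class ResultantSummary:
    """Resultant vector of a participant's session unit vectors."""

    sum_cos: float
    sum_sin: float
    n_usable_sessions: int

    @property
    def mean_resultant_length(self) -> float:
        r = np.hypot(self.sum_cos, self.sum_sin) / self.n_usable_sessions
        # floating error can push |R|/n infinitesimally past 1
        if 1.0 < r <= 1.0 + 1e-9:
            return 1.0
        return float(r)


def mean_resultant_length(cos, sin) -> ResultantSummary:
    """Sum the usable unit vectors into a :class:`ResultantSummary`.

    NaN entries (origin sessions) are ignored. Requires at least 2 usable
    sessions; fewer leave the dispersion undefined.
    """
    c = np.asarray(cos, dtype=float)
    s = np.asarray(sin, dtype=float)
    usable = ~(np.isnan(c) | np.isnan(s))
    n = int(usable.sum())
    if n < 2:
        raise ValueError(f"need >= 2 usable sessions, got {n}")
    return ResultantSummary(
        sum_cos=float(c[usable].sum()), sum_sin=float(s[usable].sum()), n_usable_sessions=n
    )


def spin(summary: ResultantSummary, *, circular_sd: bool = True) -> float:
    """Spin from a resultant summary.

    Default is the circular standard deviation ``sqrt(-2 ln Rbar)``; with
    ``circular_sd=False`` the non-rooted variance form ``-2 ln Rbar`` is
    returned instead. ``Rbar = 0`` (perfect cancellation) yields ``inf`` —
    callers should carry a flag rather than cap it silently.
    """
    rbar = summary.mean_resultant_length
    if rbar <= 0:
        return float("inf")
    val = -2.0 * np.log(rbar)
    val = max(0.0, val)  # guard tiny negative from rbar ~ 1 rounding
    return float(np.sqrt(val)) if circular_sd else float(val)


def pulse(valence, activation, ddof: int = 1) -> float:
    """Within-person SD of circumplex magnitudes across sessions."""
    v = np.asarray(valence, dtype=float)
    a = np.asarray(activation, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 sessions for pulse")
    return float(np.hypot(v, a).std(ddof=ddof))


def flux(values, ddof: int = 1) -> float:
    """Within-person SD of one quadrant's session scores."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 sessions for flux")
    return float(x.std(ddof=ddof))


def mean_levels(session_affect: pd.DataFrame) -> pd.DataFrame:
    """Session-averaged quadrant scores, one row per participant."""
    out = session_affect.groupby("participant_id")[list(QUADRANTS)].mean()
    return out.rename(columns={q: f"mean_{q}" for q in QUADRANTS}).reset_index()


def build_profiles(
    session_affect: pd.DataFrame,
    min_sessions: int = 14,
    ddof: int = 1,
    circular_sd: bool = True,
) -> pd.DataFrame:
    """One affect profile per participant: 10 predictors plus audit fields.

    Parameters
    ----------
    session_affect : output of :func:`affectvar.core_data.score_session_affect`
        (already restricted to screened-in participants).
    min_sessions : participants with fewer sessions are dropped (the study
        design has 14 complete sessions; lower this to retain partial data).
    ddof : SD denominator offset (1 = sample SD).
    circular_sd : spin as circular SD (default) vs. its squared form.

    Returns a frame with :data:`PROFILE_COLUMNS`. Participants whose unit
    vectors cancel exactly get ``spin = inf`` and ``spin_infinite = True``;
    participants whose sessions all sit at the circumplex origin get
    ``spin = NaN`` (undefined). Both are excluded later by dataset assembly.
    """
    rows = []
    for pid, grp in session_affect.groupby("participant_id", sort=True):
        if len(grp) < min_sessions or len(grp) < 2:
            continue
        v = grp["valence"].to_numpy(dtype=float)
        a = grp["activation"].to_numpy(dtype=float)
        row = {"participant_id": pid}
        for q in QUADRANTS:
            vals = grp[q].to_numpy(dtype=float)
            row[f"mean_{q}"] = float(vals.mean())
            row[f"flux_{q}"] = flux(vals, ddof=ddof)
        row["valence_mean"] = float(v.mean())
        row["activation_mean"] = float(a.mean())
        row["valence_sd"] = float(v.std(ddof=ddof))
        row["activation_sd"] = float(a.std(ddof=ddof))
        row["pulse"] = pulse(v, a, ddof=ddof)
        try:
            c, s, usable = unit_vectors(v, a)
            summary = mean_resultant_length(c, s)
            row["spin"] = spin(summary, circular_sd=circular_sd)
            row["n_zero_magnitude"] = int((~usable).sum())
        except ValueError:
            # all-origin participant, or < 2 usable angles: spin undefined
            row["spin"] = float("nan")
            row["n_zero_magnitude"] = int((np.hypot(v, a) <= _EPS).sum())
        row["spin_infinite"] = bool(np.isinf(row["spin"]))
        row["n_sessions_used"] = len(grp)
        rows.append(row)
    profiles = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    return profiles
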