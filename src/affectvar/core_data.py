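"""Data model, file I/O, and scoring of raw ratings into analysis variables.

The study design this package targets: participants repeatedly rate 16
emotion adjectives (9-point scale) after each of 14 sessions of a complex
computer task, report off-task attention (5 items, 7-point scale) per
session, and accumulate per-game performance records (kills, deaths, rank).
This module turns those raw long-format tables into session-level affect
scores on the valence/activation circumplex, session outcomes, and a
participant-level analysis dataset with one row per retained participant.

Scoring conventions
-------------------
Each adjective belongs to exactly one circumplex quadrant: positive
activating (PA), positive deactivating (PD), negative activating (NA),
negative deactivating (ND). A session's quadrant score is the mean of its
items, and the composite axes are::

    valence    = (PA + PD) - (NA + ND)
    activation = (PA + NA) - (PD + ND)

Game performance is ``(kills / (kills + deaths) + rank_score) * 100`` per
game, averaged over each consecutive pair of games to give 14 session
scores; sessions 1-7 are the pre-change (acquisition) phase and 8-14 the
post-change (adaptation) phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ITEM_QUADRANTS",
    "QUADRANTS",
    "EMOTION_ITEMS",
    "N_SESSIONS",
    "PRE_CHANGE_SESSIONS",
    "POST_CHANGE_SESSIONS",
    "N_ATTENTION_ITEMS",
    "PREDICTOR_COLUMNS",
    "OUTCOME_COLUMNS",
    "read_ratings",
    "read_attention",
    "read_games",
    "score_session_affect",
    "score_off_task_attention",
    "coefficient_alpha",
    "session_alphas",
    "game_score",
    "rank_from_place",
    "collapse_sessions",
    "assemble_analysis_dataset",
    "descriptives",
    "Descriptives",
]

# Fixed adjective -> quadrant map (16 items: 4 ND, 6 NA, 3 PD, 3 PA).
ITEM_QUADRANTS: dict[str, str] = {
    "discouraged": "nd",
    "disappointed": "nd",
    "fatigued": "nd",
    "bored": "nd",
    "uneasy": "na",
    "frustrated": "na",
    "irritated": "na",
    "tense": "na",
    "anxious": "na",
    "angry": "na",
    "ease": "pd",
    "calm": "pd",
    "relaxed": "pd",
    "enthusiastic": "pa",
    "excited": "pa",
    "happy": "pa",
}

QUADRANTS = ("pa", "pd", "na", "nd")
EMOTION_ITEMS = tuple(ITEM_QUADRANTS)

N_SESSIONS = 14
PRE_CHANGE_SESSIONS = tuple(range(1, 8))
POST_CHANGE_SESSIONS = tuple(range(8, 15))
N_ATTENTION_ITEMS = 5

RATING_MIN, RATING_MAX = 1, 9
ATTENTION_MIN, ATTENTION_MAX = 1, 7

#: Participant-level predictor columns in analysis-dataset order.
PREDICTOR_COLUMNS = (
    "spin",
    "pulse",
    "flux_nd",
    "flux_na",
    "flux_pd",
    "flux_pa",
    "mean_nd",
    "mean_na",
    "mean_pd",
    "mean_pa",
)

#: Phase-level outcome columns.
OUTCOME_COLUMNS = (
    "pre_ota",
    "post_ota",
    "pre_performance",
    "post_performance",
)


class SchemaError(ValueError):
    """A raw input file violates its documented schema."""


def _read_table(path, required: dict[str, type], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col, kind in required.items():
        if kind is int:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals != vals.round())
            if bad.any():
                line = int(df.index[bad][0]) + 2  # header is line 1
                raise SchemaError(
                    f"{path}: non-integer value {df[col][bad].iloc[0]!r} "
                    f"in column '{col}' at line {line}"
                )
            df[col] = vals.astype(int)
        elif kind is float:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                line = int(df.index[vals.isna()][0]) + 2
                raise SchemaError(
                    f"{path}: non-numeric value in column '{col}' at line {line}"
                )
            df[col] = vals.astype(float)
        else:
            df[col] = df[col].astype(str)
    return df


def _check_range(df: pd.DataFrame, col: str, lo, hi, path) -> None:
    bad = (df[col] < lo) | (df[col] > hi)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(
            f"{path}: {col}={df[col][bad].iloc[0]} outside [{lo}, {hi}] "
            f"at line {line}"
        )


def read_ratings(path, sep: str = ",") -> pd.DataFrame:
    """Read a long-format emotion-ratings file.

    Expected columns: ``participant_id, session, item, rating``. Every item
    label must belong to the fixed 16-adjective map and every rating must be
    an integer in 1-9. Returns rows sorted by participant then session.
    """
    df = _read_table(
        path,
        {"participant_id": str, "session": int, "item": str, "rating": int},
        sep=sep,
    )
    df["item"] = df["item"].str.strip().str.lower()
    unknown = ~df["item"].isin(ITEM_QUADRANTS)
    if unknown.any():
        line = int(df.index[unknown][0]) + 2
        raise SchemaError(
            f"{path}: unknown item label {df['item'][unknown].iloc[0]!r} "
            f"at line {line}"
        )
    _check_range(df, "rating", RATING_MIN, RATING_MAX, path)
    _check_range(df, "session", 1, N_SESSIONS, path)
    return df.sort_values(["participant_id", "session"], kind="stable").reset_index(
        drop=True
    )


def read_attention(path, sep: str = ",") -> pd.DataFrame:
    """Read the off-task-attention file (participant_id, session, item_index,
    rating); ratings are integers in 1-7, item_index in 1-5."""
    df = _read_table(
        path,
        {"participant_id": str, "session": int, "item_index": int, "rating": int},
        sep=sep,
    )
    _check_range(df, "rating", ATTENTION_MIN, ATTENTION_MAX, path)
    _check_range(df, "session", 1, N_SESSIONS, path)
    _check_range(df, "item_index", 1, N_ATTENTION_ITEMS, path)
    return df.sort_values(["participant_id", "session"], kind="stable").reset_index(
        drop=True
    )


def read_games(path, sep: str = ",") -> pd.DataFrame:
    """Read the games file (participant_id, game, kills, deaths, rank_score)."""
    df = _read_table(
        path,
        {
            "participant_id": str,
            "game": int,
            "kills": int,
            "deaths": int,
            "rank_score": float,
        },
        sep=sep,
    )
    _check_range(df, "kills", 0, np.inf, path)
    _check_range(df, "deaths", 0, np.inf, path)
    _check_range(df, "rank_score", 0.0, 1.0, path)
    return df.sort_values(["participant_id", "game"], kind="stable").reset_index(
        drop=True
    )


def score_session_affect(ratings: pd.DataFrame) -> pd.DataFrame:
    """Quadrant means plus valence/activation per participant-session.

    Requires all 16 items for every participant-session present in the
    input; raises ``ValueError`` naming the first missing combination.

    Returns a frame with columns ``participant_id, session, pa, pd, na, nd,
    valence, activation``.
    """
    df = ratings.copy()
    counts = df.groupby(["participant_id", "session"])["item"].agg(
        ["count", "nunique"]
    )
    bad = counts[(counts["count"] != 16) | (counts["nunique"] != 16)]
    if len(bad):
        pid, session = bad.index[0]
        present = set(
            df[(df["participant_id"] == pid) & (df["session"] == session)]["item"]
        )
        missing = sorted(set(ITEM_QUADRANTS) - present)
        detail = f"missing items {missing}" if missing else "duplicated items"
        raise ValueError(
            f"participant {pid!r} session {session}: expected all 16 emotion "
            f"items exactly once; {detail}"
        )
    df["quadrant"] = df["item"].map(ITEM_QUADRANTS)
    wide = (
        df.groupby(["participant_id", "session", "quadrant"])["rating"]
        .mean()
        .unstack("quadrant")
        .reset_index()
    )
    wide["valence"] = (wide["pa"] + wide["pd"]) - (wide["na"] + wide["nd"])
    wide["activation"] = (wide["pa"] + wide["na"]) - (wide["pd"] + wide["nd"])
    cols = ["participant_id", "session", "pa", "pd", "na", "nd", "valence", "activation"]
    return wide[cols].sort_values(["participant_id", "session"]).reset_index(drop=True)


def score_off_task_attention(attention: pd.DataFrame) -> pd.DataFrame:
    """Session-level off-task attention: mean of the 5 items.

    Raises ``ValueError`` if any participant-session lacks exactly 5
    distinct items.
    """
    counts = attention.groupby(["participant_id", "session"])["item_index"].agg(
        ["count", "nunique"]
    )
    bad = counts[(counts["count"] != N_ATTENTION_ITEMS) | (counts["nunique"] != N_ATTENTION_ITEMS)]
    if len(bad):
        pid, session = bad.index[0]
        raise ValueError(
            f"participant {pid!r} session {session}: expected "
            f"{N_ATTENTION_ITEMS} distinct attention items, "
            f"got {int(bad['count'].iloc[0])}"
        )
    out = (
        attention.groupby(["participant_id", "session"])["rating"]
        .mean()
        .rename("off_task_attention")
        .reset_index()
    )
    return out


def coefficient_alpha(item_matrix) -> float:
    """Cronbach's coefficient alpha for a respondents x items score matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / var(total score)),
    with sample (n-1) variances. Requires >= 2 items and >= 3 respondents.
    Raises ``ValueError`` on zero total-score variance (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be 2-D with at least 2 items")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def session_alphas(attention: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-session coefficient alpha of the attention items and their mean."""
    alphas = {}
    for session, grp in attention.groupby("session"):
        wide = grp.pivot(index="participant_id", columns="item_index", values="rating")
        wide = wide.dropna()
        alphas[session] = coefficient_alpha(wide.to_numpy())
    series = pd.Series(alphas, name="alpha").sort_index()
    return series, float(series.mean())


def game_score(kills, deaths, rank_score):
    """Per-game performance: (kills/(kills+deaths) + rank_score) * 100.

    ``rank_score`` is the standing relative to the bots rescaled to [0, 1]
    (1 = first place). A game with kills + deaths = 0 gets kill ratio 0
    (the degenerate case is flagged upstream). Vectorized.
    """
    kills = np.asarray(kills, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    rank_score = np.asarray(rank_score, dtype=float)
    if (kills < 0).any() or (deaths < 0).any():
        raise ValueError("kills and deaths must be non-negative")
    if ((rank_score < 0) | (rank_score > 1)).any():
        raise ValueError("rank_score must lie in [0, 1]")
    total = kills + deaths
    ratio = np.divide(kills, total, out=np.zeros_like(kills), where=total > 0)
    out = (ratio + rank_score) * 100.0
    return out if out.ndim else float(out)


def rank_from_place(place: int, n_opponents: int) -> float:
    """Convert an ordinal finishing place among ``n_opponents + 1`` players
    to a [0, 1] rank score (1 = first place, 0 = last)."""
    if not 1 <= place <= n_opponents + 1:
        raise ValueError(f"place {place} outside 1..{n_opponents + 1}")
    return (n_opponents + 1 - place) / n_opponents


def collapse_sessions(games: pd.DataFrame, games_per_session: int = 2) -> pd.DataFrame:
    """Collapse per-game scores into session scores.

    Session ``s`` is the mean of games ``(s-1)*g + 1 .. s*g`` for
    ``g = games_per_session`` (default: pairs, 28 games -> 14 sessions).
    Adds a ``phase`` column ('pre' for sessions 1-7, 'post' for 8-14) and a
    ``degenerate_games`` count of games with kills + deaths = 0.

    Raises ``ValueError`` if any participant's game count is not a multiple
    of ``games_per_session``.
    """
    df = games.copy()
    counts = df.groupby("participant_id")["game"].count()
    bad = counts[counts % games_per_session != 0]
    if len(bad):
        raise ValueError(
            f"participant {bad.index[0]!r} has {int(bad.iloc[0])} games, "
            f"not a multiple of {games_per_session}"
        )
    df["score"] = game_score(df["kills"], df["deaths"], df["rank_score"])
    df["session"] = (df["game"] - 1) // games_per_session + 1
    df["degenerate"] = (df["kills"] + df["deaths"]) == 0
    out = (
        df.groupby(["participant_id", "session"])
        .agg(performance=("score", "mean"), degenerate_games=("degenerate", "sum"))
        .reset_index()
    )
    out["phase"] = np.where(out["session"] <= PRE_CHANGE_SESSIONS[-1], "pre", "post")
    return out


def assemble_analysis_dataset(
    profiles: pd.DataFrame,
    ota: pd.DataFrame,
    performance: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join participant affect profiles with phase-averaged outcomes.

    Parameters
    ----------
    profiles : one row per participant with the 10 predictors (see
        :data:`PREDICTOR_COLUMNS`).
    ota : session-level off-task attention (participant_id, session,
        off_task_attention).
    performance : session-level performance (participant_id, session,
        performance).

    Phase outcomes are arithmetic means over sessions 1-7 (pre) and 8-14
    (post). Participants absent from any input, or with spin flagged
    non-finite, are excluded and listed in the reconciliation report.

    Returns
    -------
    (dataset, report) : the analysis dataset (one row per retained
        participant, predictors + 4 outcomes) and a reconciliation report
        (participant_id, reason) for exclusions.
    """

    def phase_means(df: pd.DataFrame, col: str, prefix: str) -> pd.DataFrame:
        df = df.copy()
        df["phase"] = np.where(
            df["session"] <= PRE_CHANGE_SESSIONS[-1], f"pre_{prefix}", f"post_{prefix}"
        )
        wide = df.pivot_table(
            index="participant_id", columns="phase", values=col, aggfunc="mean"
        )
        return wide

    ota_wide = phase_means(ota, "off_task_attention", "ota")
    perf_wide = phase_means(performance, "performance", "performance")

    prof = profiles.set_index("participant_id")
    report_rows = []
    ids = set(prof.index) | set(ota_wide.index) | set(perf_wide.index)
    keep = []
    for pid in sorted(ids):
        missing = [
            name
            for name, frame in (
                ("profile", prof),
                ("off-task attention", ota_wide),
                ("performance", perf_wide),
            )
            if pid not in frame.index
        ]
        if missing:
            report_rows.append((pid, "missing " + ", ".join(missing)))
            continue
        row = prof.loc[pid]
        if not np.isfinite(row[list(PREDICTOR_COLUMNS)].astype(float)).all():
            report_rows.append((pid, "non-finite predictor (e.g. undefined spin)"))
            continue
        keep.append(pid)

    dataset = prof.loc[keep, list(PREDICTOR_COLUMNS)].join(ota_wide).join(perf_wide)
    dataset = dataset.rename_axis("participant_id").reset_index()
    dataset = dataset[
        ["participant_id", *PREDICTOR_COLUMNS, *OUTCOME_COLUMNS]
    ]
    report = pd.DataFrame(report_rows, columns=["participant_id", "reason"])
    return dataset, report


@dataclass
class Descriptives:
    """Means, SDs and the pairwise Pearson correlation matrix of the
    analysis variables, with two-sided significance stars at 0.05 / 0.01."""

    means: pd.Series
    sds: pd.Series
    correlations: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame = field(repr=False)
    zero_variance: list[str] = field(default_factory=list)


def descriptives(dataset: pd.DataFrame, columns: list[str] | None = None) -> Descriptives:
    """Descriptive statistics table for the analysis dataset.

    Requires at least 3 rows. Zero-variance columns are reported in
    ``zero_variance`` and carry NaN correlations.
    """
    if columns is None:
        columns = [*PREDICTOR_COLUMNS, *OUTCOME_COLUMNS]
        columns = [c for c in columns if c in dataset.columns]
    x = dataset[columns].astype(float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 rows for descriptives")
    means = x.mean()
    sds = x.std(ddof=1)
    zero_var = [c for c in columns if sds[c] == 0]
    corr = x.corr()
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    # two-sided p via the exact t transform of r
    r = corr.to_numpy(copy=True)
    np.fill_diagonal(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p_df = pd.DataFrame(p, index=corr.index, columns=corr.columns)
    stars = p_df.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    return Descriptives(
        means=means,
        sds=sds,
        correlations=corr,
        p_values=p_df,
        stars=stars,
        zero_variance=zero_var,
    )
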