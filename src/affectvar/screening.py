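"""Careless-responding detection via long-string analysis.

A long string is a run of identical consecutive responses within one
questionnaire administration (here: the 16 emotion items of one session,
in their fixed presentation order). Participants whose longest run meets a
threshold on enough administrations are flagged and excluded before any
index computation. The default rule is deliberately conservative: a run
covering the full administration (16 of 16 items identical) on at least
half of the administrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import EMOTION_ITEMS

__all__ = ["longstring", "screen_participants", "ScreeningReport"]


def longstring(responses) -> int:
    """Length of the longest run of identical consecutive values.

    ``responses`` is the ordered response vector of a single administration.
    Raises ``ValueError`` on an empty vector.
    """
    x = np.asarray(responses)
    if x.size == 0:
        raise ValueError("empty response vector")
    if x.size == 1:
        return 1
    changes = np.flatnonzero(x[1:] != x[:-1])
    # run boundaries: positions after which the value changes
    edges = np.concatenate(([-1], changes, [x.size - 1]))
    return int(np.diff(edges).max())


@dataclass
class ScreeningReport:
    """Per-participant screening outcome."""

    table: pd.DataFrame  # participant_id, max_longstring, n_flagged_administrations, flagged
    threshold: int
    min_administrations: int | None  # None: half of each participant's administrations

    @property
    def flagged_ids(self) -> list:
        return self.table.loc[self.table["flagged"], "participant_id"].tolist()


def screen_participants(
    ratings: pd.DataFrame,
    threshold: int = len(EMOTION_ITEMS),
    min_administrations: int | None = None,
    item_order: tuple[str, ...] = EMOTION_ITEMS,
) -> ScreeningReport:
    """Flag participants by long-string analysis of their emotion ratings.

    Parameters
    ----------
    ratings : long-format emotion ratings (participant_id, session, item,
        rating); each participant-session is one administration.
    threshold : minimum run length that counts as careless for one
        administration (must be >= 2). Default: the full item count.
    min_administrations : administrations at or above threshold needed to
        flag the participant. Default: half of the participant's
        administrations, rounded up.
    item_order : fixed presentation order used to sequence each
        administration before scanning runs.

    Returns a :class:`ScreeningReport`; downstream stages drop
    ``report.flagged_ids``.
    """
    if threshold < 2:
        raise ValueError(f"threshold must be >= 2, got {threshold}")
    order = {item: i for i, item in enumerate(item_order)}
    df = ratings.copy()
    df["_order"] = df["item"].map(order)
    df = df.sort_values(["participant_id", "session", "_order"], kind="stable")

    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        runs = grp.groupby("session")["rating"].apply(lambda s: longstring(s.to_numpy()))
        n_admin = len(runs)
        need = (
            min_administrations
            if min_administrations is not None
            else (n_admin + 1) // 2
        )
        n_hit = int((runs >= threshold).sum())
        rows.append((pid, int(runs.max()), n_hit, n_hit >= need))
    table = pd.DataFrame(
        rows,
        columns=["participant_id", "max_longstring", "n_flagged_administrations", "flagged"],
    )
    return ScreeningReport(
        table=table,
        threshold=threshold,
        min_administrations=min_administrations,
    )
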