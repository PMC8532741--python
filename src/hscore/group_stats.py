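"""Clinical group statistics over per-dog H-scores.

Ships the published per-dog H-score tables as fixtures: the H-group
(19 clinically treated dogs, first and — for 11 of them — follow-up
visits) and the C-group (19 healthy controls, single visit).  Provides
the three statistics reported on them: a two-tailed Mann–Whitney U
comparison of first-visit scores between groups (U reported in the
min-orientation with half credit for ties), the group medians, and the
count of treated dogs whose follow-up score dropped strictly below the
first-visit score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UTestResult",
    "load_h_group",
    "load_c_group",
    "load_visit_table",
    "mann_whitney_u",
    "group_medians",
    "paired_reduction",
    "clinical_report",
]


@dataclass(frozen=True)
class UTestResult:
    """Two-tailed Mann–Whitney U result with midrank tie handling."""

    u: float             # min(U1, U2)
    u1: float            # orientation: #(a > b) pairs, ties counting 1/2
    n1: int
    n2: int
    p_two_tailed: float
    median1: float
    median2: float
    method: str          # 'exact' | 'asymptotic'


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("hscore.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_h_group() -> pd.DataFrame:
    """H-group fixture: id, name, visit, h_score, medication, b_mod, tbv_months."""
    return _fixture("h_group_table1.csv")


def load_c_group() -> pd.DataFrame:
    """C-group fixture: id, name, h_score (single visit each)."""
    return _fixture("c_group_table2.csv")


def load_visit_table() -> pd.DataFrame:
    """Both fixtures in one long table: id, name, group, visit, h_score."""
    h = load_h_group()[["id", "name", "visit", "h_score"]].assign(group="H")
    c = load_c_group().assign(group="C", visit="first")
    table = pd.concat([h, c[["id", "name", "visit", "h_score", "group"]]],
                      ignore_index=True)
    if table.duplicated(subset=["id", "visit"]).any():
        raise ValueError("fixture holds duplicate (dog, visit) records")
    if not table["h_score"].between(0, 1).all():
        raise ValueError("fixture h_score outside [0, 1]")
    return table


def mann_whitney_u(a, b) -> UTestResult:
    """Two-tailed Mann–Whitney U via midranks; U = min(U1, U2).

    U1 counts pairs where a beats b, ties contributing 1/2.  The two-tailed
    p uses exact enumeration when the samples are tie-free and small
    (n1*n2 <= 400), otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    method = "exact" if (not ties and n1 * n2 <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return UTestResult(
        u=float(min(u1, u2)), u1=float(u1), n1=n1, n2=n2,
        p_two_tailed=float(res.pvalue),
        median1=float(np.median(a)), median2=float(np.median(b)),
        method=method,
    )


def _first_visit_scores(table: pd.DataFrame, group: str) -> np.ndarray:
    mask = (table["group"] == group) & (table["visit"] == "first")
    return table.loc[mask, "h_score"].to_numpy()


def group_medians(table: pd.DataFrame) -> tuple:
    """(median_C, median_H) of the first-visit H-scores."""
    c = _first_visit_scores(table, "C")
    h = _first_visit_scores(table, "H")
    if len(c) == 0 or len(h) == 0:
        raise ValueError("both groups must have first-visit records")
    return float(np.median(c)), float(np.median(h))


def paired_reduction(table: pd.DataFrame) -> tuple:
    """Count treated dogs whose follow-up H-score dropped strictly.

    Returns ``(n_reduced, n_pairs, deltas)`` over H-group dogs with both
    visits; ``deltas`` maps dog id to follow-up minus first score.  A tie
    is not a reduction.
    """
    h = table[table["group"] == "H"]
    first = h[h["visit"] == "first"].set_index("id")["h_score"]
    follow = h[h["visit"] == "follow-up"].set_index("id")["h_score"]
    paired = first.index.intersection(follow.index)
    deltas = {int(i): float(follow[i] - first[i]) for i in paired}
    n_reduced = sum(1 for d in deltas.values() if d < 0)
    return n_reduced, len(paired), deltas


def clinical_report(table: pd.DataFrame | None = None) -> dict:
    """The group-level statistics in one JSON-ready dict."""
    if table is None:
        table = load_visit_table()
    h = _first_visit_scores(table, "H")
    c = _first_visit_scores(table, "C")
    u = mann_whitney_u(h, c)
    median_c, median_h = group_medians(table)
    n_reduced, n_pairs, deltas = paired_reduction(table)
    return {
        "u_statistic": u.u,
        "p_two_tailed": u.p_two_tailed,
        "p_method": u.method,
        "n_h": u.n1,
        "n_c": u.n2,
        "median_h_first": median_h,
        "median_c": median_c,
        "n_reduced": n_reduced,
        "n_pairs": n_pairs,
        "deltas": deltas,
    }
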