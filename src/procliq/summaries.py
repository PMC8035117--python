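"""Clique-level description of response processes.

Each clique found by cluster edge deletion is profiled by the feature set
a practitioner reads as "the strategy this clique shares": the most
common pairwise LCS among its members, the share of members containing
it, the median time-wise importance and median time spent on it, plus
median total task time and median sequence length.  Singleton cliques are
idiosyncratic patterns; a contrast report sets them against the dominant
cliques.
"""

from __future__ import annotations

import itertools
import statistics
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .cluster import Clustering
from .patterns import ActionPattern
from .similarity import compute_lcs

__all__ = [
    "CliqueSummary",
    "contains_subsequence",
    "most_common_lcs",
    "summarize_clique",
    "summarize_clustering",
    "idiosyncrasy_report",
    "write_summaries",
]


@dataclass(frozen=True)
class CliqueSummary:
    clique_id: int
    size: int
    common_lcs: tuple[str, ...]
    pct_containing: float
    md_importance: float
    md_time_on_lcs: float
    md_total_time: float
    md_seq_length: float
    total_time_q25: float
    total_time_q75: float
    seq_length_q25: float
    seq_length_q75: float


def contains_subsequence(
    pattern: ActionPattern, seq: Sequence[str]
) -> tuple[bool, tuple[int, ...]]:
    """Is ``seq`` a (non-contiguous) subsequence of the pattern's actions?

    Returns the leftmost-greedy 0-based index map when it is; the same
    embedding is used to attribute times to a clique-level LCS.
    """
    if len(seq) == 0:
        raise ValueError("containment of an empty sequence is undefined")
    indices: list[int] = []
    pos = 0
    actions = pattern.actions
    for label in seq:
        while pos < len(actions) and actions[pos] != label:
            pos += 1
        if pos == len(actions):
            return False, ()
        indices.append(pos)
        pos += 1
    return True, tuple(indices)


def _pick_modal(counts: Counter) -> tuple[str, ...]:
    best = None
    for seq, n in counts.items():
        key = (n, len(seq))
        if (
            best is None
            or key > best[0]
            or (key == best[0] and seq < best[1])
        ):
            best = (key, seq)
    return best[1]


def most_common_lcs(members: Sequence[ActionPattern]) -> tuple[str, ...]:
    """The modal canonical pairwise LCS among a clique's members.

    All member pairs' canonical LCSs are tallied; ties are broken by
    higher multiplicity, then longer length, then lexicographic order.
    A singleton clique's "LCS" is its member's own action sequence.
    """
    if len(members) == 0:
        raise ValueError("empty clique")
    if len(members) == 1:
        return members[0].actions
    counts: Counter[tuple[str, ...]] = Counter()
    for a, b in itertools.combinations(members, 2):
        lcs = compute_lcs(a.actions, b.actions).lcs
        if lcs:
            counts[lcs] += 1
    if not counts:
        return max((m.actions for m in members), key=lambda s: (len(s), s))
    return _pick_modal(counts)


def _quantiles(values: Sequence[float]) -> tuple[float, float]:
    s = pd.Series(list(values), dtype=float)
    return float(s.quantile(0.25)), float(s.quantile(0.75))


def summarize_clique(
    members: Sequence[ActionPattern], clique_id: int = 0
) -> CliqueSummary:
    """Profile one clique's shared response process."""
    common = most_common_lcs(members)
    importances: list[float] = []
    times_on: list[float] = []
    n_contain = 0
    for m in members:
        ok, emb = contains_subsequence(m, common)
        if not ok:
            continue
        n_contain += 1
        t_on = sum(m.times[k] for k in emb)
        times_on.append(t_on)
        importances.append(t_on / m.total_time if m.total_time > 0 else 0.0)
    tot = [m.total_time for m in members]
    lens = [float(m.u) for m in members]
    t_q25, t_q75 = _quantiles(tot)
    l_q25, l_q75 = _quantiles(lens)
    return CliqueSummary(
        clique_id=clique_id,
        size=len(members),
        common_lcs=common,
        pct_containing=n_contain / len(members),
        md_importance=statistics.median(importances) if importances else 0.0,
        md_time_on_lcs=statistics.median(times_on) if times_on else 0.0,
        md_total_time=statistics.median(tot),
        md_seq_length=statistics.median(lens),
        total_time_q25=t_q25,
        total_time_q75=t_q75,
        seq_length_q25=l_q25,
        seq_length_q75=l_q75,
    )


def summarize_clustering(
    clustering: Clustering, patterns: Sequence[ActionPattern]
) -> list[CliqueSummary]:
    """One :class:`CliqueSummary` per clique, largest cliques first."""
    by_id = {p.person_id: p for p in patterns}
    out = []
    order = sorted(
        clustering.cliques, key=lambda c: (-len(c), sorted(map(str, c)))
    )
    for k, clique in enumerate(order):
        members = [by_id[v] for v in clique]
        out.append(summarize_clique(members, clique_id=k))
    return out


def idiosyncrasy_report(
    clustering: Clustering,
    patterns: Sequence[ActionPattern],
    min_dominant_size: int = 5,
) -> pd.DataFrame:
    """Contrast singleton cliques against dominant cliques.

    Rows are metrics — count, median/min/max of total task time and of
    sequence length, then per-action occurrence proportions (share of
    patterns containing the action at least once, rows ``occ:<label>``).
    Columns ``singleton`` and ``dominant`` (size ≥ ``min_dominant_size``);
    an empty side yields a NaN column, flagged in ``df.attrs['empty']``.
    """
    by_id = {p.person_id: p for p in patterns}
    singles = [
        by_id[v] for c in clustering.cliques if len(c) == 1 for v in c
    ]
    dominant = [
        by_id[v]
        for c in clustering.cliques
        if len(c) >= min_dominant_size
        for v in c
    ]
    labels = sorted({a for p in patterns for a in p.actions})

    def col(group: list[ActionPattern]) -> dict[str, float]:
        if not group:
            return {}
        tot = [p.total_time for p in group]
        lens = [p.u for p in group]
        d = {
            "n_patterns": float(len(group)),
            "median_total_time": statistics.median(tot),
            "min_total_time": min(tot),
            "max_total_time": max(tot),
            "median_seq_length": float(statistics.median(lens)),
            "min_seq_length": float(min(lens)),
            "max_seq_length": float(max(lens)),
        }
        for lab in labels:
            share = sum(lab in p.actions for p in group) / len(group)
            d[f"occ:{lab}"] = share
        return d

    df = pd.DataFrame(
        {"singleton": col(singles), "dominant": col(dominant)},
        dtype=float,
    )
    empty = [name for name, grp in
             (("singleton", singles), ("dominant", dominant)) if not grp]
    df.attrs["empty"] = empty
    df.attrs["min_dominant_size"] = min_dominant_size
    return df


def write_summaries(
    summaries: Sequence[CliqueSummary], path: str | Path
) -> None:
    rows = []
    for s in summaries:
        d = asdict(s)
        d["common_lcs"] = " ".join(s.common_lcs)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
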