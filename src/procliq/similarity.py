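"""Pairwise similarity of action patterns based on the timed LCS.

Three measures are provided, all in [0, 1]:

``original``
    The mean min–max ratio of the times-to-action attached to the two
    embeddings of the longest common subsequence (LCS), weighted by the
    time-wise importance of the LCS.  Sensitive to timing differences on
    single shared actions.

``modified``
    The min–max ratio of the two *total* times spent on the LCS, weighted
    by the same importance.  Sensitive only to aggregate pacing over the
    area of overlap.

``action_only``
    The geometric mean of the LCS length relative to each sequence
    length; ignores timing entirely.

Importance is the geometric mean, across the two patterns, of the share
of total task time spent on LCS-mapped actions — long shared subsequences
that occupy most of both people's time weigh more than incidental overlap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from collections.abc import Sequence
from pathlib import Path

import pandas as pd

from .patterns import ActionPattern

__all__ = [
    "LCSAlignment",
    "SimilarityMeasureSpec",
    "MEASURE_KINDS",
    "compute_lcs",
    "sim_timing_original",
    "sim_timing_modified",
    "importance",
    "similarity",
    "pairwise_similarities",
    "write_edge_list",
    "read_edge_list",
]

MEASURE_KINDS = ("original", "modified", "action_only")


@dataclass(frozen=True)
class LCSAlignment:
    """A longest common subsequence plus its embeddings into both sequences.

    ``map_i`` / ``map_j`` are strictly increasing 0-based index tuples of
    length ``len(lcs)`` locating each LCS element in the two source
    sequences.
    """

    lcs: tuple[str, ...]
    map_i: tuple[int, ...]
    map_j: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.lcs)


@dataclass(frozen=True)
class SimilarityMeasureSpec:
    """Which measure to evaluate.  ``kind`` ∈ {original, modified, action_only}."""

    kind: str = "modified"

    def __post_init__(self) -> None:
        if self.kind not in MEASURE_KINDS:
            raise ValueError(
                f"kind must be one of {MEASURE_KINDS}, got {self.kind!r}"
            )


def compute_lcs(a_i: Sequence[str], a_j: Sequence[str]) -> LCSAlignment:
    """Longest common subsequence of two action sequences, with index maps.

    When several maximal common subsequences exist, the canonical one is
    returned: matches are chosen greedily left-to-right, always taking the
    lexicographically smallest feasible index pair.  This makes every
    timing measure built on the LCS deterministic.
    """
    if len(a_i) == 0 or len(a_j) == 0:
        raise ValueError("compute_lcs requires non-empty sequences")
    n, m = len(a_i), len(a_j)
    # suffix[x][y] = LCS length of a_i[x:] vs a_j[y:]
    suffix = [[0] * (m + 1) for _ in range(n + 1)]
    for x in range(n - 1, -1, -1):
        row, below = suffix[x], suffix[x + 1]
        for y in range(m - 1, -1, -1):
            if a_i[x] == a_j[y]:
                row[y] = below[y + 1] + 1
            else:
                row[y] = max(below[y], row[y + 1])
    lcs: list[str] = []
    map_i: list[int] = []
    map_j: list[int] = []
    x = y = 0
    remaining = suffix[0][0]
    while remaining > 0:
        # smallest feasible (x', y') completing an LCS of the full length
        found = False
        for x2 in range(x, n):
            if suffix[x2][y] < remaining:
                break  # skipping past x2-1 already lost length
            for y2 in range(y, m):
                if a_i[x2] == a_j[y2] and suffix[x2 + 1][y2 + 1] == remaining - 1:
                    lcs.append(a_i[x2])
                    map_i.append(x2)
                    map_j.append(y2)
                    x, y = x2 + 1, y2 + 1
                    remaining -= 1
                    found = True
                    break
            if found:
                break
        assert found, "traceback invariant violated"
    return LCSAlignment(tuple(lcs), tuple(map_i), tuple(map_j))


def _minmax(a: float, b: float) -> float:
    """min/max ratio; both zero counts as identical timing (ratio 1)."""
    if a == b:
        return 1.0
    return min(a, b) / max(a, b)


def sim_timing_original(
    align: LCSAlignment, t_i: Sequence[float], t_j: Sequence[float]
) -> float:
    """Average min–max similarity of the LCS-mapped times-to-action."""
    if len(align) == 0:
        raise ValueError("timing similarity undefined for an empty LCS")
    ratios = (
        _minmax(t_i[x], t_j[y]) for x, y in zip(align.map_i, align.map_j)
    )
    return sum(ratios) / len(align)


def sim_timing_modified(
    align: LCSAlignment, t_i: Sequence[float], t_j: Sequence[float]
) -> float:
    """Min–max similarity of total time spent on the area of overlap."""
    if len(align) == 0:
        raise ValueError("timing similarity undefined for an empty LCS")
    si = sum(t_i[x] for x in align.map_i)
    sj = sum(t_j[y] for y in align.map_j)
    return _minmax(si, sj)


def importance(
    align: LCSAlignment, pattern_i: ActionPattern, pattern_j: ActionPattern
) -> float:
    """Geometric mean of the LCS's share of total task time in each pattern."""
    ti_tot = pattern_i.total_time
    tj_tot = pattern_j.total_time
    if ti_tot <= 0 or tj_tot <= 0:
        raise ValueError("importance requires positive total task time")
    ti_lcs = sum(pattern_i.times[x] for x in align.map_i)
    tj_lcs = sum(pattern_j.times[y] for y in align.map_j)
    return math.sqrt((ti_lcs / ti_tot) * (tj_lcs / tj_tot))


def similarity(
    pattern_i: ActionPattern,
    pattern_j: ActionPattern,
    spec: SimilarityMeasureSpec | str = "modified",
) -> float:
    """Similarity s_ij of two action patterns under the chosen measure.

    An empty LCS yields 0 for every measure; a pattern compared with
    itself yields 1.  The pair is oriented canonically before the LCS
    traceback, so the value is independent of argument order even when
    several maximal common subsequences exist.
    """
    if isinstance(spec, str):
        spec = SimilarityMeasureSpec(spec)
    if (pattern_j.actions, pattern_j.times) < (pattern_i.actions, pattern_i.times):
        pattern_i, pattern_j = pattern_j, pattern_i
    align = compute_lcs(pattern_i.actions, pattern_j.actions)
    if len(align) == 0:
        return 0.0
    if spec.kind == "action_only":
        return math.sqrt(
            (len(align) / pattern_i.u) * (len(align) / pattern_j.u)
        )
    imp = importance(align, pattern_i, pattern_j)
    if spec.kind == "original":
        sim = sim_timing_original(align, pattern_i.times, pattern_j.times)
    else:
        sim = sim_timing_modified(align, pattern_i.times, pattern_j.times)
    return sim * imp


def pairwise_similarities(
    patterns: Sequence[ActionPattern],
    spec: SimilarityMeasureSpec | str = "modified",
) -> pd.DataFrame:
    """All N(N−1)/2 unordered-pair similarities as an edge-list frame.

    Columns ``i``, ``j`` (person ids) and ``s``.  Each unordered pair is
    computed exactly once, so symmetry holds by construction.
    """
    if isinstance(spec, str):
        spec = SimilarityMeasureSpec(spec)
    ids = [p.person_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate person_id among patterns")
    rows = [
        (pi.person_id, pj.person_id, similarity(pi, pj, spec))
        for pi, pj in itertools.combinations(patterns, 2)
    ]
    df = pd.DataFrame(rows, columns=["i", "j", "s"])
    df.attrs["measure"] = spec.kind
    return df


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    """TSV edge list with a ``# measure: <kind>`` metadata header line."""
    measure = edges.attrs.get("measure", "unknown")
    with open(path, "w") as fh:
        fh.write(f"# measure: {measure}\n")
        edges.to_csv(fh, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        measure = None
        if first.startswith("#"):
            measure = first.split(":", 1)[1].strip() if ":" in first else None
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    if measure:
        df.attrs["measure"] = measure
    return df
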