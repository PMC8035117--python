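import itertools

import numpy as np
import pandas as pd
import pytest

from procliq import worked_example_fixture, worked_example_patterns


@pytest.fixture
def p1_p2():
    """The two fully printed illustration patterns."""
    return worked_example_patterns()


@pytest.fixture
def example_graph():
    """The 4-vertex post-threshold illustration graph (unit weights)."""
    graph, _ = worked_example_fixture()
    return graph


def lcs_length_oracle(a, b):
    """Exhaustive LCS length: max over all subsequences of the shorter seq."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        for comb in itertools.combinations(short, r):
            if is_subsequence(comb, long_):
                return r
    return best


def is_subsequence(sub, seq):
    it = iter(seq)
    return all(x in it for x in sub)


def random_weighted_graph(rng, n, p):
    """Erdős–Rényi graph with uniform (0,1] weights as an edge-list frame."""
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            rows.append((i, j, float(1.0 - rng.random())))  # weight in (0,1]
    return pd.DataFrame(rows, columns=["i", "j", "s"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
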