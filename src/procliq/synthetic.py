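"""Synthetic event logs with planted response-process structure.

Real interactive-item logs show groups of people executing a shared core
strategy — the same actions in the same order — interleaved with
idiosyncratic extra actions (exploration, checks), at group-specific
pacing, with positively skewed per-action latencies.  The generator
emulates exactly that: each group has a core action sequence, a time
scale multiplier, a log-normal latency sigma and a noise-insertion rate;
outliers get long random sequences.  True group labels are returned so
downstream recovery can be scored.

The printed worked-example pair (p1 = [(A,1.5)(B,2)(C,2.5)],
p2 = [(A,1)(D,1)(B,1.5)(E,1)(C,2.5)]) and the 4-vertex post-threshold
graph it belongs to are shipped as a deterministic fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import SimilarityGraph, build_graph
from .patterns import ActionPattern

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "default_config",
    "generate",
    "labels_to_frame",
    "worked_example_patterns",
    "worked_example_fixture",
]

#: median seconds per action at time scale 1 (typical click/drag latency)
BASE_ACTION_TIME = 2.0


@dataclass(frozen=True)
class GroupSpec:
    """One planted group: shared core sequence plus noise parameters."""

    name: str
    core: tuple[str, ...]
    n_members: int
    time_scale: float = 1.0
    sigma: float = 0.2
    insertion_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_members < 0:
            raise ValueError("n_members must be >= 0")
        if not (0.0 <= self.insertion_rate < 1.0):
            raise ValueError("insertion_rate must lie in [0, 1)")
        if self.sigma <= 0 or self.time_scale <= 0:
            raise ValueError("sigma and time_scale must be positive")
        if len(self.core) == 0:
            raise ValueError("core sequence must be non-empty")


@dataclass(frozen=True)
class GeneratorConfig:
    groups: tuple[GroupSpec, ...]
    outlier_count: int = 0
    outlier_length: int = 18
    noise_alphabet: tuple[str, ...] = ("help", "explore", "check", "scroll")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("config must define at least one group")
        if self.outlier_count < 0:
            raise ValueError("outlier_count must be >= 0")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Three strategy groups of 10 plus 2 outliers.

    Two groups share the drag-and-drop core but differ 3.5× in pacing;
    the third reaches the same goal through a toolbar/menu route (only
    the final confirm is shared).  Insertion rate 0.10 and latency sigma
    0.20 are the study's noise conditions; per-action median time is
    2 s at scale 1.
    """
    drag_core = ("open1", "move1", "open2", "move2", "open3", "confirm")
    toolbar_core = (
        "menu", "toolbar", "select1",
        "menu", "toolbar", "select2",
        "menu", "toolbar", "select3",
        "confirm",
    )
    return GeneratorConfig(
        groups=(
            GroupSpec("drag_fast", drag_core, 10, time_scale=1.0),
            GroupSpec("drag_slow", drag_core, 10, time_scale=3.5),
            GroupSpec("toolbar", toolbar_core, 10, time_scale=1.0),
        ),
        outlier_count=2,
        seed=seed,
    )


def _draw_time(rng: np.random.Generator, scale: float, sigma: float) -> float:
    return float(scale * BASE_ACTION_TIME * rng.lognormal(0.0, sigma))


def generate(
    config: GeneratorConfig,
) -> tuple[list[ActionPattern], dict[object, str]]:
    """Sample patterns and their true group labels (outliers: ``outlier``).

    Each member's action sequence is its group core with independent
    noise-action insertions (probability = insertion rate, before each
    core action and at the end); every time-to-action is log-normal with
    the group's scale.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    patterns: list[ActionPattern] = []
    labels: dict[object, str] = {}
    pid = 0
    for grp in config.groups:
        for _ in range(grp.n_members):
            pid += 1
            actions: list[str] = []
            times: list[float] = []
            for a in grp.core:
                if rng.random() < grp.insertion_rate:
                    actions.append(str(rng.choice(config.noise_alphabet)))
                    times.append(_draw_time(rng, grp.time_scale, grp.sigma))
                actions.append(a)
                times.append(_draw_time(rng, grp.time_scale, grp.sigma))
            if rng.random() < grp.insertion_rate:
                actions.append(str(rng.choice(config.noise_alphabet)))
                times.append(_draw_time(rng, grp.time_scale, grp.sigma))
            name = f"p{pid:03d}"
            patterns.append(ActionPattern(name, tuple(actions), tuple(times)))
            labels[name] = grp.name
    # outliers: long random sequences over the full vocabulary, noisy pacing
    vocab = tuple(
        sorted({a for g in config.groups for a in g.core})
        + list(config.noise_alphabet)
    )
    for _ in range(config.outlier_count):
        pid += 1
        length = config.outlier_length
        actions = [str(rng.choice(vocab)) for _ in range(length)]
        times = [_draw_time(rng, 2.0, 0.6) for _ in range(length)]
        name = f"p{pid:03d}"
        patterns.append(ActionPattern(name, tuple(actions), tuple(times)))
        labels[name] = "outlier"
    return patterns, labels


def labels_to_frame(labels: dict[object, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"person_id": list(labels), "group": list(labels.values())}
    )


# ------------------------------------------------------- worked example ----


def worked_example_patterns() -> tuple[ActionPattern, ActionPattern]:
    """The two fully printed illustration patterns p1, p2."""
    p1 = ActionPattern("1", ("A", "B", "C"), (1.5, 2.0, 2.5))
    p2 = ActionPattern(
        "2", ("A", "D", "B", "E", "C"), (1.0, 1.0, 1.5, 1.0, 2.5)
    )
    return p1, p2


def worked_example_fixture() -> tuple[SimilarityGraph, tuple[ActionPattern, ActionPattern]]:
    """The 4-examinee illustration: post-threshold graph plus p1, p2.

    Only p1 and p2 are printed with full timing; examinees 3 and 4 appear
    schematically, so the fixture carries the resulting thresholded graph
    directly — edges {1,2}, {1,3}, {2,3}, {2,4} with unit weights — whose
    unique optimal cluster edge deletion removes {2,4}, leaving cliques
    (1,2,3) and (4).
    """
    edges = pd.DataFrame(
        {
            "i": ["1", "1", "2", "2"],
            "j": ["2", "3", "3", "4"],
            "s": [1.0, 1.0, 1.0, 1.0],
        }
    )
    graph = build_graph(edges, kappa=0.5, vertices=["1", "2", "3", "4"])
    return graph, worked_example_patterns()
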