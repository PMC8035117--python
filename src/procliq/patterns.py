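"""Action-pattern data model and event-log preprocessing.

An *action pattern* is one person's ordered sequence of executed actions
together with the time-to-action of each: the seconds that elapsed between
the previous action (or task onset, for the first action) and the action
itself.  Patterns are the atomic unit that every downstream stage —
similarity, graph construction, clustering, summarisation — consumes.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ActionPattern",
    "RecodingTable",
    "NegativeTimeError",
    "OnsetMissingError",
    "patterns_from_log",
    "recode",
    "read_log",
    "read_recoding_table",
    "patterns_to_frame",
    "write_patterns",
    "read_patterns",
]


class NegativeTimeError(ValueError):
    """A computed time-to-action is negative (out-of-order timestamps)."""


class OnsetMissingError(KeyError):
    """Timestamp mode requires an onset time that was not supplied."""


@dataclass(frozen=True)
class ActionPattern:
    """One person's ordered (action, time-to-action) sequence.

    Parameters
    ----------
    person_id
        Opaque identifier of the actor.
    actions
        Action labels in execution order.
    times
        Times to action in seconds, aligned with ``actions``.  Zero is
        permitted (sub-resolution events such as keystrokes); negative
        values are not.
    """

    person_id: object
    actions: tuple[str, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.actions) != len(self.times):
            raise ValueError(
                f"pattern {self.person_id!r}: {len(self.actions)} actions "
                f"but {len(self.times)} times"
            )
        if len(self.actions) == 0:
            raise ValueError(f"pattern {self.person_id!r}: empty sequence")
        if any(t < 0 for t in self.times):
            raise NegativeTimeError(
                f"pattern {self.person_id!r}: negative time-to-action"
            )

    @property
    def u(self) -> int:
        """Sequence length."""
        return len(self.actions)

    @property
    def total_time(self) -> float:
        """Total task time: the sum of all times-to-action."""
        return sum(self.times)

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class RecodingTable:
    """Raw-label → aggregated-category recoding, plus labels to drop.

    ``unmapped`` controls labels absent from ``mapping``: ``"keep"``
    passes them through unchanged, ``"error"`` raises.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    drop_set: set[str] = field(default_factory=set)
    unmapped: str = "keep"

    def __post_init__(self) -> None:
        if self.unmapped not in ("keep", "error"):
            raise ValueError("unmapped must be 'keep' or 'error'")

    def apply_label(self, label: str) -> str | None:
        """Map one label; ``None`` means the action is dropped."""
        if label in self.drop_set:
            return None
        if label in self.mapping:
            return self.mapping[label]
        if self.unmapped == "error":
            raise KeyError(f"no recoding for action label {label!r}")
        return label


def patterns_from_log(
    rows: pd.DataFrame,
    time_mode: str = "times_to_action",
    item_onset: float | Mapping[object, float] = 0.0,
) -> list[ActionPattern]:
    """Build one :class:`ActionPattern` per person from a long event log.

    ``rows`` needs columns ``person_id``, ``action`` and either
    ``time_to_action`` or ``timestamp`` depending on ``time_mode``.  Row
    order within a person is taken as execution order.  In timestamp mode
    the first time-to-action is ``timestamp_1 - onset`` and subsequent ones
    are first differences of the timestamps.

    Raises
    ------
    NegativeTimeError
        If a computed time-to-action is negative for some person.
    OnsetMissingError
        In timestamp mode, if a person has no onset in the mapping.
    """
    if time_mode not in ("times_to_action", "timestamps"):
        raise ValueError(f"unknown time_mode {time_mode!r}")
    time_col = "time_to_action" if time_mode == "times_to_action" else "timestamp"
    for col in ("person_id", "action", time_col):
        if col not in rows.columns:
            raise ValueError(f"event log lacks required column {col!r}")

    patterns: list[ActionPattern] = []
    for pid, grp in rows.groupby("person_id", sort=False):
        actions = tuple(str(a) for a in grp["action"])
        raw = [float(t) for t in grp[time_col]]
        if time_mode == "times_to_action":
            times = raw
        else:
            if isinstance(item_onset, Mapping):
                if pid not in item_onset:
                    raise OnsetMissingError(
                        f"no item onset supplied for person {pid!r}"
                    )
                onset = float(item_onset[pid])
            else:
                onset = float(item_onset)
            times = [raw[0] - onset]
            times += [b - a for a, b in zip(raw, raw[1:])]
        if any(t < 0 for t in times):
            raise NegativeTimeError(
                f"person {pid!r}: negative time-to-action in log"
            )
        patterns.append(ActionPattern(pid, actions, tuple(times)))
    return patterns


def recode(
    patterns: Iterable[ActionPattern], table: RecodingTable
) -> list[ActionPattern]:
    """Drop and relabel actions per ``table``, preserving order.

    A dropped action's time is removed with it (not folded into the next
    action).  Patterns emptied entirely by dropping are excluded from the
    output with a logged warning.
    """
    out: list[ActionPattern] = []
    for p in patterns:
        actions: list[str] = []
        times: list[float] = []
        for a, t in zip(p.actions, p.times):
            new = table.apply_label(a)
            if new is None:
                continue
            actions.append(new)
            times.append(t)
        if not actions:
            logger.warning(
                "pattern %r emptied by recoding; excluded", p.person_id
            )
            continue
        out.append(ActionPattern(p.person_id, tuple(actions), tuple(times)))
    return out


# ---------------------------------------------------------------- I/O ----


def read_log(path: str | Path) -> pd.DataFrame:
    """Read a long-format event log (CSV, or JSON-lines for ``.jsonl``)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        return pd.read_json(path, lines=True)
    return pd.read_csv(path)


def read_recoding_table(path: str | Path) -> RecodingTable:
    """Read a recoding table: columns ``raw``, ``aggregated``, optional ``drop``."""
    df = pd.read_csv(path)
    if "raw" not in df.columns:
        raise ValueError("recoding table needs a 'raw' column")
    mapping: dict[str, str] = {}
    drop: set[str] = set()
    for _, row in df.iterrows():
        raw = str(row["raw"])
        if "drop" in df.columns and bool(row["drop"]) and str(row["drop"]) != "nan":
            drop.add(raw)
            continue
        if "aggregated" in df.columns and pd.notna(row.get("aggregated")):
            mapping[raw] = str(row["aggregated"])
    return RecodingTable(mapping=mapping, drop_set=drop)


def patterns_to_frame(patterns: Sequence[ActionPattern]) -> pd.DataFrame:
    """Long-format frame (person_id, action, time_to_action), round-trip safe."""
    recs = [
        {"person_id": p.person_id, "action": a, "time_to_action": t}
        for p in patterns
        for a, t in zip(p.actions, p.times)
    ]
    return pd.DataFrame.from_records(
        recs, columns=["person_id", "action", "time_to_action"]
    )


def write_patterns(patterns: Sequence[ActionPattern], path: str | Path) -> None:
    patterns_to_frame(patterns).to_csv(path, index=False)


def read_patterns(path: str | Path) -> list[ActionPattern]:
    """Inverse of :func:`write_patterns`."""
    return patterns_from_log(read_log(path), time_mode="times_to_action")
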