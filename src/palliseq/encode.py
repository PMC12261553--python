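"""Pathway encoding: initiation days -> timed linear sequences.

A pathway is the ordered list of palliative-care services an individual
initiated, earliest first (largest day-before-death first), together with
the transition times in days between consecutive initiations.  A gap of 0
marks simultaneous initiation; the leading gap is fixed at 0.  Individuals
without any palliative-care service have no pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import CohortMember
from .datasets import PALLIATIVE_SERVICES

__all__ = [
    "PathwaySequence",
    "TransitionGraph",
    "encode_pathway",
    "encode_cohort",
    "build_transition_graph",
    "sequences_to_frame",
    "frame_to_sequences",
    "CANONICAL_ORDER",
]

#: Tie order for services initiated on the same day (makes encoding, and
#: therefore alignment, deterministic).
CANONICAL_ORDER = {s: i for i, s in enumerate(PALLIATIVE_SERVICES)}


@dataclass(frozen=True)
class PathwaySequence:
    """Timed sequence of service initiations for one individual."""

    individual_id: str
    events: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.events) <= 4:
            raise ValueError(f"{self.individual_id}: need 1-4 events")
        if len(set(self.events)) != len(self.events):
            raise ValueError(f"{self.individual_id}: repeated service")
        if len(self.gaps) != len(self.events):
            raise ValueError(f"{self.individual_id}: gaps length != events length")
        if self.gaps[0] != 0:
            raise ValueError(f"{self.individual_id}: leading gap must be 0")
        if any(g < 0 for g in self.gaps):
            raise ValueError(f"{self.individual_id}: negative gap")

    def __len__(self) -> int:
        return len(self.events)

    def to_days(self, first_day: int) -> dict[str, int]:
        """Reconstruct absolute initiation days, anchored at the earliest one."""
        days, day = {}, first_day
        for event, gap in zip(self.events, self.gaps):
            day -= gap
            days[event] = day
        return days


def encode_pathway(member: CohortMember) -> PathwaySequence | None:
    """Encode one member's initiation days; ``None`` if no palliative care.

    Events are ordered from earliest initiation (largest day before death)
    to latest; same-day initiations are ordered PPC < SPHC < IPC < HOSPICE
    and separated by a gap of 0.
    """
    if not member.pc_initiation:
        return None
    items = sorted(
        member.pc_initiation.items(),
        key=lambda kv: (-kv[1], CANONICAL_ORDER[kv[0]]),
    )
    events = tuple(s for s, _ in items)
    days = [d for _, d in items]
    gaps = (0,) + tuple(prev - cur for prev, cur in zip(days, days[1:]))
    return PathwaySequence(member.individual_id, events, gaps)


def encode_cohort(cohort: list[CohortMember]) -> list[PathwaySequence]:
    """Encode every member with palliative care, preserving cohort order."""
    return [s for s in map(encode_pathway, cohort) if s is not None]


@dataclass
class TransitionGraph:
    """Counts of sequential and simultaneous service initiations.

    Vertices count individuals who initiated a service at all; a directed
    edge (a, b) counts individuals who initiated b strictly after a
    (consecutively in their pathway); simultaneous initiations are tallied
    separately per unordered pair and never contribute to edges.
    """

    vertex_counts: dict[str, int] = field(default_factory=dict)
    edge_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    simultaneous_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": dict(sorted(self.vertex_counts.items())),
                "edges": {f"{a}>{b}": n
                          for (a, b), n in sorted(self.edge_counts.items())},
                "simultaneous": {f"{a}+{b}": n
                                 for (a, b), n in sorted(self.simultaneous_counts.items())},
            },
            indent=2,
        )


def build_transition_graph(sequences: list[PathwaySequence]) -> TransitionGraph:
    graph = TransitionGraph()
    for seq in sequences:
        for event in seq.events:
            graph.vertex_counts[event] = graph.vertex_counts.get(event, 0) + 1
        for a, b, gap in zip(seq.events, seq.events[1:], seq.gaps[1:]):
            if gap > 0:
                graph.edge_counts[(a, b)] = graph.edge_counts.get((a, b), 0) + 1
            else:
                pair = tuple(sorted((a, b), key=CANONICAL_ORDER.get))
                graph.simultaneous_counts[pair] = (
                    graph.simultaneous_counts.get(pair, 0) + 1
                )
    return graph


def sequences_to_frame(sequences: list[PathwaySequence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [s.individual_id for s in sequences],
            "events": [">".join(s.events) for s in sequences],
            "gaps": [",".join(map(str, s.gaps)) for s in sequences],
        }
    )


def frame_to_sequences(frame: pd.DataFrame) -> list[PathwaySequence]:
    return [
        PathwaySequence(
            row.individual_id,
            tuple(row.events.split(">")),
            tuple(int(g) for g in str(row.gaps).split(",")),
        )
        for row in frame.itertuples(index=False)
    ]


def write_sequences(
    sequences: list[PathwaySequence], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequences_to_frame(sequences).to_csv(out / "sequences.csv", index=False)
    (out / "graph.json").write_text(build_transition_graph(sequences).to_json())
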