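"""Shared record types for node tables."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

NATIVE = "native"
TEMPLATE = "template"
SPACES = (NATIVE, TEMPLATE)

#: Canonical column order of the CSV node table.
NODE_COLUMNS = (
    "patient_id",
    "node_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "space",
    "level",
    "side",
    "surgery",
)


@dataclass(frozen=True)
class NodeRecord:
    """One lymph-node center point.

    ``level``/``side`` describe the level assignment of the template-space
    position ("outside" / "none" when unassigned); ``space`` tags whether
    ``position`` is in native patient coordinates or in the template.
    """

    patient_id: str
    node_id: str
    position: tuple[float, float, float]
    space: str = TEMPLATE
    level: str = "outside"
    side: str = "none"
    surgery: bool = False

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown space tag {self.space!r}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite node position {self.position}")

    def with_position(self, position, space: str) -> "NodeRecord":
        return replace(self, position=tuple(float(c) for c in position), space=space)


def nodes_to_frame(nodes: Iterable[NodeRecord]) -> pd.DataFrame:
    rows = [
        (
            n.patient_id,
            n.node_id,
            n.position[0],
            n.position[1],
            n.position[2],
            n.space,
            n.level,
            n.side,
            n.surgery,
        )
        for n in nodes
    ]
    return pd.DataFrame(rows, columns=list(NODE_COLUMNS))


def frame_to_nodes(frame: pd.DataFrame) -> list[NodeRecord]:
    nodes = []
    for row in frame.itertuples(index=False):
        nodes.append(
            NodeRecord(
                patient_id=str(row.patient_id),
                node_id=str(row.node_id),
                position=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
                space=str(row.space),
                level=str(row.level),
                side=str(row.side),
                surgery=bool(row.surgery),
            )
        )
    return nodes


def positions(nodes: Sequence[NodeRecord]):
    import numpy as np

    return np.array([n.position for n in nodes], dtype=float).reshape(len(nodes), 3)
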