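"""Point mapping through displacement vector fields.

A :class:`DisplacementField` stores a dense 3-component vector volume (mm)
on a :class:`~nodalmap.grid.TemplateGrid`; mapping a point adds the
trilinearly interpolated displacement to it.  Registration itself is out of
scope — fields come from the synthetic generator or from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import TemplateGrid
from .records import NATIVE, TEMPLATE, NodeRecord

NATIVE_TO_TEMPLATE = "native_to_template"
TEMPLATE_TO_NATIVE = "template_to_native"
DIRECTIONS = (NATIVE_TO_TEMPLATE, TEMPLATE_TO_NATIVE)


@dataclass(frozen=True)
class DisplacementField:
    """Dense displacement field: ``mapped = p + vectors(p)`` (mm, LPS)."""

    grid: TemplateGrid
    vectors: np.ndarray  # shape (*grid.shape, 3)
    direction: str

    def __post_init__(self) -> None:
        vec = np.ascontiguousarray(np.asarray(self.vectors, dtype=float))
        if vec.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"vector map shape {vec.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError("displacement field contains non-finite vectors")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown field direction {self.direction!r}")
        object.__setattr__(self, "vectors", vec)

    def interpolator(self) -> RegularGridInterpolator:
        axes = tuple(self.grid.axis_coords(a) for a in range(3))
        return RegularGridInterpolator(axes, self.vectors, method="linear")

    def scaled(self, alpha: float) -> "DisplacementField":
        return DisplacementField(self.grid, self.vectors * float(alpha), self.direction)


def apply_dvf(
    points: np.ndarray, field: DisplacementField
) -> tuple[np.ndarray, np.ndarray]:
    """Displace points by the interpolated field.

    Points outside the field extent are interpolated with edge clamping and
    flagged.

    Returns
    -------
    mapped : (n, 3) array
    clamped : (n,) bool array, True where the point was outside the extent
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates")
    lo = np.array([e[0] for e in field.grid.extent_mm])
    hi = np.array([e[1] for e in field.grid.extent_mm])
    clamped_pts = np.clip(pts, lo, hi)
    flags = np.any(clamped_pts != pts, axis=1)
    disp = field.interpolator()(clamped_pts)
    return pts + disp, flags


def map_cohort(
    cohort,
    fields: dict[str, DisplacementField] | None = None,
) -> tuple[list[NodeRecord], pd.DataFrame]:
    """Map every patient's native node centers into template space.

    Parameters
    ----------
    cohort : sequence of PatientCase
    fields : optional per-patient ``native_to_template`` fields; defaults to
        each case's own inverse field.

    Returns
    -------
    nodes : template-space NodeRecords (ids preserved)
    qc : per-node frame with displacement magnitude and clamp flag
    """
    out: list[NodeRecord] = []
    qc_rows = []
    for case in cohort:
        field = None
        if fields is not None:
            field = fields.get(case.patient_id)
        elif getattr(case, "dvf_inverse", None) is not None:
            field = case.dvf_inverse
        if field is None:
            raise ValueError(f"no displacement field for patient {case.patient_id!r}")
        if field.direction != NATIVE_TO_TEMPLATE:
            raise ValueError(
                f"field for patient {case.patient_id!r} has direction "
                f"{field.direction!r}, expected {NATIVE_TO_TEMPLATE!r}"
            )
        native = [n for n in case.nodes_native]
        if not native:
            continue
        pts = np.array([n.position for n in native], dtype=float)
        mapped, flags = apply_dvf(pts, field)
        for node, pos, flag in zip(native, mapped, flags):
            out.append(node.with_position(pos, TEMPLATE))
            qc_rows.append(
                (
                    case.patient_id,
                    node.node_id,
                    float(np.linalg.norm(pos - np.asarray(node.position))),
                    bool(flag),
                )
            )
    qc = pd.DataFrame(
        qc_rows, columns=["patient_id", "node_id", "displacement_mm", "clamped"]
    )
    return out, qc
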