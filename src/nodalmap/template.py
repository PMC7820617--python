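"""Template space and the synthetic nodal-level atlas.

The atlas is a labeled voxel map on a :class:`~nodalmap.grid.TemplateGrid`.
Levels are built from geometric primitives (capsule-shaped tubes along a
polyline, boxes, ellipsoids); paired levels are defined on the right side
and mirrored across the mid-sagittal plane, which makes left/right masks
bit-exact mirror images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid import TemplateGrid
from .records import NodeRecord

LEVEL_FAMILIES = (
    "external_iliac",
    "internal_iliac",
    "obturator",
    "common_iliac",
    "presacral",
    "perirectal",
    "inguinal",
    "prevesical",
    "paraaortic",
)

SIDES = ("left", "right", "none")

OUTSIDE = "outside"

#: Levels excluded from pelvic analyses (treated as extra-pelvic).
EXTRA_PELVIC = frozenset({"paraaortic"})

#: Vessel-hugging levels the dilation margin applies to by default.
VESSEL_LEVELS = frozenset(
    {"external_iliac", "internal_iliac", "obturator", "common_iliac", "presacral"}
)


@dataclass(frozen=True)
class LevelInfo:
    label: int
    name: str
    side: str
    consensus: bool

    def __post_init__(self) -> None:
        if self.name not in LEVEL_FAMILIES:
            raise ValueError(f"unknown level name {self.name!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.label <= 0:
            raise ValueError("level labels must be positive (0 is background)")


@dataclass(frozen=True)
class MarginSpec:
    """Isotropic expansion margin applied to a set of levels."""

    margin_mm: float = 7.0
    applies_to: frozenset[str] = VESSEL_LEVELS

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be >= 0")
        object.__setattr__(self, "applies_to", frozenset(self.applies_to))


@dataclass(frozen=True)
class LevelAtlas:
    """Labeled level map plus the level table and per-level volumes."""

    grid: TemplateGrid
    labels: np.ndarray
    table: tuple[LevelInfo, ...]

    def __post_init__(self) -> None:
        labels = np.ascontiguousarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("label map shape does not match grid")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "table", tuple(self.table))
        present = set(np.unique(labels)) - {0}
        listed = {info.label for info in self.table}
        if len(listed) != len(self.table):
            raise ValueError("duplicate labels in level table")
        if not present <= listed:
            raise ValueError(f"labels {sorted(present - listed)} missing from table")

    # -- lookups ---------------------------------------------------------------

    def info(self, label: int) -> LevelInfo:
        for entry in self.table:
            if entry.label == label:
                return entry
        raise KeyError(label)

    def label_of(self, name: str, side: str = "none") -> int:
        for entry in self.table:
            if entry.name == name and entry.side == side:
                return entry.label
        raise KeyError((name, side))

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def family_mask(self, name: str) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for entry in self.table:
            if entry.name == name:
                out |= self.labels == entry.label
        return out

    @property
    def volumes_cm3(self) -> dict[int, float]:
        """Per-label volume in cm³ (voxel count × voxel volume)."""
        counts = np.bincount(self.labels.ravel(), minlength=max((e.label for e in self.table), default=0) + 1)
        return {e.label: float(counts[e.label]) * self.grid.voxel_volume_cm3 for e in self.table}

    def family_volumes_cm3(self, names: Iterable[str] | None = None) -> dict[str, float]:
        vols = self.volumes_cm3
        names = tuple(names) if names is not None else LEVEL_FAMILIES
        out: dict[str, float] = {}
        for name in names:
            total = sum(vols[e.label] for e in self.table if e.name == name)
            if any(e.name == name for e in self.table):
                out[name] = total
        return out

    @property
    def consensus_labels(self) -> frozenset[int]:
        return frozenset(e.label for e in self.table if e.consensus)


# ---------------------------------------------------------------------------
# Primitive rasterization
# ---------------------------------------------------------------------------


def _bbox_mesh(grid: TemplateGrid, lo, hi):
    """Index slices and voxel-center submesh covering world box [lo, hi]."""
    lo_idx = np.maximum(np.floor(grid.world_to_index(np.asarray(lo, float))).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil(grid.world_to_index(np.asarray(hi, float))).astype(int) + 1,
        np.asarray(grid.shape),
    )
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
    coords = [grid.axis_coords(a)[slices[a]] for a in range(3)]
    return slices, np.meshgrid(*coords, indexing="ij")


def _raster_box(grid: TemplateGrid, center, half_size) -> np.ndarray:
    c, h = np.asarray(center, float), np.asarray(half_size, float)
    mask = np.zeros(grid.shape, dtype=bool)
    slices, (x, y, z) = _bbox_mesh(grid, c - h, c + h)
    mask[slices] = (
        (np.abs(x - c[0]) <= h[0])
        & (np.abs(y - c[1]) <= h[1])
        & (np.abs(z - c[2]) <= h[2])
    )
    return mask


def _raster_ellipsoid(grid: TemplateGrid, center, radii) -> np.ndarray:
    c, r = np.asarray(center, float), np.asarray(radii, float)
    if np.any(r <= 0):
        raise ValueError("ellipsoid radii must be > 0")
    mask = np.zeros(grid.shape, dtype=bool)
    slices, (x, y, z) = _bbox_mesh(grid, c - r, c + r)
    mask[slices] = (
        ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2
    ) <= 1.0
    return mask


def _raster_tube(grid: TemplateGrid, points, radius: float) -> np.ndarray:
    """Capsule of given radius around a polyline (union of segment capsules)."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("tube needs >= 2 polyline points")
    if radius <= 0:
        raise ValueError("tube radius must be > 0")
    mask = np.zeros(grid.shape, dtype=bool)
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - radius
        hi = np.maximum(a, b) + radius
        slices, (x, y, z) = _bbox_mesh(grid, lo, hi)
        vox = np.stack([x, y, z], axis=-1)
        ab = np.asarray(b, float) - np.asarray(a, float)
        denom = float(ab @ ab)
        ap = vox - np.asarray(a, float)
        t = np.clip((ap @ ab) / denom if denom > 0 else 0.0, 0.0, 1.0)
        closest = np.asarray(a, float) + t[..., None] * ab
        d2 = np.sum((vox - closest) ** 2, axis=-1)
        mask[slices] |= d2 <= radius * radius
    return mask


_RASTERIZERS = {"box": _raster_box, "ellipsoid": _raster_ellipsoid, "tube": _raster_tube}


def _rasterize(grid: TemplateGrid, primitive: Mapping) -> np.ndarray:
    kind = primitive["kind"]
    if kind not in _RASTERIZERS:
        raise ValueError(f"unknown primitive kind {kind!r}")
    params = {k: v for k, v in primitive.items() if k != "kind"}
    return _RASTERIZERS[kind](grid, **params)


# ---------------------------------------------------------------------------
# Default geometry
# ---------------------------------------------------------------------------


def default_template_config() -> dict:
    """Synthetic pelvic geometry on a 128x128x160 grid at 2 mm.

    Paired levels give the right-side primitive; the left side is the
    mid-sagittal mirror image.  Consensus membership marks the levels a
    nodal CTV is assumed to cover (perirectal, inguinal, prevesical and
    paraaortic are non-consensus).
    """
    return {
        "shape": [128, 128, 160],
        "spacing": [2.0, 2.0, 2.0],
        "origin": [0.0, 0.0, 0.0],
        "levels": [
            {
                "name": "external_iliac",
                "sided": True,
                "consensus": True,
                "primitive": {
                    "kind": "tube",
                    "points": [[92.0, 108.0, 196.0], [80.0, 96.0, 130.0]],
                    "radius": 8.0,
                },
            },
            {
                "name": "internal_iliac",
                "sided": True,
                "consensus": True,
                "primitive": {
                    "kind": "tube",
                    "points": [[98.0, 132.0, 196.0], [90.0, 158.0, 142.0]],
                    "radius": 7.5,
                },
            },
            {
                "name": "obturator",
                "sided": True,
                "consensus": True,
                "primitive": {
                    "kind": "tube",
                    "points": [[82.0, 122.0, 120.0], [88.0, 150.0, 100.0]],
                    "radius": 7.0,
                },
            },
            {
                "name": "common_iliac",
                "sided": True,
                "consensus": True,
                "primitive": {
                    "kind": "tube",
                    "points": [[116.0, 112.0, 258.0], [100.0, 116.0, 222.0]],
                    "radius": 9.0,
                },
            },
            {
                "name": "presacral",
                "sided": False,
                "consensus": True,
                "primitive": {
                    "kind": "box",
                    "center": [127.0, 172.0, 166.0],
                    "half_size": [12.0, 12.0, 26.0],
                },
            },
            {
                "name": "perirectal",
                "sided": True,
                "consensus": False,
                "primitive": {
                    "kind": "ellipsoid",
                    "center": [112.0, 170.0, 108.0],
                    "radii": [10.0, 15.0, 24.0],
                },
            },
            {
                "name": "inguinal",
                "sided": True,
                "consensus": False,
                "primitive": {
                    "kind": "ellipsoid",
                    "center": [78.0, 104.0, 80.0],
                    "radii": [10.0, 11.0, 18.0],
                },
            },
            {
                "name": "prevesical",
                "sided": True,
                "consensus": False,
                "primitive": {
                    "kind": "ellipsoid",
                    "center": [112.0, 92.0, 100.0],
                    "radii": [9.0, 8.0, 13.0],
                },
            },
            {
                "name": "paraaortic",
                "sided": True,
                "consensus": False,
                "primitive": {
                    "kind": "tube",
                    "points": [[119.0, 112.0, 310.0], [119.0, 112.0, 282.0]],
                    "radius": 7.0,
                },
            },
        ],
    }


def build_template(config: Mapping | None = None, seed: int = 0) -> tuple[TemplateGrid, LevelAtlas]:
    """Rasterize the configured level primitives into a LevelAtlas.

    Construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other pipeline stages.
    """
    cfg = dict(default_template_config() if config is None else config)
    grid = TemplateGrid(tuple(cfg["shape"]), tuple(cfg["spacing"]), tuple(cfg.get("origin", (0.0, 0.0, 0.0))))
    labels = np.zeros(grid.shape, dtype=np.int16)
    table: list[LevelInfo] = []
    owner: dict[int, str] = {}
    next_label = 1
    for level in cfg["levels"]:
        name = level["name"]
        consensus = bool(level.get("consensus", True))
        right = _rasterize(grid, level["primitive"])
        if level.get("sided", True):
            masks = [(right, "right"), (right[::-1, :, :], "left")]
        else:
            masks = [(right, "none")]
        for mask, side in masks:
            if not mask.any():
                raise ValueError(f"level {name!r} ({side}) rasterized to zero volume")
            collision = mask & (labels != 0)
            if collision.any():
                hit = int(labels[collision][0])
                raise ValueError(
                    f"level {name!r} ({side}) overlaps level {owner[hit]!r}"
                )
            labels[mask] = next_label
            table.append(LevelInfo(next_label, name, side, consensus))
            owner[next_label] = f"{name}/{side}"
            next_label += 1
    return grid, LevelAtlas(grid, labels, tuple(table))


# ---------------------------------------------------------------------------
# Margin expansion
# ---------------------------------------------------------------------------


def expand_levels(atlas: LevelAtlas, margin: MarginSpec) -> LevelAtlas:
    """Euclidean dilation of the selected levels by ``margin.margin_mm``.

    Every voxel is assigned to the nearest undilated level among those whose
    (possibly zero) margin reaches it; ties go to the lowest label id, so
    original level voxels are never reassigned.
    """
    if margin.margin_mm == 0:
        return atlas
    grid = atlas.grid
    sampling = grid.spacing
    best_dist = np.full(grid.shape, np.inf, dtype=np.float32)
    new_labels = np.zeros(grid.shape, dtype=atlas.labels.dtype)
    for entry in atlas.table:  # ascending label order => lowest label wins ties
        mask = atlas.mask(entry.label)
        reach = margin.margin_mm if entry.name in margin.applies_to else 0.0
        if reach == 0.0:
            new_labels[mask] = entry.label  # dist 0 always beats any other claim
            best_dist[mask] = 0.0
            continue
        # EDT restricted to the mask's bounding box padded by the reach
        pad = np.ceil(reach / np.asarray(sampling)).astype(int) + 1
        present = np.argwhere(mask)
        lo = np.maximum(present.min(axis=0) - pad, 0)
        hi = np.minimum(present.max(axis=0) + pad + 1, np.asarray(grid.shape))
        sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        dist = ndimage.distance_transform_edt(~mask[sub], sampling=sampling).astype(np.float32)
        dist[dist > reach] = np.inf
        claim = dist < best_dist[sub]
        new_labels[sub][claim] = entry.label
        best_dist[sub][claim] = dist[claim]
    return LevelAtlas(grid, new_labels, atlas.table)


# ---------------------------------------------------------------------------
# Point classification
# ---------------------------------------------------------------------------


def classify_points(points: np.ndarray, atlas: LevelAtlas) -> np.ndarray:
    """Label id of the voxel containing each point (0 = background/outside)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx, inside = atlas.grid.nearest_index(pts)
    labels = atlas.labels[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
    labels[~inside] = 0
    return labels


def classify_point(p, atlas: LevelAtlas) -> str:
    """Level family name at point ``p``, or ``"outside"``."""
    label = int(classify_points(np.asarray(p, dtype=float)[None, :], atlas)[0])
    return OUTSIDE if label == 0 else atlas.info(label).name


# ---------------------------------------------------------------------------
# Consensus coverage
# ---------------------------------------------------------------------------


def _pct(k: int, n: int) -> float:
    """Percentage, rounded half-up to one decimal place."""
    from decimal import ROUND_HALF_UP, Decimal

    if n == 0:
        raise ValueError("empty denominator")
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class CoverageReport:
    margin_mm: float
    n_patients: int
    uncovered_patients: tuple[str, ...]
    uncovered_fraction_pct: float
    per_level_uncovered: dict[str, int] = field(default_factory=dict)

    @property
    def n_uncovered(self) -> int:
        return len(self.uncovered_patients)


def consensus_coverage(
    nodes: Sequence[NodeRecord],
    atlas: LevelAtlas,
    margins: Sequence[MarginSpec] = (MarginSpec(0.0), MarginSpec(7.0), MarginSpec(10.0)),
    exclude_levels: frozenset[str] = EXTRA_PELVIC,
) -> dict[float, CoverageReport]:
    """Per-margin report of patients with >=1 node outside the consensus levels.

    Nodes in ``exclude_levels`` (paraaortic by default) are dropped before
    assessment; nodes must already be in template space.  Membership is
    inclusive: a node on a dilated boundary voxel counts as covered.
    """
    nodes = [n for n in nodes]
    if any(n.space != "template" for n in nodes):
        bad = sorted({n.patient_id for n in nodes if n.space != "template"})
        raise ValueError(f"nodes must be in template space (native: {bad})")
    reports: dict[float, CoverageReport] = {}
    for spec in margins:
        expanded = expand_levels(atlas, spec)
        excluded_labels = {
            e.label for e in expanded.table if e.name in exclude_levels
        }
        consensus = expanded.consensus_labels
        uncovered: dict[str, set[str]] = {}
        per_level: dict[str, int] = {}
        patients: set[str] = set()
        for node in nodes:
            label = int(classify_points(np.asarray(node.position)[None, :], expanded)[0])
            if label in excluded_labels:
                continue
            patients.add(node.patient_id)
            if label != 0 and label in consensus:
                continue
            where = OUTSIDE if label == 0 else expanded.info(label).name
            uncovered.setdefault(node.patient_id, set()).add(where)
            per_level[where] = per_level.get(where, 0) + 1
        n = len(patients)
        flagged = tuple(sorted(uncovered))
        reports[spec.margin_mm] = CoverageReport(
            margin_mm=spec.margin_mm,
            n_patients=n,
            uncovered_patients=flagged,
            uncovered_fraction_pct=_pct(len(flagged), n) if n else 0.0,
            per_level_uncovered=dict(sorted(per_level.items())),
        )
    return reports
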