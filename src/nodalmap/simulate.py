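"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: per-level
involvement weights, overdispersed per-patient node counts (median 2, hard
range 1-11), mostly-unilateral laterality, intra-patient spatial clustering
via an anchor level plus a fixed level-adjacency graph, a surgery covariate
with per-level probability multipliers, and one smooth displacement field
per patient linking template and native coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import nbinom

from .grid import TemplateGrid
from .mapping import (
    NATIVE_TO_TEMPLATE,
    TEMPLATE_TO_NATIVE,
    DisplacementField,
    apply_dvf,
)
from .records import NATIVE, TEMPLATE, NodeRecord
from .template import LevelAtlas

#: Default per-level anchor weights (marginal involvement targets).
DEFAULT_LEVEL_PROBS: dict[str, float] = {
    "external_iliac": 0.373,
    "paraaortic": 0.320,
    "internal_iliac": 0.253,
    "perirectal": 0.253,
    "common_iliac": 0.227,
    "obturator": 0.200,
    "presacral": 0.107,
    "inguinal": 0.040,
    "prevesical": 0.040,
}

#: Fixed family-level adjacency used for node spillover around the anchor.
ADJACENCY: dict[str, tuple[str, ...]] = {
    "external_iliac": ("obturator", "common_iliac"),
    "obturator": ("external_iliac", "internal_iliac"),
    "internal_iliac": ("obturator", "perirectal", "presacral"),
    "perirectal": ("internal_iliac",),
    "presacral": ("internal_iliac",),
    "common_iliac": ("external_iliac", "paraaortic"),
    "paraaortic": ("common_iliac",),
    "inguinal": (),
    "prevesical": (),
}


@dataclass(frozen=True)
class NodeCountSpec:
    """Zero-truncated negative binomial, hard-truncated at ``max_nodes``.

    Defaults give median 2 and P(X > 11) < 0.01 before hard truncation.
    """

    r: float = 1.5
    p: float = 0.4
    max_nodes: int = 11

    def pmf(self) -> np.ndarray:
        """Probability of 1..max_nodes counts."""
        raw = nbinom.pmf(np.arange(1, self.max_nodes + 1), self.r, self.p)
        return raw / raw.sum()


@dataclass(frozen=True)
class GenParams:
    n_patients: int = 75
    level_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_PROBS)
    )
    node_count: NodeCountSpec = field(default_factory=NodeCountSpec)
    cluster_rho: float = 0.5
    unilateral_prob: float = 0.768
    surgery_prob: float = 55 / 75
    surgery_effects: Mapping[str, float] = field(
        default_factory=lambda: {"external_iliac:right": 0.25}
    )
    dvf_sd_mm: float = 3.0
    dvf_grid_mm: float = 50.0
    dvf_field_spacing_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.level_probs:
            raise ValueError("level_probs must not be empty")
        for name, p in self.level_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"level_probs[{name!r}] = {p} outside [0, 1]")
        for name, val in (
            ("cluster_rho", self.cluster_rho),
            ("unilateral_prob", self.unilateral_prob),
            ("surgery_prob", self.surgery_prob),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} = {val} outside [0, 1]")
        if self.dvf_sd_mm < 0:
            raise ValueError("dvf_sd_mm must be >= 0")
        if self.dvf_grid_mm <= 0 or self.dvf_field_spacing_mm <= 0:
            raise ValueError("DVF spacings must be > 0")


@dataclass
class PatientCase:
    patient_id: str
    surgery: bool
    anchor: str
    preferred_side: str
    unilateral: bool
    nodes_template: list[NodeRecord]
    nodes_native: list[NodeRecord]
    dvf_ref: str
    dvf_forward: DisplacementField | None = None
    dvf_inverse: DisplacementField | None = None

    @property
    def nodes(self) -> list[NodeRecord]:
        return self.nodes_template


# ---------------------------------------------------------------------------
# Displacement field synthesis
# ---------------------------------------------------------------------------


def make_dvf(
    grid: TemplateGrid,
    sd_mm: float,
    control_spacing_mm: float,
    seed: int,
    tol_mm: float = 0.1,
    max_iter: int = 100,
) -> tuple[DisplacementField, DisplacementField]:
    """Smooth random displacement field and its numerical inverse.

    Control-point displacements are iid Gaussian(0, sd_mm) per axis on a
    coarse lattice and densified to ``grid`` by trilinear interpolation.
    The inverse is obtained by fixed-point iteration on the grid's voxel
    centers to a residual below ``tol_mm``.

    Returns ``(forward, inverse)`` with directions template->native and
    native->template respectively.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    if control_spacing_mm <= 0:
        raise ValueError("control_spacing_mm must be > 0")
    if sd_mm == 0.0:
        zeros = np.zeros((*grid.shape, 3))
        return (
            DisplacementField(grid, zeros, TEMPLATE_TO_NATIVE),
            DisplacementField(grid, zeros.copy(), NATIVE_TO_TEMPLATE),
        )
    rng = np.random.default_rng(seed)
    # control lattice extends two nodes beyond the grid so cubic interpolation
    # covers the full extent
    axes = []
    for a in range(3):
        lo, hi = grid.extent_mm[a]
        n = int(np.ceil((hi - lo) / control_spacing_mm)) + 5
        axes.append(lo - 2 * control_spacing_mm + control_spacing_mm * np.arange(n))
    control = rng.normal(0.0, sd_mm, size=(len(axes[0]), len(axes[1]), len(axes[2]), 3))
    # mild lattice-scale smoothing keeps the inverse field representable on
    # the output grid (raw iid control noise makes the 0.2 mm round-trip
    # bound unreachable at practical field resolutions); renormalize by the
    # kernel power so stationary-region control displacements keep SD sd_mm
    smooth_sigma = 1.0
    control = ndimage.gaussian_filter(control, sigma=(smooth_sigma,) * 3 + (0.0,))
    impulse = np.zeros(2 * int(4 * smooth_sigma) + 1)
    impulse[len(impulse) // 2] = 1.0
    w = ndimage.gaussian_filter1d(impulse, smooth_sigma)
    control /= float(np.sum(w**2)) ** 1.5
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(tuple(axes), control, method="cubic")
    x, y, z = grid.voxel_center_mesh()
    centers = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    forward_vec = interp(centers).reshape(*grid.shape, 3)
    forward = DisplacementField(grid, forward_vec, TEMPLATE_TO_NATIVE)

    fwd_interp = forward.interpolator()
    lo = np.array([e[0] for e in grid.extent_mm])
    hi = np.array([e[1] for e in grid.extent_mm])
    inv = np.zeros_like(centers)
    residual = np.inf
    for _ in range(max_iter):
        probe = np.clip(centers + inv, lo, hi)
        pull = fwd_interp(probe)
        residual = float(np.max(np.linalg.norm(inv + pull, axis=1)))
        inv = -pull
        if residual < tol_mm:
            break
    else:
        raise RuntimeError(
            f"DVF inversion did not converge: max residual {residual:.3f} mm "
            f"after {max_iter} iterations"
        )
    inverse = DisplacementField(
        grid, inv.reshape(*grid.shape, 3), NATIVE_TO_TEMPLATE
    )
    return forward, inverse


def _dvf_grid(template: TemplateGrid, spacing_mm: float) -> TemplateGrid:
    """Coarser grid over (at least) the template extent for storing DVFs."""
    shape = []
    for a in range(3):
        lo, hi = template.extent_mm[a]
        shape.append(int(np.ceil((hi - lo) / spacing_mm)) + 1)
    return TemplateGrid(tuple(shape), (spacing_mm,) * 3, template.origin)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _anchor_weights(
    params: GenParams, atlas: LevelAtlas, surgery: bool, side: str
) -> tuple[list[str], np.ndarray]:
    names = [n for n in params.level_probs if params.level_probs[n] > 0]
    if not names:
        raise ValueError("all level_probs are zero")
    weights = np.array([params.level_probs[n] for n in names], dtype=float)
    if surgery:
        for key, mult in params.surgery_effects.items():
            name, _, eff_side = key.partition(":")
            if name in names and (not eff_side or eff_side == side):
                weights[names.index(name)] *= mult
    return names, weights / weights.sum()


def _level_sides(atlas: LevelAtlas, name: str) -> tuple[str, ...]:
    return tuple(e.side for e in atlas.table if e.name == name)


class _VoxelCache:
    """Lazy per-label voxel index lists for uniform in-mask sampling."""

    def __init__(self, atlas: LevelAtlas) -> None:
        self.atlas = atlas
        self._voxels: dict[int, np.ndarray] = {}

    def sample(self, name: str, side: str, rng: np.random.Generator) -> np.ndarray:
        label = self.atlas.label_of(name, side)
        voxels = self._voxels.get(label)
        if voxels is None:
            voxels = np.argwhere(self.atlas.labels == label)
            self._voxels[label] = voxels
        if len(voxels) == 0:
            raise ValueError(f"level {name!r} ({side}) has zero volume")
        pick = voxels[rng.integers(len(voxels))]
        jitter = rng.uniform(-0.49, 0.49, size=3) * np.asarray(self.atlas.grid.spacing)
        return self.atlas.grid.index_to_world(pick) + jitter


def _other(side: str) -> str:
    return {"left": "right", "right": "left"}.get(side, side)


def _pick_level(
    anchor: str, rho: float, rng: np.random.Generator, available: set[str]
) -> str:
    if rng.uniform() < rho:
        return anchor
    neighbors = [n for n in ADJACENCY.get(anchor, ()) if n in available]
    if not neighbors:
        return anchor
    return neighbors[rng.integers(len(neighbors))]


def sample_cohort(params: GenParams, atlas: LevelAtlas) -> list[PatientCase]:
    """Draw a reproducible synthetic cohort.

    One master seed spawns independent per-patient streams, so patient k is
    identical regardless of cohort size.
    """
    available = {e.name for e in atlas.table}
    missing = set(params.level_probs) - available
    if missing:
        raise ValueError(f"level_probs refer to levels absent from atlas: {sorted(missing)}")
    count_pmf = params.node_count.pmf()
    counts_support = np.arange(1, params.node_count.max_nodes + 1)
    master = np.random.SeedSequence(params.seed)
    streams = master.spawn(params.n_patients)
    cohort: list[PatientCase] = []
    cache = _VoxelCache(atlas)
    pad = len(str(params.n_patients))
    for k, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"P{k + 1:0{pad}d}"
        surgery = bool(rng.uniform() < params.surgery_prob)
        side = "left" if rng.uniform() < 0.5 else "right"
        unilateral = bool(rng.uniform() < params.unilateral_prob)
        names, weights = _anchor_weights(params, atlas, surgery, side)
        anchor = names[rng.choice(len(names), p=weights)]
        n_nodes = int(rng.choice(counts_support, p=count_pmf))
        if not unilateral:
            n_nodes = max(n_nodes, 2)

        levels: list[tuple[str, str]] = []
        for j in range(n_nodes):
            fam = _pick_level(anchor, params.cluster_rho, rng, available)
            sides = _level_sides(atlas, fam)
            node_side = side if side in sides else "none"
            levels.append((fam, node_side))
        if not unilateral:
            # force at least one sided node on the opposite side
            sided_idx = [i for i, (_, s) in enumerate(levels) if s in ("left", "right")]
            if sided_idx:
                i = sided_idx[-1]
                fam, s = levels[i]
                levels[i] = (fam, _other(s))
            else:  # anchor chain landed only on unsided levels; add a sided one
                fam = anchor if "none" not in _level_sides(atlas, anchor) else "internal_iliac"
                if fam in available:
                    levels[-1] = (fam, _other(side))

        nodes_template: list[NodeRecord] = []
        for j, (fam, node_side) in enumerate(levels):
            pos = cache.sample(fam, node_side, rng)
            nodes_template.append(
                NodeRecord(
                    patient_id=pid,
                    node_id=f"{pid}_N{j + 1}",
                    position=tuple(float(c) for c in pos),
                    space=TEMPLATE,
                    level=fam,
                    side=node_side,
                    surgery=surgery,
                )
            )

        dvf_seed = int(rng.integers(2**31 - 1))
        field_grid = _dvf_grid(atlas.grid, params.dvf_field_spacing_mm)
        forward, inverse = make_dvf(
            field_grid, params.dvf_sd_mm, params.dvf_grid_mm, dvf_seed
        )
        pts = np.array([n.position for n in nodes_template], dtype=float)
        native_pts, _ = apply_dvf(pts, forward)
        nodes_native = [
            n.with_position(p, NATIVE) for n, p in zip(nodes_template, native_pts)
        ]
        cohort.append(
            PatientCase(
                patient_id=pid,
                surgery=surgery,
                anchor=anchor,
                preferred_side=side,
                unilateral=unilateral,
                nodes_template=nodes_template,
                nodes_native=nodes_native,
                dvf_ref=f"dvf_{pid}",
                dvf_forward=forward,
                dvf_inverse=inverse,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Ground truth summary (test support)
# ---------------------------------------------------------------------------


def ground_truth_table(
    cohort: Sequence[PatientCase], params: GenParams | None = None
) -> dict:
    """Generating-parameter summary used by parameter-recovery tests."""
    if not cohort:
        raise ValueError("empty cohort")
    anchor_counts: dict[str, int] = {}
    involvement_counts: dict[str, int] = {}
    node_counts: dict[str, int] = {}
    total_nodes = 0
    for case in cohort:
        anchor_counts[case.anchor] = anchor_counts.get(case.anchor, 0) + 1
        seen = {n.level for n in case.nodes_template}
        for fam in seen:
            involvement_counts[fam] = involvement_counts.get(fam, 0) + 1
        node_counts[case.patient_id] = len(case.nodes_template)
        total_nodes += len(case.nodes_template)
    n = len(cohort)
    out = {
        "n_patients": n,
        "n_nodes": total_nodes,
        "anchor_freq": {k: v / n for k, v in sorted(anchor_counts.items())},
        "involvement_freq": {k: v / n for k, v in sorted(involvement_counts.items())},
        "node_counts": node_counts,
        "unilateral_frac": sum(c.unilateral for c in cohort) / n,
        "surgery_frac": sum(c.surgery for c in cohort) / n,
    }
    if params is not None:
        names = [m for m in params.level_probs if params.level_probs[m] > 0]
        w = np.array([params.level_probs[m] for m in names], dtype=float)
        out["generating"] = {
            "cluster_rho": params.cluster_rho,
            "unilateral_prob": params.unilateral_prob,
            "anchor_probs": dict(zip(names, w / w.sum())),
            "level_probs": dict(params.level_probs),
        }
    return out
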