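"""Intra-patient vs cohort-level pairwise distance statistics.

Extra-pelvic (paraaortic) nodes are excluded before any distance is
computed, matching the pelvic scope of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy import stats

from .records import NodeRecord
from .template import EXTRA_PELVIC

INTRA_NATIVE = "intra_patient_native"
INTRA_TEMPLATE = "intra_patient_template"
COHORT_TEMPLATE = "cohort_template"
SCOPES = (INTRA_NATIVE, INTRA_TEMPLATE, COHORT_TEMPLATE)

POOLED_T = "pooled_t"
PATIENT_BOOTSTRAP = "patient_bootstrap"


@dataclass(frozen=True)
class DistanceSet:
    distances: np.ndarray  # mm
    scope: str
    n_points: int
    n_patients: int

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        object.__setattr__(self, "distances", d)

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.distances)) if self.distances.size else float("nan")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    method: str
    n_adjust: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")


def _pelvic(nodes: Sequence[NodeRecord]) -> list[NodeRecord]:
    return [n for n in nodes if n.level not in EXTRA_PELVIC]


def _by_patient(nodes: Sequence[NodeRecord]) -> dict[str, list[NodeRecord]]:
    out: dict[str, list[NodeRecord]] = {}
    for n in nodes:
        out.setdefault(n.patient_id, []).append(n)
    return out


def intra_patient_distances(nodes: Sequence[NodeRecord], space: str) -> DistanceSet:
    """All within-patient unordered pairwise distances, concatenated.

    ``space`` selects which coordinates the records must carry
    ("native" or "template"); single-node patients contribute nothing.
    """
    if space not in ("native", "template"):
        raise ValueError(f"unknown space tag {space!r}")
    pelvic = [n for n in _pelvic(nodes) if n.space == space]
    groups = _by_patient(pelvic)
    chunks = []
    for patient_nodes in groups.values():
        if len(patient_nodes) >= 2:
            pts = np.array([n.position for n in patient_nodes], dtype=float)
            chunks.append(pdist(pts))
    dists = np.concatenate(chunks) if chunks else np.empty(0)
    scope = INTRA_NATIVE if space == "native" else INTRA_TEMPLATE
    return DistanceSet(dists, scope, n_points=len(pelvic), n_patients=len(groups))


def cohort_distances(nodes: Sequence[NodeRecord]) -> DistanceSet:
    """All n(n-1)/2 pairwise distances across the mapped cohort."""
    pelvic = _pelvic(nodes)
    if len(pelvic) < 2:
        raise ValueError("need >= 2 pelvic nodes for cohort distances")
    if any(n.space != "template" for n in pelvic):
        raise ValueError("cohort distances require template-space nodes")
    pts = np.array([n.position for n in pelvic], dtype=float)
    return DistanceSet(
        pdist(pts),
        COHORT_TEMPLATE,
        n_points=len(pelvic),
        n_patients=len({n.patient_id for n in pelvic}),
    )


def compare_means(
    a: DistanceSet,
    b: DistanceSet,
    method: str = POOLED_T,
    nodes: Sequence[NodeRecord] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TestResult:
    """Compare mean distances of two sets.

    ``pooled_t`` runs a Welch t-test directly on the two distance lists — a
    naive analysis that ignores the dependence between pairwise distances.
    ``patient_bootstrap`` resamples patients with replacement (requires the
    template-space ``nodes``), recomputes both means per replicate, and
    derives p/CI from the bootstrap distribution of the mean difference.
    """
    if a.distances.size == 0 or b.distances.size == 0:
        raise ValueError("empty distance set")
    diff = a.mean_mm - b.mean_mm
    if method == POOLED_T:
        res = stats.ttest_ind(a.distances, b.distances, equal_var=False)
        ci = res.confidence_interval(1 - alpha)
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            method=POOLED_T,
        )
    if method == PATIENT_BOOTSTRAP:
        if nodes is None:
            raise ValueError("patient_bootstrap requires the node records")
        groups = list(_by_patient(_pelvic(nodes)).values())
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_boot)
        for b_i in range(n_boot):
            pick = rng.integers(len(groups), size=len(groups))
            intra_chunks = []
            pts_all = []
            for j, g_idx in enumerate(pick):
                pts = np.array([n.position for n in groups[g_idx]], dtype=float)
                # re-tag so duplicated patients stay distinct
                if len(pts) >= 2:
                    intra_chunks.append(pdist(pts))
                pts_all.append(pts)
            pooled = np.concatenate(pts_all)
            intra = (
                np.concatenate(intra_chunks) if intra_chunks else np.array([np.nan])
            )
            diffs[b_i] = np.mean(intra) - np.mean(pdist(pooled))
        diffs = diffs[np.isfinite(diffs)]
        if diffs.size == 0:
            raise ValueError("bootstrap produced no valid replicates")
        # add-one correction avoids a degenerate p of exactly 0
        n_ge = int(np.sum(diffs >= 0))
        n_le = int(np.sum(diffs <= 0))
        p = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (diffs.size + 1))
        lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
        return TestResult(
            statistic=float(diff),
            p_value=float(p),
            ci_low=float(lo),
            ci_high=float(hi),
            method=PATIENT_BOOTSTRAP,
        )
    raise ValueError(f"unknown method {method!r}")


def max_intra_distance_quantiles(
    nodes: Sequence[NodeRecord], space: str = "template"
) -> tuple[float, float, float]:
    """(median, 75th, 95th percentile) of the per-patient maximum pairwise
    distance, linear-interpolation quantile convention, in mm."""
    pelvic = [n for n in _pelvic(nodes) if n.space == space]
    maxima = []
    for patient_nodes in _by_patient(pelvic).values():
        if len(patient_nodes) >= 2:
            pts = np.array([n.position for n in patient_nodes], dtype=float)
            maxima.append(float(pdist(pts).max()))
    if not maxima:
        raise ValueError("no patient has >= 2 pelvic nodes")
    med, q75, q95 = np.quantile(maxima, [0.5, 0.75, 0.95], method="linear")
    return float(med), float(q75), float(q95)
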