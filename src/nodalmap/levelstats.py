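"""Level-wise involvement statistics.

Binary involvement frequencies (combined and side-split), Fisher exact
subgroup contrasts with Bonferroni adjustment, per-patient relative level
proportions normalized by level volume against a homogeneous-distribution
reference, and BCa bootstrap confidence intervals / one-sample tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr, ndtri

from .distances import TestResult
from .records import NodeRecord
from .template import LevelAtlas

#: Fig-7-style default scope: consensus (NRG-like) levels plus perirectal.
def default_considered_levels(atlas: LevelAtlas) -> tuple[str, ...]:
    names = []
    for entry in atlas.table:
        if (entry.consensus or entry.name == "perirectal") and entry.name not in names:
            names.append(entry.name)
    return tuple(names)


def round_pct(k: int, n: int) -> float:
    """Percentage rounded half-up to one decimal (report convention)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# Binary involvement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InvolvementTable:
    n_patients: int
    combined: pd.DataFrame  # region, count, pct
    by_side: pd.DataFrame  # region, side, count, pct

    def count(self, region: str, side: str | None = None) -> int:
        if side is None:
            row = self.combined[self.combined.region == region]
        else:
            row = self.by_side[
                (self.by_side.region == region) & (self.by_side.side == side)
            ]
        if row.empty:
            raise KeyError((region, side))
        return int(row["count"].iloc[0])

    def pct(self, region: str, side: str | None = None) -> float:
        if side is None:
            row = self.combined[self.combined.region == region]
        else:
            row = self.by_side[
                (self.by_side.region == region) & (self.by_side.side == side)
            ]
        if row.empty:
            raise KeyError((region, side))
        return float(row["pct"].iloc[0])


def binary_involvement(
    nodes: Sequence[NodeRecord],
    n_patients: int | None = None,
    regions: Iterable[str] | None = None,
) -> InvolvementTable:
    """Patients with >=1 node per region, as counts and percentages.

    ``n_patients`` sets the denominator (defaults to the number of distinct
    patients among ``nodes``); pass the full cohort size when some patients
    contribute no classified nodes.
    """
    if len(nodes) == 0:
        raise ValueError("empty cohort")
    patients = sorted({n.patient_id for n in nodes})
    total = n_patients if n_patients is not None else len(patients)
    if total < len(patients):
        raise ValueError("n_patients smaller than the number of distinct patients")
    if regions is None:
        seen: list[str] = []
        for n in nodes:
            if n.level not in seen and n.level != "outside":
                seen.append(n.level)
        regions = seen
    regions = list(regions)
    combined_rows = []
    side_rows = []
    for region in regions:
        involved = {n.patient_id for n in nodes if n.level == region}
        combined_rows.append((region, len(involved), round_pct(len(involved), total)))
        for side in ("left", "right"):
            inv_side = {
                n.patient_id for n in nodes if n.level == region and n.side == side
            }
            side_rows.append((region, side, len(inv_side), round_pct(len(inv_side), total)))
    return InvolvementTable(
        n_patients=total,
        combined=pd.DataFrame(combined_rows, columns=["region", "count", "pct"]),
        by_side=pd.DataFrame(side_rows, columns=["region", "side", "count", "pct"]),
    )


# ---------------------------------------------------------------------------
# Fisher exact / Bonferroni
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    The two-sided p sums, over all tables with the observed margins, the
    probabilities not exceeding that of the observed table
    (minimum-likelihood rule), evaluated in log space.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be > 0")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)

    def log_pmf(k):
        return (
            gammaln(r1 + 1)
            - gammaln(k + 1)
            - gammaln(r1 - k + 1)
            + gammaln(n - r1 + 1)
            - gammaln(c1 - k + 1)
            - gammaln(n - r1 - c1 + k + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    logs = log_pmf(ks)
    obs = log_pmf(np.array([a]))[0]
    # relative tolerance guards against ties lost to floating point
    keep = logs <= obs + 1e-12 * abs(obs) + 1e-12
    p = float(np.exp(logs[keep]).sum())
    p = min(1.0, p)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(
        statistic=float(odds),
        p_value=p,
        ci_low=float("nan"),
        ci_high=float("nan"),
        method="fisher_exact",
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """p_adj = min(1, m * p) with m = number of comparisons."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def surgery_contrasts(
    nodes: Sequence[NodeRecord],
    surgery_by_patient: Mapping[str, bool],
    rows: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fisher tests of involvement vs surgery per (region, side) row,
    Bonferroni-adjusted over the listed rows."""
    patients = sorted(surgery_by_patient)
    if rows is None:
        sided = []
        for n in nodes:
            key = (n.level, n.side)
            if n.side in ("left", "right") and key not in sided:
                sided.append(key)
        unsided = sorted({n.level for n in nodes if n.side == "none" and n.level != "outside"})
        rows = sorted(sided) + [(name, "none") for name in unsided]
    results = []
    for region, side in rows:
        involved = {
            n.patient_id
            for n in nodes
            if n.level == region and (side == "none" or n.side == side)
        }
        a = sum(1 for p in patients if not surgery_by_patient[p] and p in involved)
        b = sum(1 for p in patients if not surgery_by_patient[p] and p not in involved)
        c = sum(1 for p in patients if surgery_by_patient[p] and p in involved)
        d = sum(1 for p in patients if surgery_by_patient[p] and p not in involved)
        res = fisher_exact_2x2([[a, b], [c, d]])
        results.append((region, side, a, b, c, d, res.p_value))
    frame = pd.DataFrame(
        results,
        columns=["region", "side", "no_surg_inv", "no_surg_not", "surg_inv", "surg_not", "p"],
    )
    frame["p_adj"] = bonferroni(frame["p"].tolist())
    frame["n_adjust"] = len(frame)
    return frame


# ---------------------------------------------------------------------------
# Relative proportions / volume normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionProfile:
    patient_id: str
    r: dict[str, float]


def relative_proportions(
    nodes: Sequence[NodeRecord],
    considered_levels: Sequence[str],
) -> tuple[list[ProportionProfile], list[str]]:
    """Per-patient share of counted nodes per considered level.

    Returns the profiles plus the ids of patients excluded for having no
    node in any considered level.
    """
    if not considered_levels:
        raise ValueError("considered_levels must be nonempty")
    considered = list(considered_levels)
    by_patient: dict[str, list[NodeRecord]] = {}
    for n in nodes:
        by_patient.setdefault(n.patient_id, []).append(n)
    profiles = []
    dropped = []
    for pid in sorted(by_patient):
        counted = [n for n in by_patient[pid] if n.level in considered]
        if not counted:
            dropped.append(pid)
            continue
        total = len(counted)
        r = {
            lvl: sum(1 for n in counted if n.level == lvl) / total
            for lvl in considered
        }
        profiles.append(ProportionProfile(pid, r))
    return profiles, dropped


def volume_normalized_means(
    profiles: Sequence[ProportionProfile],
    volumes_cm3: Mapping[str, float],
    considered_levels: Sequence[str],
) -> tuple[dict[str, float], float]:
    """Mean relative proportion per cm³ of level volume, in ‰/cm³.

    value_l = 1000 * mean_p(r_pl) / V_l.  The homogeneous-distribution
    reference 1000/ΣV is identical for every level.
    """
    if not profiles:
        raise ValueError("no proportion profiles")
    for lvl in considered_levels:
        if volumes_cm3.get(lvl, 0.0) <= 0:
            raise ValueError(f"level {lvl!r} has nonpositive volume")
    total_volume = sum(volumes_cm3[lvl] for lvl in considered_levels)
    values = {}
    for lvl in considered_levels:
        mean_r = float(np.mean([p.r.get(lvl, 0.0) for p in profiles]))
        values[lvl] = 1000.0 * mean_r / volumes_cm3[lvl]
    reference = 1000.0 / total_volume
    return values, reference


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapSpec:
    B: int = 10_000
    method: str = "BCa"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method != "BCa":
            raise ValueError("only BCa bootstrapping is implemented")


def _bca_params(sample: np.ndarray, boot_means: np.ndarray) -> tuple[float, float]:
    """Bias-correction z0 and jackknife acceleration a for the mean."""
    obs = sample.mean()
    prop = (np.sum(boot_means < obs) + 0.5 * np.sum(boot_means == obs)) / boot_means.size
    prop = min(max(prop, 1.0 / (2 * boot_means.size)), 1 - 1.0 / (2 * boot_means.size))
    z0 = float(ndtri(prop))
    n = sample.size
    jack = (sample.sum() - sample) / (n - 1)
    dev = jack.mean() - jack
    denom = float(np.sum(dev**2)) ** 1.5
    a = 0.0 if denom == 0 else float(np.sum(dev**3)) / (6.0 * denom)
    return z0, a


def _bca_interval(
    boot_means: np.ndarray, z0: float, a: float, alpha: float
) -> tuple[float, float]:
    out = []
    for z in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        out.append(float(np.quantile(boot_means, ndtr(adj))))
    return out[0], out[1]


def _boot_means(sample: np.ndarray, spec: BootstrapSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    n = sample.size
    idx = rng.integers(n, size=(spec.B, n))
    return sample[idx].mean(axis=1)


def bca_ci(sample: Sequence[float], spec: BootstrapSpec) -> tuple[float, float]:
    """BCa confidence interval for the mean at level 1 - spec.alpha."""
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if arr.size < 2 or np.ptp(arr) == 0.0:
        return float(arr[0]), float(arr[0])
    boot = _boot_means(arr, spec)
    z0, a = _bca_params(arr, boot)
    return _bca_interval(boot, z0, a, spec.alpha)


def bootstrap_mean_test(
    sample: Sequence[float], mu0: float, spec: BootstrapSpec
) -> TestResult:
    """Two-sided one-sample test of mean == mu0 by BCa interval inversion.

    p is the smallest alpha on a 10^-3 grid at which mu0 falls outside the
    BCa (1 - alpha) interval built from one shared replicate set; p = 1 if
    mu0 is inside at every grid point.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    lo_ci, hi_ci = bca_ci(arr, spec)
    if arr.size < 2 or np.ptp(arr) == 0.0:
        p = 1.0 if arr[0] == mu0 else 0.001
        return TestResult(float(arr.mean() - mu0), p, lo_ci, hi_ci, "bootstrap_mean_test")
    boot = np.sort(_boot_means(arr, spec))
    z0, a = _bca_params(arr, boot)

    def outside(alpha: float) -> bool:
        lo, hi = _bca_interval(boot, z0, a, alpha)
        return not (lo <= mu0 <= hi)

    # {alpha : mu0 outside} is an up-set, so bisect the 10^-3 grid for its
    # smallest element
    grid = np.arange(1, 1000)
    if not outside(grid[-1] / 1000.0):
        p = 1.0
    elif outside(grid[0] / 1000.0):
        p = 0.001
    else:
        lo_i, hi_i = 0, len(grid) - 1  # inside at lo_i, outside at hi_i
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if outside(grid[mid] / 1000.0):
                hi_i = mid
            else:
                lo_i = mid
        p = float(grid[hi_i]) / 1000.0
    return TestResult(
        statistic=float(arr.mean() - mu0),
        p_value=p,
        ci_low=lo_ci,
        ci_high=hi_ci,
        method="bootstrap_mean_test",
    )
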