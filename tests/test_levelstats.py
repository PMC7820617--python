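import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import bootstrap as scipy_bootstrap

from nodalmap.levelstats import (
    BootstrapSpec,
    ProportionProfile,
    bca_ci,
    binary_involvement,
    bonferroni,
    bootstrap_mean_test,
    fisher_exact_2x2,
    relative_proportions,
    round_pct,
    surgery_contrasts,
    volume_normalized_means,
)
from nodalmap.records import NodeRecord


def _node(pid, level, side="right", nid=None):
    return NodeRecord(
        pid, nid or f"{pid}_{level}_{side}", (1.0, 2.0, 3.0), level=level, side=side
    )


def _fisher_oracle(a, b, c, d):
    """Exact rational two-sided p by exhaustive hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    return sum(p for p in pmf.values() if p <= pmf[a])


class TestFisherExact:
    def test_printed_surgery_contrast(self):
        res = fisher_exact_2x2([[9, 11], [6, 49]])
        assert round(res.p_value, 3) == 0.002

    def test_no_association_possible(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]).p_value == 1.0

    def test_exact_fraction_example(self):
        res = fisher_exact_2x2([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(float(Fraction(34, 70)), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(250):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            if a + b + c + d == 0:
                continue
            got = fisher_exact_2x2([[a, b], [c, d]]).p_value
            assert got == pytest.approx(float(_fisher_oracle(a, b, c, d)), abs=1e-11)


class TestBonferroni:
    def test_printed_example(self):
        # 0.002444... within the 11 Table-3-style comparisons
        p = fisher_exact_2x2([[9, 11], [6, 49]]).p_value
        adj = bonferroni([p] + [1.0] * 10)[0]
        assert adj == pytest.approx(11 * p)

    def test_capped_at_one(self):
        assert bonferroni([0.2] * 11)[0] == 1.0

    def test_single_comparison_identity(self):
        assert bonferroni([0.37]) == [0.37]

    def test_monotone(self):
        ps = [0.001, 0.01, 0.04, 0.2]
        adj = bonferroni(ps)
        assert all(x <= y for x, y in zip(adj, adj[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestBinaryInvolvement:
    def test_28_of_75_is_37_3(self):
        nodes = [_node(f"P{k}", "external_iliac") for k in range(28)]
        nodes += [_node(f"Q{k}", "obturator") for k in range(47)]
        table = binary_involvement(nodes, n_patients=75)
        assert table.count("external_iliac") == 28
        assert table.pct("external_iliac") == 37.3

    def test_single_patient_single_node(self):
        table = binary_involvement([_node("P1", "obturator", "left")])
        assert table.pct("obturator") == 100.0
        assert table.pct("obturator", "left") == 100.0
        assert table.pct("obturator", "right") == 0.0

    def test_matches_per_patient_scan(self, rng):
        levels = ["external_iliac", "obturator", "perirectal"]
        nodes = []
        for p in range(40):
            for _ in range(int(rng.integers(1, 5))):
                nodes.append(
                    _node(
                        f"P{p:02d}",
                        levels[rng.integers(3)],
                        ("left", "right")[rng.integers(2)],
                        nid=f"P{p}_{rng.integers(10**6)}",
                    )
                )
        table = binary_involvement(nodes)
        for level in levels:
            expected = len({n.patient_id for n in nodes if n.level == level})
            assert table.count(level) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binary_involvement([])

    def test_half_up_rounding(self):
        # 26/75 = 34.666... -> 34.7 ; 5/75 = 6.666... -> 6.7
        assert round_pct(26, 75) == 34.7
        assert round_pct(5, 75) == 6.7
        assert round_pct(1, 16) == 6.3  # 6.25 rounds half-up to 6.3


class TestSurgeryContrasts:
    def test_reconstructed_table3_row(self):
        surgery = {f"S{k}": True for k in range(55)} | {
            f"N{k}": False for k in range(20)
        }
        nodes = [_node(f"N{k}", "external_iliac", "right") for k in range(9)]
        nodes += [_node(f"S{k}", "external_iliac", "right") for k in range(6)]
        rows = [("external_iliac", "right")] + [("obturator", "left")] * 10
        frame = surgery_contrasts(nodes, surgery, rows=rows)
        row = frame.iloc[0]
        assert (row.no_surg_inv, row.no_surg_not) == (9, 11)
        assert (row.surg_inv, row.surg_not) == (6, 49)
        assert round(row.p, 3) == 0.002
        assert row.n_adjust == 11


class TestRelativeProportions:
    CONSIDERED = ["external_iliac", "obturator", "internal_iliac"]

    def test_two_thirds_one_third(self):
        nodes = [
            _node("P1", "external_iliac", nid="a"),
            _node("P1", "external_iliac", nid="b"),
            _node("P1", "obturator", nid="c"),
        ]
        profiles, dropped = relative_proportions(nodes, self.CONSIDERED)
        assert dropped == []
        assert profiles[0].r == pytest.approx(
            {"external_iliac": 2 / 3, "obturator": 1 / 3, "internal_iliac": 0.0}
        )

    def test_single_node_patients_are_indicators(self, rng):
        nodes = [
            _node(f"P{k}", self.CONSIDERED[rng.integers(3)]) for k in range(20)
        ]
        profiles, _ = relative_proportions(nodes, self.CONSIDERED)
        for prof in profiles:
            assert sorted(prof.r.values(), reverse=True)[0] == 1.0

    def test_mean_shares_sum_to_one(self, rng):
        nodes = []
        for p in range(30):
            for j in range(int(rng.integers(1, 6))):
                nodes.append(_node(f"P{p}", self.CONSIDERED[rng.integers(3)], nid=f"{p}_{j}"))
        profiles, _ = relative_proportions(nodes, self.CONSIDERED)
        total = sum(
            np.mean([p.r[lvl] for p in profiles]) for lvl in self.CONSIDERED
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_excluded_patients_reported(self):
        nodes = [_node("P1", "external_iliac"), _node("P2", "inguinal")]
        profiles, dropped = relative_proportions(nodes, self.CONSIDERED)
        assert [p.patient_id for p in profiles] == ["P1"]
        assert dropped == ["P2"]

    def test_empty_considered_rejected(self):
        with pytest.raises(ValueError):
            relative_proportions([], [])


class TestVolumeNormalizedMeans:
    def test_worked_example(self):
        profiles = [
            ProportionProfile("P1", {"A": 1.0, "B": 0.0}),
            ProportionProfile("P2", {"A": 0.5, "B": 0.5}),
        ]
        values, ref = volume_normalized_means(
            profiles, {"A": 10.0, "B": 40.0}, ["A", "B"]
        )
        assert values["A"] == pytest.approx(75.0)
        assert values["B"] == pytest.approx(6.25)
        assert ref == pytest.approx(20.0)

    def test_volume_doubling_halves_everything(self):
        profiles = [ProportionProfile("P1", {"A": 0.7, "B": 0.3})]
        v1, r1 = volume_normalized_means(profiles, {"A": 5.0, "B": 20.0}, ["A", "B"])
        v2, r2 = volume_normalized_means(profiles, {"A": 10.0, "B": 40.0}, ["A", "B"])
        assert v2["A"] == pytest.approx(v1["A"] / 2)
        assert v2["B"] == pytest.approx(v1["B"] / 2)
        assert r2 == pytest.approx(r1 / 2)

    def test_reference_is_level_independent(self):
        profiles = [ProportionProfile("P1", {"A": 1.0, "B": 0.0, "C": 0.0})]
        volumes = {"A": 3.0, "B": 11.0, "C": 29.0}
        _, ref = volume_normalized_means(profiles, volumes, ["A", "B", "C"])
        assert ref == pytest.approx(1000.0 / 43.0)

    def test_zero_volume_rejected(self):
        profiles = [ProportionProfile("P1", {"A": 1.0})]
        with pytest.raises(ValueError):
            volume_normalized_means(profiles, {"A": 0.0}, ["A"])

    def test_homogeneous_cohort_near_reference(self, rng):
        volumes = {"A": 10.0, "B": 20.0, "C": 70.0}
        levels = list(volumes)
        probs = np.array([volumes[l] for l in levels]) / sum(volumes.values())
        n = 4000
        profiles = []
        for p in range(n):
            k = int(rng.integers(1, 5))
            draws = rng.choice(3, size=k, p=probs)
            profiles.append(
                ProportionProfile(
                    f"P{p}", {lvl: float(np.mean(draws == i)) for i, lvl in enumerate(levels)}
                )
            )
        values, ref = volume_normalized_means(profiles, volumes, levels)
        for lvl in levels:
            # SE of mean r is <= 0.5/sqrt(n); scale to permille/cm3
            se = 1000.0 * 0.5 / np.sqrt(n) / volumes[lvl]
            assert abs(values[lvl] - ref) < 3 * se + 0.02 * ref


class TestBcaCi:
    def test_degenerate_sample(self):
        assert bca_ci([4.2] * 10, BootstrapSpec(B=1000, seed=0)) == (4.2, 4.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bca_ci([], BootstrapSpec())

    def test_close_to_percentile_for_symmetric_sample(self, rng):
        sample = rng.normal(0.0, 1.0, 400)
        spec = BootstrapSpec(B=4000, seed=9)
        lo, hi = bca_ci(sample, spec)
        boot = np.sort(
            sample[rng.integers(400, size=(4000, 400))].mean(axis=1)
        )
        plo, phi = np.quantile(boot, [0.025, 0.975])
        width = phi - plo
        assert abs(lo - plo) < 0.05 * width + 0.01
        assert abs(hi - phi) < 0.05 * width + 0.01

    def test_matches_scipy_bca(self, rng):
        sample = rng.gamma(2.0, 3.0, 80)
        lo, hi = bca_ci(sample, BootstrapSpec(B=8000, seed=3))
        res = scipy_bootstrap(
            (sample,),
            np.mean,
            n_resamples=8000,
            confidence_level=0.95,
            method="BCa",
            random_state=np.random.default_rng(5),
        )
        width = res.confidence_interval.high - res.confidence_interval.low
        assert abs(lo - res.confidence_interval.low) < 0.1 * width
        assert abs(hi - res.confidence_interval.high) < 0.1 * width


class TestBootstrapMeanTest:
    def test_null_sample_large_p(self, rng):
        sample = rng.normal(5.0, 1.0, 200)
        res = bootstrap_mean_test(sample, float(sample.mean()), BootstrapSpec(B=2000, seed=1))
        assert res.p_value > 0.9

    def test_shifted_sample_tiny_p(self, rng):
        sample = rng.normal(5.0, 1.0, 200)
        res = bootstrap_mean_test(sample, 10.0, BootstrapSpec(B=2000, seed=1))
        assert res.p_value <= 0.001

    def test_p_consistent_with_ci(self, rng):
        sample = rng.gamma(3.0, 2.0, 60)
        spec = BootstrapSpec(B=3000, seed=7)
        lo, hi = bca_ci(sample, spec)
        for mu0 in (lo - 0.5, hi + 0.5):
            assert bootstrap_mean_test(sample, mu0, spec).p_value < 0.05
        mid = (lo + hi) / 2
        assert bootstrap_mean_test(sample, mid, spec).p_value > 0.05
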