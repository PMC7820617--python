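import numpy as np
import pytest

from nodalmap.grid import TemplateGrid
from nodalmap.records import NodeRecord
from nodalmap.template import (
    LEVEL_FAMILIES,
    MarginSpec,
    build_template,
    classify_point,
    classify_points,
    consensus_coverage,
    default_template_config,
    expand_levels,
)

from conftest import coarse_config


def _single_box_config(shape=(40, 40, 60), spacing=(1.0, 1.0, 1.0)):
    return {
        "shape": list(shape),
        "spacing": list(spacing),
        "levels": [
            {
                "name": "presacral",
                "sided": False,
                "consensus": True,
                "primitive": {
                    "kind": "box",
                    # center on the mid-sagittal plane of the grid
                    "center": [(shape[0] - 1) * spacing[0] / 2, 20.0, 30.0],
                    "half_size": [10.0, 12.5, 20.0],
                },
            }
        ],
    }


class TestBuildTemplate:
    def test_default_has_all_families_with_sides(self, atlas2mm):
        names = {(e.name, e.side) for e in atlas2mm.table}
        assert {e.name for e in atlas2mm.table} == set(LEVEL_FAMILIES)
        unsided = {n for n, s in names if s == "none"}
        assert unsided == {"presacral"}
        for fam in set(LEVEL_FAMILIES) - {"presacral"}:
            assert (fam, "left") in names and (fam, "right") in names

    def test_box_volume_arithmetic(self):
        # 20 x 25 x 40 mm box on a 1 mm grid, centered between voxel centers
        # so it covers exactly 20*25*40 voxels -> 20.0 cm³
        cfg = _single_box_config()
        cfg["levels"][0]["primitive"]["center"] = [19.5, 20.0, 30.5]
        _, atlas = build_template(cfg)
        label = atlas.label_of("presacral", "none")
        assert atlas.volumes_cm3[label] == pytest.approx(20.0, abs=1e-9)

    def test_determinism(self):
        _, a = build_template(coarse_config(), seed=5)
        _, b = build_template(coarse_config(), seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.table == b.table

    def test_overlap_error_names_levels(self):
        cfg = _single_box_config()
        cfg["levels"].append(
            {
                "name": "perirectal",
                "sided": False,
                "consensus": False,
                "primitive": {
                    "kind": "ellipsoid",
                    "center": [19.5, 20.0, 30.0],
                    "radii": [5.0, 5.0, 5.0],
                },
            }
        )
        with pytest.raises(ValueError, match="perirectal.*overlaps.*presacral"):
            build_template(cfg)

    def test_zero_volume_error(self):
        cfg = _single_box_config()
        cfg["levels"][0]["primitive"] = {
            "kind": "ellipsoid",
            "center": [-500.0, 0.0, 0.0],
            "radii": [1.0, 1.0, 1.0],
        }
        with pytest.raises(ValueError, match="zero volume"):
            build_template(cfg)

    def test_volume_additivity_exact(self, atlas2mm):
        vols = atlas2mm.volumes_cm3
        background = int(np.sum(atlas2mm.labels == 0)) * atlas2mm.grid.voxel_volume_cm3
        total = np.prod(atlas2mm.grid.shape) * atlas2mm.grid.voxel_volume_cm3
        assert sum(vols.values()) + background == pytest.approx(total, abs=1e-9)

    def test_mirror_symmetry_swaps_sides(self, atlas2mm, rng):
        grid = atlas2mm.grid
        pts = rng.uniform([0, 0, 0], [254, 254, 318], size=(3000, 3))
        lab = classify_points(pts, atlas2mm)
        lab_m = classify_points(grid.mirror_x(pts), atlas2mm)
        info = {e.label: e for e in atlas2mm.table}
        for a, b in zip(lab, lab_m):
            if a == 0:
                assert b == 0
                continue
            assert info[a].name == info[b].name
            expected = {"left": "right", "right": "left", "none": "none"}[info[a].side]
            assert info[b].side == expected


class TestExpandLevels:
    def test_margin_zero_is_identity(self, atlas4mm):
        out = expand_levels(atlas4mm, MarginSpec(0.0))
        assert np.array_equal(out.labels, atlas4mm.labels)

    def test_single_voxel_ball_volume(self):
        grid_cfg = {
            "shape": [31, 31, 31],
            "spacing": [1.0, 1.0, 1.0],
            "levels": [
                {
                    "name": "presacral",
                    "sided": False,
                    "consensus": True,
                    "primitive": {
                        "kind": "box",
                        "center": [15.0, 15.0, 15.0],
                        "half_size": [0.4, 0.4, 0.4],
                    },
                }
            ],
        }
        _, atlas = build_template(grid_cfg)
        label = atlas.label_of("presacral", "none")
        assert int((atlas.labels == label).sum()) == 1
        out = expand_levels(atlas, MarginSpec(7.0, frozenset({"presacral"})))
        ball = (4.0 / 3.0) * np.pi * 0.7**3  # cm³
        assert out.volumes_cm3[label] == pytest.approx(ball, rel=0.05)

    def test_monotone_in_margin(self, atlas4mm):
        m7 = expand_levels(atlas4mm, MarginSpec(7.0))
        m10 = expand_levels(atlas4mm, MarginSpec(10.0))
        assert np.all((m10.labels != 0)[m7.labels != 0])

    def test_original_voxels_never_reassigned(self, atlas4mm):
        out = expand_levels(atlas4mm, MarginSpec(10.0, frozenset(LEVEL_FAMILIES)))
        own = atlas4mm.labels != 0
        assert np.array_equal(out.labels[own], atlas4mm.labels[own])

    def test_overlap_resolved_by_nearest_level(self):
        # two single-voxel levels 10 mm apart, both dilated by 7 mm
        cfg = {
            "shape": [41, 21, 21],
            "spacing": [1.0, 1.0, 1.0],
            "levels": [
                {
                    "name": "external_iliac",
                    "sided": False,
                    "consensus": True,
                    "primitive": {
                        "kind": "box",
                        "center": [15.0, 10.0, 10.0],
                        "half_size": [0.4, 0.4, 0.4],
                    },
                },
                {
                    "name": "internal_iliac",
                    "sided": False,
                    "consensus": True,
                    "primitive": {
                        "kind": "box",
                        "center": [25.0, 10.0, 10.0],
                        "half_size": [0.4, 0.4, 0.4],
                    },
                },
            ],
        }
        _, atlas = build_template(cfg)
        out = expand_levels(
            atlas, MarginSpec(7.0, frozenset({"external_iliac", "internal_iliac"}))
        )
        # midpoint voxels split at x=20: <=20 nearest to label 1 (tie at 20 -> label 1)
        assert out.labels[19, 10, 10] == atlas.label_of("external_iliac", "none")
        assert out.labels[20, 10, 10] == atlas.label_of("external_iliac", "none")
        assert out.labels[21, 10, 10] == atlas.label_of("internal_iliac", "none")


class TestClassifyPoint:
    def test_centroid_of_left_obturator(self, atlas2mm):
        label = atlas2mm.label_of("obturator", "left")
        centroid = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == label).mean(axis=0)
        )
        assert classify_point(centroid, atlas2mm) == "obturator"
        assert atlas2mm.info(int(classify_points(centroid[None, :], atlas2mm)[0])).side == "left"

    def test_margin_changes_classification(self, atlas2mm):
        # 5 mm lateral (toward x=0) of the right common-iliac tube surface
        p = np.array([116.0 - 9.0 - 5.0, 112.0, 258.0])
        assert classify_point(p, atlas2mm) == "outside"
        expanded = expand_levels(atlas2mm, MarginSpec(7.0))
        assert classify_point(p, expanded) == "common_iliac"

    def test_out_of_grid_is_outside(self, atlas2mm):
        assert classify_point([1e5, 0.0, 0.0], atlas2mm) == "outside"

    def test_nonfinite_is_error(self, atlas2mm):
        with pytest.raises(ValueError):
            classify_point([np.nan, 0.0, 0.0], atlas2mm)

    def test_matches_separable_scan_oracle(self, atlas4mm, rng):
        # nearest voxel factorizes over axes, so an exhaustive per-axis scan
        # over all voxel-center coordinates is an exact oracle
        pts = rng.uniform([-20, -20, -20], [280, 280, 340], size=(10_000, 3))
        got = classify_points(pts, atlas4mm)
        expected = np.empty(len(pts), dtype=int)
        axes = [atlas4mm.grid.axis_coords(a) for a in range(3)]
        for i, p in enumerate(pts):
            idx = [int(np.argmin(np.abs(ax - c))) for ax, c in zip(axes, p)]
            inside = all(
                abs(p[a] - axes[a][idx[a]]) <= atlas4mm.grid.spacing[a] / 2 + 1e-9
                or (0 <= idx[a] < len(axes[a]))
                for a in range(3)
            )
            lo = [axes[a][0] - atlas4mm.grid.spacing[a] / 2 for a in range(3)]
            hi = [axes[a][-1] + atlas4mm.grid.spacing[a] / 2 for a in range(3)]
            if any(p[a] < lo[a] or p[a] > hi[a] for a in range(3)):
                expected[i] = 0
            else:
                expected[i] = atlas4mm.labels[idx[0], idx[1], idx[2]]
        np.testing.assert_array_equal(got, expected)

    def test_matches_full_voxel_scan(self, rng):
        _, atlas = build_template(_single_box_config(shape=(20, 20, 25)))
        centers = np.stack(atlas.grid.voxel_center_mesh(), axis=-1).reshape(-1, 3)
        flat = atlas.labels.reshape(-1)
        pts = rng.uniform([-5, -5, -5], [25, 25, 30], size=(400, 3))
        got = classify_points(pts, atlas)
        for p, g in zip(pts, got):
            d2 = np.sum((centers - p) ** 2, axis=1)
            nearest = flat[int(np.argmin(d2))]
            lo = [atlas.grid.axis_coords(a)[0] - atlas.grid.spacing[a] / 2 for a in range(3)]
            hi = [atlas.grid.axis_coords(a)[-1] + atlas.grid.spacing[a] / 2 for a in range(3)]
            outside = any(p[a] < lo[a] or p[a] > hi[a] for a in range(3))
            assert g == (0 if outside else nearest)


def _node(pid, pos, level="external_iliac", side="right", space="template"):
    return NodeRecord(pid, f"{pid}_n", tuple(pos), space=space, level=level, side=side)


class TestConsensusCoverage:
    def test_fraction_26_of_75(self, atlas2mm, rng):
        ext = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == atlas2mm.label_of("external_iliac", "right")).mean(0)
        )
        peri = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == atlas2mm.label_of("perirectal", "right")).mean(0)
        )
        nodes = []
        for k in range(75):
            nodes.append(_node(f"P{k:02d}", ext))
            if k < 26:
                nodes.append(_node(f"P{k:02d}", peri, level="perirectal"))
        report = consensus_coverage(nodes, atlas2mm, margins=[MarginSpec(0.0)])
        assert report[0.0].n_uncovered == 26
        assert report[0.0].uncovered_fraction_pct == 34.7

    def test_all_covered_fraction_zero(self, atlas2mm):
        ext = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == atlas2mm.label_of("external_iliac", "left")).mean(0)
        )
        nodes = [_node(f"P{k}", ext, side="left") for k in range(10)]
        report = consensus_coverage(nodes, atlas2mm, margins=[MarginSpec(0.0)])
        assert report[0.0].uncovered_fraction_pct == 0.0

    def test_native_space_nodes_rejected(self, atlas2mm):
        nodes = [_node("P1", [10, 10, 10], space="native")]
        with pytest.raises(ValueError, match="template space"):
            consensus_coverage(nodes, atlas2mm)

    def test_boundary_voxel_of_dilated_level_is_covered(self, atlas2mm):
        # a point ~6.5 mm lateral of the tube surface: uncovered at 0, covered at 7
        p = [116.0 - 9.0 - 6.5, 112.0, 258.0]
        nodes = [_node("P1", p)]
        report = consensus_coverage(
            nodes, atlas2mm, margins=[MarginSpec(0.0), MarginSpec(7.0)]
        )
        assert report[0.0].n_uncovered == 1
        assert report[7.0].n_uncovered == 0

    def test_margin_sensitivity_monotone(self, cohort_rigid, atlas2mm):
        nodes = [n for c in cohort_rigid for n in c.nodes_template]
        report = consensus_coverage(nodes, atlas2mm)
        assert (
            report[10.0].n_uncovered
            <= report[7.0].n_uncovered
            <= report[0.0].n_uncovered
        )

    def test_paraaortic_only_patients_excluded(self, atlas2mm):
        pa = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == atlas2mm.label_of("paraaortic", "right")).mean(0)
        )
        ext = atlas2mm.grid.index_to_world(
            np.argwhere(atlas2mm.labels == atlas2mm.label_of("external_iliac", "right")).mean(0)
        )
        nodes = [_node("P1", pa, level="paraaortic"), _node("P2", ext)]
        report = consensus_coverage(nodes, atlas2mm, margins=[MarginSpec(0.0)])
        assert report[0.0].n_patients == 1
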