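"""End-to-end orchestration: simulate → map → density → distances → level stats.

A run is driven by a :class:`RunConfig` (parsed from YAML), executes its
enabled stages in order into an output directory, and writes a manifest
with parameters, seeds and sha256 checksums so identical configurations
produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import io as nio
from .density import KdeConfig, density_from_nodes, hotspot_summary
from .distances import (
    PATIENT_BOOTSTRAP,
    POOLED_T,
    cohort_distances,
    compare_means,
    intra_patient_distances,
    max_intra_distance_quantiles,
)
from .levelstats import (
    BootstrapSpec,
    binary_involvement,
    bca_ci,
    bootstrap_mean_test,
    default_considered_levels,
    relative_proportions,
    surgery_contrasts,
    volume_normalized_means,
)
from .mapping import map_cohort
from .records import nodes_to_frame
from .simulate import GenParams, sample_cohort
from .template import (
    LevelAtlas,
    MarginSpec,
    build_template,
    classify_points,
    consensus_coverage,
)

ALL_STAGES = ("template", "simulate", "map", "density", "distances", "levelstats")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    gen: GenParams = field(default_factory=GenParams)
    kde: KdeConfig = field(default_factory=KdeConfig)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    margins_mm: tuple[float, ...] = (0.0, 7.0, 10.0)
    template_config: Mapping | None = None
    write_dvfs: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        stages = tuple(raw.pop("stages", ALL_STAGES))
        unknown = [s for s in stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        gen_kwargs = dict(raw.pop("gen", {}))
        gen_kwargs.setdefault("seed", seed)
        gen = GenParams(**gen_kwargs)
        kde = KdeConfig(**raw.pop("kde", {}))
        boot_kwargs = dict(raw.pop("bootstrap", {}))
        boot_kwargs.setdefault("seed", seed + 1)
        bootstrap = BootstrapSpec(**boot_kwargs)
        margins = tuple(float(m) for m in raw.pop("margins_mm", (0.0, 7.0, 10.0)))
        template_config = raw.pop("template", None)
        write_dvfs = bool(raw.pop("write_dvfs", False))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(
            seed=seed,
            stages=stages,
            gen=gen,
            kde=kde,
            bootstrap=bootstrap,
            margins_mm=margins,
            template_config=template_config,
            write_dvfs=write_dvfs,
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config": {
            "gen": _jsonable(config.gen),
            "kde": _jsonable(config.kde),
            "bootstrap": _jsonable(config.bootstrap),
            "margins_mm": list(config.margins_mm),
        },
        "outputs": {},
    }
    artifacts: dict[str, Any] = {}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    stage = "template"
    try:
        atlas: LevelAtlas | None = None
        if "template" in config.stages:
            _, atlas = build_template(config.template_config, seed=config.seed)
            atlas_path = out / "atlas.nrrd"
            nio.write_atlas(atlas_path, atlas)
            record("atlas", atlas_path)
            record("atlas_table", atlas_path.with_suffix(".json"))
            artifacts["atlas"] = atlas

        cohort = None
        stage = "simulate"
        if "simulate" in config.stages:
            if atlas is None:
                raise ValueError("simulate stage requires the template stage")
            cohort = sample_cohort(config.gen, atlas)
            native = [n for case in cohort for n in case.nodes_native]
            truth = [n for case in cohort for n in case.nodes_template]
            native_path = out / "nodes_native.csv"
            truth_path = out / "nodes_template_truth.csv"
            nio.write_nodes(native_path, native)
            nio.write_nodes(truth_path, truth)
            record("nodes_native", native_path)
            record("nodes_template_truth", truth_path)
            if config.write_dvfs:
                dvf_dir = out / "dvf"
                dvf_dir.mkdir(exist_ok=True)
                for case in cohort:
                    fwd = dvf_dir / f"{case.dvf_ref}_forward.nrrd"
                    inv = dvf_dir / f"{case.dvf_ref}_inverse.nrrd"
                    nio.write_dvf(fwd, case.dvf_forward)
                    nio.write_dvf(inv, case.dvf_inverse)
            artifacts["cohort"] = cohort

        mapped = None
        stage = "map"
        if "map" in config.stages:
            if cohort is None:
                raise ValueError("map stage requires the simulate stage")
            mapped, qc = map_cohort(cohort)
            # re-assign levels from the mapped positions (observer-independent)
            labels = classify_points(
                np.array([n.position for n in mapped]), atlas
            )
            reassigned = []
            for node, lab in zip(mapped, labels):
                if lab == 0:
                    reassigned.append(
                        dataclasses.replace(node, level="outside", side="none")
                    )
                else:
                    info = atlas.info(int(lab))
                    reassigned.append(
                        dataclasses.replace(node, level=info.name, side=info.side)
                    )
            mapped = reassigned
            mapped_path = out / "nodes_mapped.csv"
            qc_path = out / "mapping_qc.csv"
            nio.write_nodes(mapped_path, mapped)
            qc.to_csv(qc_path, index=False)
            record("nodes_mapped", mapped_path)
            record("mapping_qc", qc_path)
            artifacts["mapped"] = mapped

        stage = "density"
        if "density" in config.stages:
            if mapped is None:
                raise ValueError("density stage requires the map stage")
            pelvic = [n for n in mapped if n.level != "paraaortic"]
            density = density_from_nodes(pelvic, config.kde, atlas.grid)
            density_path = out / "density.nrrd"
            nio.write_density(density_path, density)
            record("density", density_path)
            record("density_meta", density_path.with_suffix(".json"))
            artifacts["density"] = density
            artifacts["hotspots"] = hotspot_summary(density, atlas, quantile=0.95)

        stage = "distances"
        if "distances" in config.stages:
            if mapped is None or cohort is None:
                raise ValueError("distances stage requires the map stage")
            native_nodes = [n for case in cohort for n in case.nodes_native]
            intra_native = intra_patient_distances(native_nodes, "native")
            intra_template = intra_patient_distances(mapped, "template")
            cohort_set = cohort_distances(mapped)
            pooled = compare_means(intra_native, cohort_set, POOLED_T)
            boot = compare_means(
                intra_native,
                cohort_set,
                PATIENT_BOOTSTRAP,
                nodes=mapped,
                seed=config.seed + 2,
            )
            quantiles = max_intra_distance_quantiles(mapped)
            dist_report = {
                "intra_native": {
                    "n_distances": int(intra_native.distances.size),
                    "mean_cm": intra_native.mean_mm / 10.0,
                },
                "intra_template": {
                    "n_distances": int(intra_template.distances.size),
                    "mean_cm": intra_template.mean_mm / 10.0,
                },
                "cohort": {
                    "n_distances": int(cohort_set.distances.size),
                    "n_points": cohort_set.n_points,
                    "mean_cm": cohort_set.mean_mm / 10.0,
                },
                "pooled_t": _jsonable(pooled),
                "patient_bootstrap": _jsonable(boot),
                "max_intra_quantiles_cm": [q / 10.0 for q in quantiles],
            }
            dist_path = out / "distances.json"
            dist_path.write_text(json.dumps(dist_report, indent=2, sort_keys=True))
            record("distances", dist_path)
            artifacts["distances"] = dist_report

        stage = "levelstats"
        if "levelstats" in config.stages:
            if mapped is None or cohort is None:
                raise ValueError("levelstats stage requires the map stage")
            table = binary_involvement(
                [n for n in mapped if n.level != "outside"],
                n_patients=len(cohort),
            )
            surgery = {case.patient_id: case.surgery for case in cohort}
            contrasts = surgery_contrasts(
                [n for n in mapped if n.level not in ("outside", "paraaortic")], surgery
            )
            considered = default_considered_levels(atlas)
            profiles, dropped = relative_proportions(mapped, considered)
            volumes = atlas.family_volumes_cm3(considered)
            values, reference = volume_normalized_means(profiles, volumes, considered)
            level_tests = {}
            for i, lvl in enumerate(considered):
                sample = [1000.0 * p.r.get(lvl, 0.0) / volumes[lvl] for p in profiles]
                spec = dataclasses.replace(
                    config.bootstrap, seed=config.bootstrap.seed + i
                )
                ci = bca_ci(sample, spec)
                test = bootstrap_mean_test(sample, reference, spec)
                level_tests[lvl] = {
                    "mean_permille_per_cm3": values[lvl],
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p_vs_homogeneous": test.p_value,
                }
            coverage = consensus_coverage(
                mapped, atlas, margins=[MarginSpec(m) for m in config.margins_mm]
            )
            report = {
                "involvement_combined": table.combined.to_dict("records"),
                "involvement_by_side": table.by_side.to_dict("records"),
                "surgery_contrasts": contrasts.to_dict("records"),
                "proportions": {
                    "considered_levels": list(considered),
                    "n_profiles": len(profiles),
                    "dropped_patients": dropped,
                    "homogeneous_reference_permille_per_cm3": reference,
                    "levels": level_tests,
                },
                "coverage": {
                    str(m): _jsonable(rep) for m, rep in coverage.items()
                },
            }
            stats_path = out / "levelstats.json"
            stats_path.write_text(json.dumps(report, indent=2, sort_keys=True))
            record("levelstats", stats_path)
            artifacts["levelstats"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_text = write_report(artifacts)
    report_path = out / "report.txt"
    report_path.write_text(report_text)
    record("report", report_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(artifacts: Mapping[str, Any]) -> str:
    """Human-readable summary with one section per available artifact."""
    lines: list[str] = ["nodalmap run report", "=" * 19, ""]
    if "levelstats" in artifacts:
        stats = artifacts["levelstats"]
        lines += ["Binary involvement (patients, %)", "-" * 32]
        for row in stats["involvement_combined"]:
            lines.append(f"  {row['region']:<16} {row['count']:>3}  {row['pct']:>5.1f}%")
        lines.append("")
        lines += ["Involvement by side (left / right)", "-" * 34]
        regions = {}
        for row in stats["involvement_by_side"]:
            regions.setdefault(row["region"], {})[row["side"]] = row
        for region, sides in regions.items():
            left = sides.get("left", {"count": 0, "pct": 0.0})
            right = sides.get("right", {"count": 0, "pct": 0.0})
            lines.append(
                f"  {region:<16} {left['count']:>3} ({left['pct']:.1f}%) / "
                f"{right['count']:>3} ({right['pct']:.1f}%)"
            )
        lines.append("")
        lines += ["Surgery subgroup contrasts (Fisher exact, Bonferroni)", "-" * 53]
        for row in stats["surgery_contrasts"]:
            lines.append(
                f"  {row['region']:<16} {row['side']:<6} p={row['p']:.3f} "
                f"p_adj={row['p_adj']:.3f}"
            )
        lines.append("")
        prop = stats["proportions"]
        lines += [
            "Volume-normalized level proportions (permille per cm3)",
            "-" * 54,
            f"  homogeneous reference: {prop['homogeneous_reference_permille_per_cm3']:.3f}",
            f"  profiles: {prop['n_profiles']} (dropped: {len(prop['dropped_patients'])})",
        ]
        for lvl, entry in prop["levels"].items():
            lines.append(
                f"  {lvl:<16} {entry['mean_permille_per_cm3']:>7.3f} "
                f"[{entry['ci_low']:.3f}, {entry['ci_high']:.3f}] "
                f"p={entry['p_vs_homogeneous']:.3f}"
            )
        lines.append("")
        lines += ["Consensus coverage", "-" * 18]
        for margin, rep in stats["coverage"].items():
            lines.append(
                f"  margin {margin} mm: {len(rep['uncovered_patients'])}/"
                f"{rep['n_patients']} patients uncovered "
                f"({rep['uncovered_fraction_pct']:.1f}%)"
            )
        lines.append("")
    if "distances" in artifacts:
        dist = artifacts["distances"]
        lines += ["Pairwise distances", "-" * 18]
        lines.append(
            f"  intra-patient (native):   n={dist['intra_native']['n_distances']}, "
            f"mean {dist['intra_native']['mean_cm']:.1f} cm"
        )
        lines.append(
            f"  intra-patient (template): n={dist['intra_template']['n_distances']}, "
            f"mean {dist['intra_template']['mean_cm']:.1f} cm"
        )
        lines.append(
            f"  cohort-level:             n={dist['cohort']['n_distances']}, "
            f"mean {dist['cohort']['mean_cm']:.1f} cm"
        )
        lines.append(
            f"  pooled t-test p={dist['pooled_t']['p_value']:.2e}; "
            f"patient bootstrap p={dist['patient_bootstrap']['p_value']:.3f}"
        )
        med, q75, q95 = dist["max_intra_quantiles_cm"]
        lines.append(
            f"  max intra-patient distance: median {med:.1f} / "
            f"75th {q75:.1f} / 95th {q95:.1f} cm"
        )
        lines.append("")
    if "density" in artifacts:
        density = artifacts["density"]
        lines += ["Density atlas", "-" * 13]
        lines.append(
            f"  nodes: {density.n_nodes}, patients: {density.n_patients}, "
            f"peak {density.values.max():.1f} permille/cm3, "
            f"mass {density.total_mass_permille:.0f} permille"
        )
        for spot in artifacts.get("hotspots", [])[:5]:
            lines.append(
                f"  hotspot {spot.rank}: peak {spot.peak_permille_per_cm3:.1f} "
                f"in {'/'.join(spot.levels)}"
            )
        lines.append("")
    return "\n".join(lines)
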