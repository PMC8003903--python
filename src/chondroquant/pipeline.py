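"""End-to-end driver: phantom cohort -> T2 fitting -> thickness -> VOI
aggregation -> longitudinal statistics, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import FitOptions, RunConfig, VOIOptions
from .longstats import run_severity_analysis
from .meshmodel import compute_thickness, mean_thickness_per_voi
from .phantom import Cohort, KneeTimepoint, cartilage_mask, phantom_frame, simulate_cohort
from .relaxometry import fit_t2_map, median_t2, ml_ratio
from .voiatlas import VOI_LABELS, assign_voxels, partition_vois, split_layers

__all__ = ["process_knee_timepoint", "build_measure_table", "run_all", "RunResult"]

log = logging.getLogger("chondroquant")


def process_knee_timepoint(
    ktp: KneeTimepoint,
    fit_opts: FitOptions | None = None,
    voi_opts: VOIOptions | None = None,
) -> dict[str, float]:
    """Measure one imaged knee-timepoint: per-(sub-)VOI T2 medians,
    thickness means and medial-lateral ratios.

    The ground-truth cartilage mask stands in for the manual segmentation;
    everything downstream (fit, partition, voxel assignment, aggregation)
    runs through the measurement pipeline proper.
    """
    fo = fit_opts or FitOptions()
    vo = voi_opts or VOIOptions()
    if ktp.volume is None:
        raise ValueError("knee-timepoint has no rendered volume")
    geom = ktp.volume.geometry
    mask = cartilage_mask(ktp.field, geom)
    t2map = fit_t2_map(ktp.volume, mask, exclude_first=fo.exclude_first)
    partition = partition_vois(
        ktp.bone, phantom_frame(), ap_fractions=vo.ap_fractions, ml_fractions=vo.ml_fractions
    )
    assign = assign_voxels(mask, geom, ktp.bone, ktp.cartilage, partition)
    ijk = tuple(assign.indices.T)
    t2_vals = t2map.t2[ijk]
    valid = t2map.valid[ijk]
    sub_full = assign.sub_voi_labels()

    measures: dict[str, float] = {}
    t2_by_region: dict[str, float] = {}

    def t2_median(sel: np.ndarray) -> float:
        vals = t2_vals[sel & valid]
        if vals.size == 0:
            return float("nan")
        res = median_t2(vals, quantile_method=fo.quantile_method, order=fo.raya_order)
        return res.median

    for voi in VOI_LABELS:
        t2_by_region[voi] = t2_median(assign.voi == voi)
        measures[f"{voi}_T2"] = t2_by_region[voi]
        if voi.endswith("a"):
            for sub in ("e", "c", "i"):
                label = voi + sub
                t2_by_region[label] = t2_median(sub_full == label)
                measures[f"{label}_T2"] = t2_by_region[label]
    if vo.include_layers:
        layers = split_layers(assign.depth)
        for voi in VOI_LABELS:
            for layer in ("deep", "superficial"):
                measures[f"{voi}_T2_{layer}"] = t2_median((assign.voi == voi) & (layers == layer))

    tmap = compute_thickness(ktp.bone, ktp.cartilage, coverage_cap=vo.coverage_cap)
    th_voi = mean_thickness_per_voi(tmap, partition.vertex_voi)
    th_sub = mean_thickness_per_voi(tmap, partition.sub_voi_labels())
    th_by_region = dict(zip(th_voi["voi"], th_voi["mean_mm"]))
    th_by_region.update(dict(zip(th_sub["voi"], th_sub["mean_mm"])))
    for region, value in th_by_region.items():
        measures[f"{region}_thickness"] = float(value)

    for name, ratio in ml_ratio(t2_by_region).items():
        measures[f"{name}_T2"] = ratio
    for name, ratio in ml_ratio(th_by_region).items():
        measures[f"{name}_thickness"] = ratio
    return measures


def build_measure_table(
    cohort: Cohort,
    fit_opts: FitOptions | None = None,
    voi_opts: VOIOptions | None = None,
) -> pd.DataFrame:
    """Long-format cohort table (knee, timepoint, months, measure, value)."""
    rows = []
    for tps in cohort.knees:
        for tp, ktp in tps.items():
            log.info("measuring knee %d timepoint %s", ktp.knee, tp)
            measures = process_knee_timepoint(ktp, fit_opts, voi_opts)
            for measure, value in measures.items():
                rows.append(
                    {
                        "knee": ktp.knee,
                        "timepoint": tp,
                        "months": ktp.months,
                        "measure": measure,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    table: pd.DataFrame
    stats: pd.DataFrame
    truth_table: pd.DataFrame
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Simulate, measure and analyze a cohort; write tables and a manifest.

    Deterministic for a fixed config (the manifest records the config hash
    and a content hash per output file, so a re-run can be verified
    byte-for-byte).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    stage = "simulate"
    try:
        from dataclasses import replace

        spec = replace(config.phantom, seed=config.seed)
        cohort = simulate_cohort(
            config.n_knees, spec, config.progression, seed=config.seed, render=config.render
        )
        stage = "measure"
        if not config.render:
            raise ValueError("run_all requires render=True to measure the cohort")
        table = build_measure_table(cohort, config.fit, config.voi)
        stage = "stats"
        stats = run_severity_analysis(table, config.stats)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    outputs = {}
    table_path = outdir / "cohort_table.csv"
    table.to_csv(table_path, index=False)
    stats_path = outdir / "stat_results.csv"
    stats.to_csv(stats_path, index=False)
    truth_path = outdir / "truth_table.csv"
    cohort.truth_table.to_csv(truth_path, index=False)
    for p in (table_path, stats_path, truth_path):
        outputs[p.name] = _sha256(p)

    if config.save_images:
        from .io import write_mesh, write_volume

        for tps in cohort.knees:
            for tp, ktp in tps.items():
                stem = f"knee{ktp.knee:02d}_{tp}"
                vol_path = write_volume(ktp.volume, outdir / f"{stem}_msme.nii")
                bone_path = write_mesh(ktp.bone, outdir / f"{stem}_bone.ply")
                cart_path = write_mesh(ktp.cartilage, outdir / f"{stem}_cartilage.ply")
                for p in (vol_path, bone_path, cart_path):
                    outputs[Path(p).name] = _sha256(Path(p))

    manifest = {
        "package_version": __version__,
        "config_hash": config.canonical_hash(),
        "config": config.to_dict(),
        "outputs": outputs,
        "warnings": warnings,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(table=table, stats=stats, truth_table=cohort.truth_table,
                     manifest=manifest, outdir=outdir)
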