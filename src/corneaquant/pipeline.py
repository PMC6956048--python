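"""End-to-end study pipeline: simulate -> quantify -> compare groups.

For every configured group the pipeline generates synthetic inputs with known
ground truth, runs each enabled quantification stage, and collects everything
into one machine-readable report:

* ``tem``    — fibril density (windowed median over >= 3 images) and the
               equivalent-diameter distribution, against the generator truth;
* ``tensile``— Young's modulus per replicate strip and group mean;
* ``dsc``    — denaturation temperature per replicate scan and group mean;
* ``qpcr``   — housekeeping-normalized fold changes per gene;

plus group statistics (one-way ANOVA across all groups and pairwise t tests
against the control and the ectatic model group) for each quantified endpoint.

The report is deterministic: identical config and seed give byte-identical
JSON (no timestamps; all randomness flows from the global seed through named
per-stage substreams).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, expression, mechanics, tem, thermal
from .config import PipelineConfig
from .seeding import derive_seed
from .synthetic import (
    CtTableParams,
    FibrilFieldParams,
    TensileParams,
    ThermogramParams,
    generate_ct_table,
    generate_fibril_field,
    generate_tensile_record,
    generate_thermogram,
)

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    """Wraps any stage failure with the failing stage and group named."""

    def __init__(self, stage: str, group: str | None, cause: Exception):
        where = f"stage {stage!r}" + (f", group {group!r}" if group else "")
        super().__init__(f"pipeline aborted in {where}: {cause}")
        self.stage = stage
        self.group = group
        self.__cause__ = cause


def _run_tem_group(cfg: PipelineConfig, group: str) -> dict[str, Any]:
    sec = cfg.section("tem")
    seg = tem.SegmentationConfig(**sec["segmentation"])
    n_images = int(sec["n_images"])
    estimates = []
    detections_all: list[tem.FibrilDetection] = []
    truth_density = []
    truth_diameters: list[float] = []
    for i in range(n_images):
        params = FibrilFieldParams(
            **{**sec["field"], **sec["group_fields"][group]},
            seed=derive_seed(cfg.seed, "tem", group, f"image{i}"),
        )
        field, image = generate_fibril_field(params)
        mask = tem.binarize_adaptive(image, seg)
        dets = tem.detect_fibrils(mask, params.pixel_size_nm, seg)
        detections_all.extend(dets)
        dcfg = tem.DensityConfig(
            **sec["density"], seed=derive_seed(cfg.seed, "tem-windows", group, f"image{i}")
        )
        estimates.append(
            tem.estimate_density(dets, image.shape, params.pixel_size_nm, dcfg)
        )
        truth_density.append(field.realized_density)
        truth_diameters.extend(field.diameters_nm.tolist())
    agg = tem.aggregate_density(estimates, min_images=int(sec["density"]["min_images"]))
    dist = tem.diameter_distribution(detections_all, bin_width_nm=float(sec["bin_width_nm"]))
    return {
        "density_per_um2": agg.density_per_um2,
        "median_window_count": agg.median_count,
        "n_windows_total": int(len(agg.per_window_counts)),
        "n_images": agg.n_images,
        "n_detections": len(detections_all),
        "diameter_median_nm": dist.median_nm,
        "diameter_iqr_nm": dist.iqr_nm,
        "diameter_mean_nm": dist.mean_nm,
        "diameter_sd_nm": dist.sd_nm,
        "truth": {
            "realized_density_per_um2": float(np.mean(truth_density)),
            "n_fibrils": len(truth_diameters),
            "diameter_median_nm": float(np.median(truth_diameters)),
        },
    }


def _run_tensile_group(cfg: PipelineConfig, group: str) -> dict[str, Any]:
    sec = cfg.section("tensile")
    moduli = []
    for rep in range(int(sec["n_replicates"])):
        params = TensileParams(
            gauge_length_mm=sec["gauge_length_mm"],
            model=sec["model"],
            toe_amplitude=float(sec["group_toe_amplitude"][group]),
            toe_rate=sec["toe_rate"],
            strip_width_mm=sec["strip_width_mm"],
            thickness_mm=sec["thickness_mm"],
            displacement_rate_mm_s=sec["displacement_rate_mm_s"],
            max_strain=sec["max_strain"],
            sampling_hz=sec["sampling_hz"],
            noise_sd_N=sec["noise_sd_N"],
            seed=derive_seed(cfg.seed, "tensile", group, f"rep{rep}"),
        )
        record = generate_tensile_record(params)
        curve = mechanics.compute_stress_strain(record)
        est = mechanics.estimate_modulus(
            curve, fit_lo_frac=float(sec["fit_lo_frac"]), fit_hi_frac=float(sec["fit_hi_frac"])
        )
        moduli.append(est.young_modulus_MPa)
    return {
        "young_modulus_MPa": moduli,
        "mean_young_modulus_MPa": float(np.mean(moduli)),
        "sd_young_modulus_MPa": float(np.std(moduli, ddof=1)) if len(moduli) > 1 else 0.0,
    }


def _run_dsc_group(cfg: PipelineConfig, group: str) -> dict[str, Any]:
    sec = cfg.section("dsc")
    td_spec = sec["group_td"][group]
    rng = np.random.default_rng(derive_seed(cfg.seed, "dsc-td", group))
    tds = []
    truths = []
    for rep in range(int(sec["n_replicates"])):
        td_true = float(rng.normal(td_spec["mean"], td_spec["sd"]))
        params = ThermogramParams(
            td_C=td_true,
            peak_width_C=sec["peak_width_C"],
            peak_depth_mW=sec["peak_depth_mW"],
            baseline_intercept_mW=sec["baseline_intercept_mW"],
            baseline_slope_mW_per_C=sec["baseline_slope_mW_per_C"],
            t_start_C=sec["t_start_C"],
            t_end_C=sec["t_end_C"],
            heating_rate_C_min=sec["heating_rate_C_min"],
            sampling_interval_C=sec["sampling_interval_C"],
            noise_sd_mW=sec["noise_sd_mW"],
            seed=derive_seed(cfg.seed, "dsc", group, f"rep{rep}"),
        )
        tg = generate_thermogram(params)
        result = thermal.detect_denaturation(tg)
        tds.append(result.td_C)
        truths.append(td_true)
    return {
        "td_C": tds,
        "mean_td_C": float(np.mean(tds)),
        "sd_td_C": float(np.std(tds, ddof=1)) if len(tds) > 1 else 0.0,
        "truth_td_C": truths,
    }


def _run_qpcr(cfg: PipelineConfig) -> dict[str, Any]:
    sec = cfg.section("qpcr")
    effects = {
        (grp, gene): float(eff)
        for grp, per_gene in sec.get("log2_effects", {}).items()
        for gene, eff in per_gene.items()
    }
    params = CtTableParams(
        genes=sec["genes"],
        groups=cfg.groups,
        housekeeping=sec["housekeeping"],
        control_group=sec["control_group"],
        log2_effects=effects,
        baseline_ct=sec.get("baseline_ct", {}),
        replicates_per_group=int(sec["replicates_per_group"]),
        ct_noise_sd=float(sec["ct_noise_sd"]),
        seed=derive_seed(cfg.seed, "qpcr"),
    )
    table = generate_ct_table(params)
    fc = expression.delta_delta_ct(
        table, housekeeping=sec["housekeeping"], control_group=sec["control_group"]
    )
    out: dict[str, Any] = {"fold_changes": {}}
    for _, row in fc.group_summary.iterrows():
        out["fold_changes"].setdefault(row["gene"], {})[row["group"]] = {
            "geo_mean_fold": float(row["geo_mean_fold"]),
            "sd_log2_fold": float(row["sd_log2_fold"]),
            "n": int(row["n"]),
        }
    out["_per_sample_log2_fold"] = {
        gene: {
            grp: (-sub["ddct"]).tolist()
            for grp, sub in fc.per_sample[fc.per_sample["gene"] == gene].groupby("group")
        }
        for gene in fc.per_sample["gene"].unique()
        if gene != params.housekeeping
    }
    return out


def _group_stats(values_by_group: dict[str, list[float]], control: str, model: str) -> dict:
    """ANOVA across groups plus pairwise t tests vs control and vs the model group."""
    out: dict[str, Any] = {}
    usable = {g: v for g, v in values_by_group.items() if len(v) >= 2}
    if len(usable) >= 2:
        try:
            a = expression.one_way_anova(list(usable.values()))
            out["anova"] = {"F": a.statistic, "df": list(a.df), "p": a.p_two_sided}
        except expression.DegenerateStatisticError as exc:
            out["anova"] = {"error": str(exc)}
    for ref in (control, model):
        if ref not in usable:
            continue
        for grp, vals in usable.items():
            if grp == ref:
                continue
            try:
                t = expression.two_sample_t(vals, usable[ref], variant="student")
                out.setdefault(f"t_vs_{ref}", {})[grp] = {
                    "t": t.statistic,
                    "df": t.df,
                    "p": t.p_two_sided,
                }
            except (ValueError, expression.DegenerateStatisticError) as exc:
                out.setdefault(f"t_vs_{ref}", {})[grp] = {"error": str(exc)}
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute every enabled stage for every group and return the report.

    With ``out_dir`` set, writes ``report.json`` (sorted keys, no timestamps)
    there. Any stage failure raises :class:`StageError` naming the stage and
    group.
    """
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "groups": cfg.groups,
        "stages": cfg.stages,
    }
    stage_runners = {
        "tem": _run_tem_group,
        "tensile": _run_tensile_group,
        "dsc": _run_dsc_group,
    }
    for stage in cfg.stages:
        if stage == "qpcr":
            try:
                report["qpcr"] = _run_qpcr(cfg)
            except Exception as exc:  # noqa: BLE001 - rewrapped with context
                raise StageError("qpcr", None, exc) from exc
            continue
        runner = stage_runners[stage]
        section: dict[str, Any] = {}
        for group in cfg.groups:
            try:
                section[group] = runner(cfg, group)
            except Exception as exc:  # noqa: BLE001 - rewrapped with context
                raise StageError(stage, group, exc) from exc
        report[stage] = section

    control = cfg.section("qpcr")["control_group"]
    model_group = "KC" if "KC" in cfg.groups else cfg.groups[-1]
    stats: dict[str, Any] = {}
    if "tensile" in cfg.stages:
        stats["young_modulus_MPa"] = _group_stats(
            {g: report["tensile"][g]["young_modulus_MPa"] for g in cfg.groups},
            control,
            model_group,
        )
    if "dsc" in cfg.stages:
        stats["td_C"] = _group_stats(
            {g: report["dsc"][g]["td_C"] for g in cfg.groups}, control, model_group
        )
    if "qpcr" in cfg.stages:
        per_gene = report["qpcr"].pop("_per_sample_log2_fold")
        stats["log2_fold"] = {
            gene: _group_stats(by_group, control, model_group)
            for gene, by_group in per_gene.items()
        }
    if stats:
        report["stats"] = stats

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report
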