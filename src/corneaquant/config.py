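"""Pipeline configuration: defaults, YAML loading and validation.

The shipped preset (``presets/default.yaml``) defines the five-group study
design; user configs override it key-by-key. Unknown keys are rejected and
validation collects *all* violations rather than stopping at the first.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_default_config", "validate_config"]

VALID_STAGES = ("tem", "tensile", "dsc", "qpcr")


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations))


@dataclass
class PipelineConfig:
    """Resolved configuration: the merged raw mapping plus convenience views."""

    raw: dict[str, Any]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def groups(self) -> list[str]:
        return list(self.raw["groups"])

    @property
    def stages(self) -> list[str]:
        return list(self.raw["stages"])

    def section(self, name: str) -> dict[str, Any]:
        return self.raw[name]


def load_default_config() -> dict[str, Any]:
    text = resources.files("corneaquant").joinpath("presets/default.yaml").read_text()
    return yaml.safe_load(text)


def _merge(base: dict, override: dict, path: str, violations: list[str]) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            # group_* maps and log2_effects accept arbitrary group keys
            leaf = path.split(".")[-1] if path else ""
            if leaf.startswith("group_") or leaf in ("log2_effects", "baseline_ct"):
                out[key] = copy.deepcopy(value)
            else:
                violations.append(f"unknown key {here!r}")
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here, violations)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _check(raw: dict[str, Any], violations: list[str]) -> None:
    """Structural checks plus each sub-config's own invariants."""
    from .synthetic import CtTableParams, FibrilFieldParams, TensileParams, ThermogramParams
    from .tem import DensityConfig, SegmentationConfig

    for stage in raw.get("stages", []):
        if stage not in VALID_STAGES:
            violations.append(f"unknown stage {stage!r}; valid stages: {VALID_STAGES}")
    groups = raw.get("groups", [])
    if not groups:
        violations.append("groups must be non-empty")

    tem = raw["tem"]
    for grp in groups:
        if grp not in tem["group_fields"]:
            violations.append(f"tem.group_fields missing group {grp!r}")
    for grp, field_spec in tem["group_fields"].items():
        try:
            FibrilFieldParams(**{**tem["field"], **field_spec})
        except (TypeError, ValueError) as exc:
            violations.append(f"tem.group_fields.{grp}: {exc} (FibrilFieldParams invariant)")
    try:
        SegmentationConfig(**tem["segmentation"])
    except (TypeError, ValueError) as exc:
        violations.append(f"tem.segmentation: {exc} (SegmentationConfig invariant)")
    try:
        dc = DensityConfig(**tem["density"])
        if dc.window_px > min(tem["field"]["field_width_px"], tem["field"]["field_height_px"]):
            violations.append(
                "tem.density.window_px exceeds field extent (DensityConfig invariant)"
            )
    except (TypeError, ValueError) as exc:
        violations.append(f"tem.density: {exc} (DensityConfig invariant)")

    tens = raw["tensile"]
    for grp in groups:
        if grp not in tens["group_toe_amplitude"]:
            violations.append(f"tensile.group_toe_amplitude missing group {grp!r}")
    try:
        TensileParams(
            gauge_length_mm=tens["gauge_length_mm"],
            model=tens["model"],
            toe_rate=tens["toe_rate"],
            strip_width_mm=tens["strip_width_mm"],
            thickness_mm=tens["thickness_mm"],
            displacement_rate_mm_s=tens["displacement_rate_mm_s"],
            max_strain=tens["max_strain"],
            sampling_hz=tens["sampling_hz"],
            noise_sd_N=tens["noise_sd_N"],
        )
    except (TypeError, ValueError) as exc:
        violations.append(f"tensile: {exc} (TensileParams invariant)")
    if not 0 <= tens["fit_lo_frac"] < tens["fit_hi_frac"] <= 1:
        violations.append("tensile: need 0 <= fit_lo_frac < fit_hi_frac <= 1")

    dsc = raw["dsc"]
    for grp in groups:
        if grp not in dsc["group_td"]:
            violations.append(f"dsc.group_td missing group {grp!r}")
    for grp, td in dsc["group_td"].items():
        try:
            ThermogramParams(
                td_C=td["mean"],
                peak_width_C=dsc["peak_width_C"],
                peak_depth_mW=dsc["peak_depth_mW"],
                t_start_C=dsc["t_start_C"],
                t_end_C=dsc["t_end_C"],
                heating_rate_C_min=dsc["heating_rate_C_min"],
                sampling_interval_C=dsc["sampling_interval_C"],
                noise_sd_mW=dsc["noise_sd_mW"],
            )
        except (TypeError, ValueError) as exc:
            violations.append(f"dsc.group_td.{grp}: {exc} (ThermogramParams invariant)")

    qp = raw["qpcr"]
    try:
        effects = {
            (grp, gene): float(eff)
            for grp, per_gene in qp.get("log2_effects", {}).items()
            for gene, eff in per_gene.items()
        }
        CtTableParams(
            genes=qp["genes"],
            groups=groups,
            housekeeping=qp["housekeeping"],
            control_group=qp["control_group"],
            log2_effects=effects,
            baseline_ct=qp.get("baseline_ct", {}),
            replicates_per_group=qp["replicates_per_group"],
            ct_noise_sd=qp["ct_noise_sd"],
        )
    except (TypeError, ValueError) as exc:
        violations.append(f"qpcr: {exc} (CtTableParams invariant)")


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load, merge over defaults, and validate a pipeline config.

    ``path=None`` (or an empty file) yields the all-defaults config. Raises
    :class:`ConfigError` carrying every violation found.
    """
    violations: list[str] = []
    base = load_default_config()
    user: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError([f"YAML parse failure in {path}: {exc}"]) from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError([f"top level of {path} must be a mapping"])
            user = loaded
    merged = _merge(base, user, "", violations)
    if overrides:
        merged = _merge(merged, overrides, "", violations)
    _check(merged, violations)
    if violations:
        raise ConfigError(violations)
    return PipelineConfig(raw=merged)
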