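"""Synthetic DSC thermograms with a collagen denaturation endotherm.

Heat flow is modeled endotherm-down: a linear instrumental baseline minus a
Gaussian endotherm centered at the denaturation temperature Td, plus detector
noise. Collagenous tissue shows this transition as a single broad peak in the
60-70 degC band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..thermal import Thermogram

__all__ = ["ThermogramParams", "generate_thermogram"]


@dataclass(frozen=True)
class ThermogramParams:
    """Endotherm shape, baseline and scan settings (10-95 degC at 5 degC/min)."""

    td_C: float
    peak_width_C: float = 2.0  # Gaussian sigma
    peak_depth_mW: float = 1.0
    baseline_intercept_mW: float = 0.0
    baseline_slope_mW_per_C: float = 0.0
    t_start_C: float = 10.0
    t_end_C: float = 95.0
    heating_rate_C_min: float = 5.0
    sampling_interval_C: float = 0.1
    noise_sd_mW: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_start_C < self.td_C < self.t_end_C:
            raise ValueError(
                f"td_C={self.td_C} must lie inside the scan range "
                f"({self.t_start_C}, {self.t_end_C})"
            )
        if self.peak_width_C <= 0:
            raise ValueError("peak_width_C must be > 0")
        if self.sampling_interval_C <= 0:
            raise ValueError("sampling_interval_C must be > 0")
        if self.heating_rate_C_min <= 0:
            raise ValueError("heating_rate_C_min must be > 0")
        if self.peak_depth_mW < 0 or self.noise_sd_mW < 0:
            raise ValueError("peak_depth_mW and noise_sd_mW must be >= 0")


def generate_thermogram(params: ThermogramParams) -> Thermogram:
    """Simulate one scan; deterministic for a fixed seed."""
    p = params
    n = int(np.floor((p.t_end_C - p.t_start_C) / p.sampling_interval_C)) + 1
    temperature_C = p.t_start_C + np.arange(n) * p.sampling_interval_C
    baseline = p.baseline_intercept_mW + p.baseline_slope_mW_per_C * temperature_C
    endotherm = p.peak_depth_mW * np.exp(-((temperature_C - p.td_C) ** 2) / (2 * p.peak_width_C**2))
    heat_flow_mW = baseline - endotherm
    if p.noise_sd_mW > 0:
        rng = np.random.default_rng(p.seed)
        heat_flow_mW = heat_flow_mW + rng.normal(0.0, p.noise_sd_mW, size=n)
    return Thermogram(temperature_C=temperature_C, heat_flow_mW=heat_flow_mW)
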