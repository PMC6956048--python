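"""Synthetic uniaxial tensile records for corneal strips.

Corneal strip tests produce J-shaped load-displacement curves: a compliant toe
region (fibril uncrimping) followed by progressive stiffening. The generator
supports a pure linear law (sigma = E epsilon) and a toe-exponential law
(sigma = A (exp(r epsilon) - 1)), converts stress to load through the strip
cross-section, and lays the record out on a constant-rate displacement ramp
exactly as a screw-driven test frame would record it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ..mechanics import TensileRecord

__all__ = ["TensileParams", "generate_tensile_record", "analytic_tangent_modulus"]


@dataclass(frozen=True)
class TensileParams:
    """Material law, strip geometry and acquisition settings.

    Defaults follow the tested protocol: 5 mm wide strips pulled at 0.1 mm/s.
    ``gauge_length_mm`` has no protocol default and must be supplied.
    """

    gauge_length_mm: float
    model: Literal["linear", "toe-exponential"] = "toe-exponential"
    E_linear: float = 5.0  # MPa, linear law only
    toe_amplitude: float = 0.05  # MPa
    toe_rate: float = 8.0  # dimensionless exponent scale
    strip_width_mm: float = 5.0
    thickness_mm: float = 0.4
    displacement_rate_mm_s: float = 0.1
    max_strain: float = 0.4
    sampling_hz: float = 10.0
    noise_sd_N: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gauge_length_mm",
            "strip_width_mm",
            "thickness_mm",
            "displacement_rate_mm_s",
            "sampling_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.max_strain <= 1.0:
            raise ValueError("max_strain must lie in (0, 1]")
        if self.noise_sd_N < 0:
            raise ValueError("noise_sd_N must be >= 0")
        if self.model not in ("linear", "toe-exponential"):
            raise ValueError(f"unknown model {self.model!r}")


def _stress_MPa(params: TensileParams, strain: np.ndarray) -> np.ndarray:
    if params.model == "linear":
        return params.E_linear * strain
    return params.toe_amplitude * np.expm1(params.toe_rate * strain)


def analytic_tangent_modulus(params: TensileParams, strain: np.ndarray | float) -> np.ndarray:
    """Closed-form tangent stiffness d sigma / d epsilon of the material law."""
    strain = np.asarray(strain, dtype=float)
    if params.model == "linear":
        return np.full_like(strain, params.E_linear)
    return params.toe_amplitude * params.toe_rate * np.exp(params.toe_rate * strain)


def generate_tensile_record(params: TensileParams) -> TensileRecord:
    """Simulate one strip test; deterministic for a fixed seed.

    Displacement ramps at ``displacement_rate_mm_s`` until the strain reaches
    ``max_strain``; load is stress x initial cross-section plus additive
    Gaussian load-cell noise.
    """
    rng = np.random.default_rng(params.seed)
    duration_s = params.max_strain * params.gauge_length_mm / params.displacement_rate_mm_s
    n = max(3, int(np.floor(duration_s * params.sampling_hz)) + 1)
    time_s = np.arange(n) / params.sampling_hz
    displacement_mm = params.displacement_rate_mm_s * time_s
    strain = displacement_mm / params.gauge_length_mm
    stress = _stress_MPa(params, strain)
    area_mm2 = params.strip_width_mm * params.thickness_mm
    load_N = stress * area_mm2  # MPa x mm^2 = N
    if params.noise_sd_N > 0:
        load_N = load_N + rng.normal(0.0, params.noise_sd_N, size=n)
    return TensileRecord(
        time_s=time_s,
        displacement_mm=displacement_mm,
        load_N=load_N,
        strip_width_mm=params.strip_width_mm,
        thickness_mm=params.thickness_mm,
        gauge_length_mm=params.gauge_length_mm,
    )
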