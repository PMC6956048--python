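"""Reduction of uniaxial tensile records to Young's modulus.

Engineering conventions throughout: stress = load / initial cross-section
(N / mm^2 = MPa), strain = grip displacement / gauge length, no cross-section
updating. Because soft-tissue curves are J-shaped, the modulus is the
least-squares tangent slope over a configurable high-strain window (default
70-90% of the maximum strain), where fibrils are recruited and the response is
closest to linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TensileRecord",
    "StressStrainCurve",
    "ModulusEstimate",
    "compute_stress_strain",
    "estimate_modulus",
]


@dataclass
class TensileRecord:
    """Raw test-frame output plus the strip geometry needed for reduction."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    load_N: np.ndarray
    strip_width_mm: float
    thickness_mm: float
    gauge_length_mm: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.load_N = np.asarray(self.load_N, dtype=float)
        n = len(self.time_s)
        if not (len(self.displacement_mm) == len(self.load_N) == n) or n < 3:
            raise ValueError("time/displacement/load must have equal length >= 3")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if min(self.strip_width_mm, self.thickness_mm, self.gauge_length_mm) <= 0:
            raise ValueError("strip geometry must be > 0")


@dataclass
class StressStrainCurve:
    strain: np.ndarray  # dimensionless, zeroed at the first sample
    stress_MPa: np.ndarray


@dataclass
class ModulusEstimate:
    young_modulus_MPa: float
    fit_strain_lo: float
    fit_strain_hi: float
    r_squared: float
    n_points: int


def compute_stress_strain(record: TensileRecord) -> StressStrainCurve:
    """Engineering stress-strain from a raw record; order-preserving."""
    area_mm2 = record.strip_width_mm * record.thickness_mm
    stress = record.load_N / area_mm2
    strain = (record.displacement_mm - record.displacement_mm[0]) / record.gauge_length_mm
    return StressStrainCurve(strain=strain, stress_MPa=stress)


def estimate_modulus(
    curve: StressStrainCurve,
    fit_lo_frac: float = 0.7,
    fit_hi_frac: float = 0.9,
) -> ModulusEstimate:
    """OLS slope of stress vs strain over [lo, hi] x max(strain).

    Raises ``ValueError`` if the window holds fewer than two points.
    """
    if not 0.0 <= fit_lo_frac < fit_hi_frac <= 1.0:
        raise ValueError("need 0 <= fit_lo_frac < fit_hi_frac <= 1")
    eps_max = float(np.max(curve.strain))
    lo, hi = fit_lo_frac * eps_max, fit_hi_frac * eps_max
    sel = (curve.strain >= lo) & (curve.strain <= hi)
    n = int(np.count_nonzero(sel))
    if n < 2:
        raise ValueError(f"fit window [{lo:.4g}, {hi:.4g}] contains {n} point(s); need >= 2")
    fit = stats.linregress(curve.strain[sel], curve.stress_MPa[sel])
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return ModulusEstimate(
        young_modulus_MPa=float(fit.slope),
        fit_strain_lo=float(lo),
        fit_strain_hi=float(hi),
        r_squared=min(1.0, r2),
        n_points=n,
    )
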