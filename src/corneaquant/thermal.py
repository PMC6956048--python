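"""Denaturation-temperature detection in DSC thermograms.

Collagen denaturation shows as a single broad endotherm. Td is taken as the
peak temperature (not onset): a linear instrumental baseline is fit through
the mean heat flow of a pre-transition and a post-transition window, the
baseline is subtracted, and the extremum of the residual endotherm is located
and refined below grid resolution by fitting a Gaussian peak profile over the
span around the half-height crossing points (collagen endotherms are broad
and nearly symmetric, so the Gaussian profile is the standard peak model);
a quadratic vertex fit and 3-point parabolic refinement serve as fallbacks
when the profile fit cannot converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Thermogram", "DenaturationResult", "NoPeakError", "detect_denaturation"]


class NoPeakError(ValueError):
    """The baseline-subtracted trace holds no resolvable endotherm."""


@dataclass
class Thermogram:
    temperature_C: np.ndarray
    heat_flow_mW: np.ndarray

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.heat_flow_mW = np.asarray(self.heat_flow_mW, dtype=float)
        if len(self.temperature_C) != len(self.heat_flow_mW) or len(self.temperature_C) < 5:
            raise ValueError("temperature and heat flow must have equal length >= 5")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperature must be strictly increasing")


@dataclass
class DenaturationResult:
    td_C: float
    peak_height_mW: float  # baseline-subtracted endotherm magnitude, >= 0
    baseline: tuple[float, float]  # (intercept mW, slope mW/degC)
    pre_window_C: tuple[float, float]
    post_window_C: tuple[float, float]
    warnings: list[str] = field(default_factory=list)


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (t >= lo) & (t <= hi)


def detect_denaturation(
    tg: Thermogram,
    pre_window_C: tuple[float, float] | None = None,
    post_window_C: tuple[float, float] | None = None,
    *,
    endotherm_down: bool = True,
) -> DenaturationResult:
    """Locate the denaturation endotherm of a thermogram.

    ``pre_window_C`` / ``post_window_C`` delimit transition-free stretches used
    for the baseline; by default the first and last 10% of the scan range.
    ``endotherm_down`` selects the sign convention (endothermic events plotted
    downward by default; set False for exo-down instruments).

    Raises :class:`NoPeakError` when the residual extremum does not exceed
    3x the noise level (MAD estimated inside the baseline windows).
    """
    t, hf = tg.temperature_C, tg.heat_flow_mW
    span = t[-1] - t[0]
    if pre_window_C is None:
        pre_window_C = (float(t[0]), float(t[0] + 0.1 * span))
    if post_window_C is None:
        post_window_C = (float(t[-1] - 0.1 * span), float(t[-1]))
    for name, win in (("pre", pre_window_C), ("post", post_window_C)):
        if win[0] < t[0] - 1e-9 or win[1] > t[-1] + 1e-9 or win[0] >= win[1]:
            raise ValueError(f"{name}_window {win} outside scan range or inverted")
    if pre_window_C[1] > post_window_C[0]:
        raise ValueError("baseline windows must be disjoint (pre before post)")
    pre = _window_mask(t, pre_window_C)
    post = _window_mask(t, post_window_C)
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("each baseline window must contain >= 2 samples")

    # baseline through the two window mean points
    t_pre, y_pre = t[pre].mean(), hf[pre].mean()
    t_post, y_post = t[post].mean(), hf[post].mean()
    slope = (y_post - y_pre) / (t_post - t_pre)
    intercept = y_pre - slope * t_pre
    resid = hf - (intercept + slope * t)
    if not endotherm_down:
        resid = -resid

    noise = 1.4826 * float(np.median(np.abs(resid[pre | post])))
    # locate the peak on a lightly smoothed copy so a single noise spike on a
    # shoulder cannot win the argmin or collapse the half-height span; the
    # sub-grid profile fit below still uses the raw residual
    from scipy.ndimage import gaussian_filter1d

    smooth = gaussian_filter1d(resid, sigma=3.0, mode="reflect")
    i_min = int(np.argmin(smooth))
    height = -float(resid[i_min])
    scale = max(float(np.max(np.abs(hf))), 1.0)
    if height < max(3.0 * noise, 1e-9 * scale):
        raise NoPeakError(
            f"no endotherm: residual extremum {height:.3g} mW below detection "
            f"threshold {max(3.0 * noise, 1e-9 * scale):.3g} mW"
        )

    # half-height span around the (smoothed) minimum
    half = float(smooth[i_min]) / 2.0
    lo = i_min
    while lo > 0 and smooth[lo - 1] <= half:
        lo -= 1
    hi = i_min
    while hi < len(t) - 1 and smooth[hi + 1] <= half:
        hi += 1

    td = _refine_vertex(t, resid, smooth, lo, hi, i_min)
    td = float(np.clip(td, t[0], t[-1]))

    warnings: list[str] = []
    for name, win in (("pre", pre_window_C), ("post", post_window_C)):
        if win[1] >= t[lo] and win[0] <= t[hi]:
            warnings.append(
                f"{name} baseline window {win} overlaps the peak half-height span "
                f"({t[lo]:.2f}, {t[hi]:.2f}) degC; baseline may be biased"
            )

    return DenaturationResult(
        td_C=td,
        peak_height_mW=height,
        baseline=(float(intercept), float(slope)),
        pre_window_C=pre_window_C,
        post_window_C=post_window_C,
        warnings=warnings,
    )


def _refine_vertex(
    t: np.ndarray, resid: np.ndarray, smooth: np.ndarray, lo: int, hi: int, i_min: int
) -> float:
    """Sub-grid peak position: Gaussian profile fit around the half-height
    span, quadratic vertex / 3-point parabola as fallbacks."""
    half_span = max(t[hi] - t[i_min], t[i_min] - t[lo])
    if half_span > 0 and hi - lo + 1 >= 5:
        sigma0 = half_span / 1.177  # half-height crossing of a Gaussian is at 1.177 sigma
        sel = (t >= t[i_min] - 2.5 * sigma0) & (t <= t[i_min] + 2.5 * sigma0)
        if sel.sum() >= 6:
            from scipy.optimize import curve_fit

            def neg_gauss(x, depth, center, sigma):
                return -depth * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))

            try:
                popt, _ = curve_fit(
                    neg_gauss,
                    t[sel],
                    resid[sel],
                    p0=(-resid[i_min], t[i_min], sigma0),
                    maxfev=2000,
                )
                center = float(popt[1])
                if popt[0] > 0 and t[lo] <= center <= t[hi]:
                    return center
            except RuntimeError:
                pass
    if hi - lo + 1 >= 5:
        # center the abscissa for conditioning
        tt = t[lo : hi + 1] - t[i_min]
        c = np.polyfit(tt, smooth[lo : hi + 1], 2)
        if c[0] > 0:  # convex, vertex is a minimum
            vertex = -c[1] / (2.0 * c[0]) + t[i_min]
            if t[lo] <= vertex <= t[hi]:
                return float(vertex)
    # 3-point parabolic refinement on the raw grid minimum
    if 0 < i_min < len(t) - 1:
        y0, y1, y2 = smooth[i_min - 1], smooth[i_min], smooth[i_min + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            step = (t[i_min + 1] - t[i_min - 1]) / 2.0
            return float(t[i_min] + np.clip(delta, -1, 1) * step)
    return float(t[i_min])
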