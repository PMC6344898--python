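"""Fluorescence recovery after photobleaching (FRAP) analysis.

A circular nuclear region (radius ``r``, 2 um in cells, 5 um in solution) is
bleached in a single frame and the recovery recorded.  Traces carry three
ROIs: the bleached spot (ROI1), an unbleached reference within the same
nucleus (ROI2) and a background area (ROI3).  Processing follows the classic
double-normalization scheme: background subtraction, division by the
reference to remove acquisition bleaching, and scaling by the prebleach
ratio so the prebleach level is 1.

The post-bleach recovery is fitted with the single-exponential model

    F(t) = a (1 - exp(-t / tau)) + c,        t = 0 at the first post-bleach
                                              frame

from which t_half = tau ln 2, the effective diffusion coefficient
D = 0.88 r^2 / (4 t_half) and, on prebleach-normalized traces, the immobile
fraction 1 - (plateau - F0)/(1 - F0) with plateau = a + c and F0 = c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import (CorrectionUnderflowError, DegenerateBleachError,
                     FitFailureError, InvalidParameterError)


@dataclass
class RecoveryTrace:
    """Raw three-ROI FRAP time series on a uniform frame grid."""

    time: np.ndarray  # s
    roi_bleach: np.ndarray  # ROI1, counts
    roi_reference: np.ndarray  # ROI2, counts
    roi_background: np.ndarray  # ROI3, counts
    n_prebleach: int = 10
    bleach_radius: float = 2.0  # um

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.roi_bleach = np.asarray(self.roi_bleach, dtype=float)
        self.roi_reference = np.asarray(self.roi_reference, dtype=float)
        self.roi_background = np.asarray(self.roi_background, dtype=float)
        n = self.time.size
        if not (self.roi_bleach.size == self.roi_reference.size
                == self.roi_background.size == n):
            raise InvalidParameterError("ROI traces must share one length")
        if self.n_prebleach < 1:
            raise InvalidParameterError("need >= 1 prebleach frame")
        if self.bleach_radius <= 0:
            raise InvalidParameterError("bleach_radius must be > 0")


@dataclass
class NormalizedTrace:
    """Background-subtracted, bleach-corrected, normalized recovery."""

    time: np.ndarray
    values: np.ndarray
    n_prebleach: int
    bleach_radius: float
    mode: str  # "prebleach" | "plateau"


@dataclass
class FrapFit:
    """Fitted recovery parameters and derived mobility quantities."""

    a: float
    tau: float  # s
    c: float
    t_half: float  # s, tau * ln 2
    r2: float
    normalization_mode: str
    bleach_radius: float
    D: float | None = None  # um^2/s
    immobile_fraction: float | None = None
    immobile_clamped: bool = False
    converged: bool = True


def preprocess_recovery(trace: RecoveryTrace, mode: str = "prebleach",
                        smooth_correction: bool = True) -> NormalizedTrace:
    """Double-normalize a raw trace.

    F_norm(t) = [(ROI1 - ROI3)/(ROI2 - ROI3)] *
                [mean_pre(ROI2 - ROI3)/mean_pre(ROI1 - ROI3)]

    which cancels any multiplicative acquisition bleaching shared with the
    reference ROI and sets the prebleach level to 1.  With
    ``smooth_correction`` (default) the background is replaced by its mean
    and the reference by a fitted exponential decay, so their frame noise is
    not injected multiplicatively into the recovery; both reductions are
    exact for a flat background and exponential acquisition bleaching.
    ``mode="plateau"`` defers an additional division by the fitted asymptote
    to :func:`fit_recovery`.
    """
    if mode not in ("prebleach", "plateau"):
        raise InvalidParameterError(f"unknown normalization mode {mode!r}")
    npre = trace.n_prebleach
    bg = trace.roi_background
    if smooth_correction:
        bg = np.full_like(trace.roi_background, trace.roi_background.mean())
    sig = trace.roi_bleach - bg
    ref = trace.roi_reference - bg
    if np.any(ref <= 0):
        raise CorrectionUnderflowError(
            "reference ROI fell to or below background; cannot correct "
            "for acquisition bleaching")
    if smooth_correction:
        # exponential model of acquisition bleaching, exact in the
        # noise-free limit; log-linear least squares
        beta, log_a = np.polyfit(trace.time, np.log(ref), 1)
        ref = np.exp(log_a + beta * trace.time)
    pre_ratio = ref[:npre].mean() / sig[:npre].mean()
    values = (sig / ref) * pre_ratio
    return NormalizedTrace(time=trace.time.copy(), values=values,
                           n_prebleach=npre,
                           bleach_radius=trace.bleach_radius, mode=mode)


def _exp_model(t, a, tau, c):
    return c + a * (1.0 - np.exp(-t / tau))


def fit_recovery(norm: NormalizedTrace,
                 tau_grid: tuple[float, ...] = (0.25, 1.0, 4.0, 16.0)) -> FrapFit:
    """Nonlinear least squares of a(1 - exp(-t/tau)) + c on post-bleach frames.

    ``t = 0`` at the first post-bleach frame.  Initialization: c0 = first
    post-bleach value, a0 = last value - c0, tau0 = time to reach
    c0 + a0 (1 - 1/e); on failure the fit restarts over a grid of tau
    multiples before raising :class:`FitFailureError`.
    """
    npre = norm.n_prebleach
    t = norm.time[npre:] - norm.time[npre]
    y = norm.values[npre:]
    if t.size < 10:
        raise InvalidParameterError("need >= 10 post-bleach frames")
    c0 = float(y[0])
    a0 = float(y[-1] - c0)
    target = c0 + a0 * (1.0 - math.exp(-1.0))
    idx = int(np.argmin(np.abs(y - target)))
    dt = float(t[1] - t[0])
    tau0 = max(float(t[idx]), dt)

    last_err = None
    for mult in (1.0,) + tuple(tau_grid):
        try:
            popt, _ = curve_fit(_exp_model, t, y, p0=[a0, tau0 * mult, c0],
                                bounds=([-np.inf, 1e-6, -np.inf],
                                        [np.inf, 1e6, np.inf]),
                                maxfev=20000)
            break
        except RuntimeError as err:  # pragma: no cover - rare non-convergence
            last_err = err
    else:  # pragma: no cover
        raise FitFailureError("recovery fit did not converge",
                              {"tau0": tau0, "grid": tau_grid,
                               "last_error": str(last_err)})
    a, tau, c = (float(v) for v in popt)
    resid = y - _exp_model(t, a, tau, c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    if norm.mode == "plateau":
        plateau = a + c
        if plateau <= 0:
            raise FitFailureError("fitted asymptote is not positive",
                                  {"a": a, "c": c})
        a, c = a / plateau, c / plateau
    t_half = tau * math.log(2)
    return FrapFit(a=a, tau=tau, c=c, t_half=t_half, r2=r2,
                   normalization_mode=norm.mode,
                   bleach_radius=norm.bleach_radius)


def diffusion_coefficient(t_half: float, radius: float) -> float:
    """Effective diffusion coefficient D = 0.88 r^2 / (4 t_half), um^2/s."""
    if t_half <= 0 or radius <= 0:
        raise InvalidParameterError("t_half and radius must be > 0")
    return 0.88 * radius ** 2 / (4.0 * t_half)


def immobile_fraction(fit: FrapFit) -> FrapFit:
    """Immobile fraction from a prebleach-normalized fit.

    mobile = (plateau - F0) / (1 - F0) with plateau = a + c, F0 = c;
    immobile = 1 - mobile, clamped to [0, 1] with clamping reported on the
    returned fit.
    """
    if fit.normalization_mode != "prebleach":
        raise InvalidParameterError(
            "immobile fraction requires prebleach normalization")
    if fit.c >= 1.0:
        raise DegenerateBleachError(
            f"post-bleach offset c = {fit.c:.3g} >= 1: no bleach depth")
    mobile = (fit.a + fit.c - fit.c) / (1.0 - fit.c)
    immobile = 1.0 - mobile
    clamped = not 0.0 <= immobile <= 1.0
    immobile = float(np.clip(immobile, 0.0, 1.0))
    return replace(fit, immobile_fraction=immobile, immobile_clamped=clamped)


def analyze_trace(trace: RecoveryTrace, mode: str = "prebleach") -> FrapFit:
    """Convenience chain: preprocess -> fit -> D (and immobile fraction in
    prebleach mode)."""
    norm = preprocess_recovery(trace, mode=mode)
    fit = fit_recovery(norm)
    fit.D = diffusion_coefficient(fit.t_half, trace.bleach_radius)
    if mode == "prebleach":
        fit = immobile_fraction(fit)
    return fit
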