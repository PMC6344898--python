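"""Fluorescence correlation spectroscopy: ACF estimation and model fitting.

Intensity fluctuations of emitters crossing the confocal detection volume
are summarized by the normalized autocorrelation

    G(tau) = <dI(t) dI(t+tau)> / <I>^2 .

Two estimators are provided: the standard multi-tau scheme (m = 16 doubling
cascade with symmetric normalization), suitable for long traces with
quasi-logarithmic lag coverage, and a direct estimator that evaluates the
definition at every integer lag and serves as the brute-force reference.

Fits use the 2D free-diffusion model with a multiplicative triplet
(dark-state) term at fixed triplet lifetime tau_T:

    G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + T/(1-T) exp(-tau/tau_T))

N, the mean particle number in the detection area, converts to a molar
concentration through a calibrated effective volume; with a reference dye of
known diffusion coefficient D_ref, w0 = sqrt(4 D_ref tau_D,ref) and
V_eff = pi^(3/2) w0^3 kappa for a configurable axial aspect ratio kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .budget import AVOGADRO
from .errors import (FitFailureError, InvalidParameterError,
                     UndefinedNormalizationError)


@dataclass
class IntensityTrace:
    """Binned photon counts from one FCS point measurement."""

    counts: np.ndarray
    bin_time: float  # s

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.bin_time <= 0:
            raise InvalidParameterError("bin_time must be > 0")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be >= 0")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_time


@dataclass
class AcfCurve:
    """Autocorrelation amplitudes on a (quasi-logarithmic) lag grid."""

    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    estimator: str

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise InvalidParameterError("G must be finite")


@dataclass
class FcsFit:
    """Fitted ACF parameters and derived concentration."""

    N: float
    tau_D: float  # s
    T: float  # triplet fraction
    tau_T: float  # s, fixed
    r2: float
    w0: float | None = None  # um
    effective_volume: float | None = None  # L
    concentration: float | None = None  # mol/L


def _prepare(trace: IntensityTrace):
    c = np.asarray(trace.counts, dtype=np.float64)
    if c.size < 64:
        raise InvalidParameterError("trace must have >= 64 bins")
    if c.mean() <= 0:
        raise UndefinedNormalizationError(
            "zero-mean trace: G(tau) normalization undefined")
    return c


def _direct_acf(c: np.ndarray, bin_time: float, max_lag: int | None):
    n = c.size
    if max_lag is None:
        max_lag = n // 4
    max_lag = min(max_lag, n - 2)
    lags = np.arange(1, max_lag + 1)
    G = np.empty(lags.size)
    for i, k in enumerate(lags):
        head, tail = c[:n - k], c[k:]
        G[i] = (np.dot(head, tail) / (n - k)) / (head.mean() * tail.mean()) - 1.0
    return lags * bin_time, G


def _multi_tau_acf(c: np.ndarray, bin_time: float, m: int):
    if m % 2:
        raise InvalidParameterError("m must be even")
    lags, G = [], []
    level_dt = bin_time
    first = True
    while c.size >= 2 * m:
        n = c.size
        ks = range(1, m + 1) if first else range(m // 2 + 1, m + 1)
        for k in ks:
            head, tail = c[:n - k], c[k:]
            # symmetric normalization: each segment by its own mean
            G.append((np.dot(head, tail) / (n - k))
                     / (head.mean() * tail.mean()) - 1.0)
            lags.append(k * level_dt)
        n2 = (n // 2) * 2
        c = 0.5 * (c[:n2:2] + c[1:n2:2])
        level_dt *= 2.0
        first = False
    return np.asarray(lags), np.asarray(G)


def autocorrelate(trace: IntensityTrace, estimator: str = "multi_tau",
                  m: int = 16, max_lag: int | None = None) -> AcfCurve:
    """Estimate G(tau) from a binned intensity trace.

    ``estimator="multi_tau"`` uses the m = 16 doubling cascade with
    symmetric normalization; ``"direct"`` evaluates the definition at every
    integer lag up to ``max_lag`` (default n/4) and is the brute-force
    reference for short traces.
    """
    c = _prepare(trace)
    if estimator == "direct":
        lags, G = _direct_acf(c, trace.bin_time, max_lag)
    elif estimator == "multi_tau":
        lags, G = _multi_tau_acf(c, trace.bin_time, m)
    else:
        raise InvalidParameterError(f"unknown estimator {estimator!r}")
    return AcfCurve(lags=lags, G=G, estimator=estimator)


def diffusion_triplet_model(tau, N, tau_D, T, tau_T=4e-6):
    """2D diffusion ACF with multiplicative triplet term."""
    tau = np.asarray(tau, dtype=float)
    g = (1.0 / N) / (1.0 + tau / tau_D)
    if T > 0:
        g = g * (1.0 + T / (1.0 - T) * np.exp(-tau / tau_T))
    return g


def fit_acf(curve: AcfCurve, fix_tau_T: float = 4e-6,
            lag_range: tuple[float, float] | None = None,
            weights: np.ndarray | None = None,
            skip_first: int = 1) -> FcsFit:
    """Weighted nonlinear least squares of the 2D-diffusion + triplet model.

    The first ``skip_first`` lags are excluded (detector shot noise
    dominates the zero-lag region); ``lag_range`` further restricts the
    window.  T is bounded to [0, 0.5]; tau_T is held fixed.  Initialization:
    N0 = 1/G(first used lag), tau_D0 = lag where G falls to half its initial
    value.
    """
    lags, G = curve.lags, curve.G
    sel = np.ones(lags.size, dtype=bool)
    sel[:skip_first] = False
    if lag_range is not None:
        sel &= (lags >= lag_range[0]) & (lags <= lag_range[1])
    lags, G = lags[sel], G[sel]
    if lags.size < 5:
        raise InvalidParameterError("fewer than 5 lags in the fit window")
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[sel]
        sigma = 1.0 / np.sqrt(np.clip(w, 1e-300, None))
    g0 = float(G[0])
    if g0 <= 0:
        raise FitFailureError("non-positive initial ACF amplitude",
                              {"G0": g0})
    n0 = 1.0 / g0
    half_idx = int(np.argmin(np.abs(G - g0 / 2.0)))
    tau_d0 = float(lags[half_idx])

    def model(tau, N, tau_D, T):
        return diffusion_triplet_model(tau, N, tau_D, T, tau_T=fix_tau_T)

    try:
        popt, _ = curve_fit(model, lags, G, p0=[n0, tau_d0, 0.05],
                            sigma=sigma,
                            bounds=([1e-6, 1e-9, 0.0],
                                    [1e9, 1e3, 0.5]), maxfev=20000)
    except RuntimeError as err:
        raise FitFailureError("ACF fit did not converge",
                              {"N0": n0, "tau_D0": tau_d0,
                               "error": str(err)}) from err
    N, tau_D, T = (float(v) for v in popt)
    resid = G - model(lags, N, tau_D, T)
    ss_tot = float(np.sum((G - G.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return FcsFit(N=N, tau_D=tau_D, T=T, tau_T=fix_tau_T, r2=r2)


def calibrate_volume(fit_ref: FcsFit, D_ref: float,
                     kappa: float = 5.0) -> tuple[float, float]:
    """Effective detection volume from a reference dye of known D.

    w0 = sqrt(4 D_ref tau_D) (um); V_eff = pi^(3/2) w0^3 kappa converted to
    litres (1 um^3 = 1e-15 L).  kappa is the axial-to-lateral aspect ratio
    closing the gap between the 2D fit model and the 3D observation volume.
    """
    if D_ref <= 0 or fit_ref.tau_D <= 0:
        raise InvalidParameterError("D_ref and tau_D must be > 0")
    w0 = math.sqrt(4.0 * D_ref * fit_ref.tau_D)
    v_eff_um3 = math.pi ** 1.5 * w0 ** 3 * kappa
    return w0, v_eff_um3 * 1e-15


def effective_volume_from_reference(N_ref: float, c_ref: float) -> float:
    """Direct calibration: V_eff = N_ref / (c_ref N_A), litres."""
    if N_ref <= 0 or c_ref <= 0:
        raise InvalidParameterError("N_ref and c_ref must be > 0")
    return N_ref / (c_ref * AVOGADRO)


def concentration_from_fit(fit: FcsFit, effective_volume: float) -> float:
    """Molar concentration c = N / (V_eff N_A)."""
    if effective_volume <= 0:
        raise InvalidParameterError("effective_volume must be > 0")
    return fit.N / (effective_volume * AVOGADRO)
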