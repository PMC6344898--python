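"""Photon-count -> molar-concentration calibration.

In photon-counting mode a hybrid detector returns discrete counts whose
expectation is linear in fluorophore concentration.  A dilution series of the
labelled compound (e.g. 0.1-1 uM standards) imaged under fixed acquisition
settings yields an affine calibration

    counts = slope * concentration + intercept

whose inverse translates whole images into absolute concentration maps.  The
fit is affine rather than through the origin: images carry detector/ambient
background, and the intercept doubles as that background estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateCalibrationError, InsufficientStandardsError


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine map between photon counts and molar concentration.

    Attributes
    ----------
    channel : detection channel identifier.
    slope : counts per (mol/L).
    intercept : background counts at zero concentration.
    concentration_range : (min, max) mol/L spanned by the standards.
    fit_r2 : coefficient of determination of the fit.
    """

    channel: str
    slope: float
    intercept: float
    concentration_range: tuple[float, float]
    fit_r2: float

    def __post_init__(self):
        if self.slope <= 0:
            raise DegenerateCalibrationError(
                f"calibration slope must be > 0, got {self.slope}")
        if self.concentration_range[0] < 0:
            raise ValueError("concentration range must be non-negative")

    def expected_counts(self, concentration):
        """Forward map: expected counts at a given molar concentration."""
        return self.slope * np.asarray(concentration) + self.intercept


@dataclass
class ConcentrationMap:
    """Per-pixel molar concentrations derived from a photon-count image.

    ``n_clamped`` counts pixels whose raw estimate fell below zero and was
    clamped; ``extrapolated`` flags pixels above the calibrated range.
    """

    values: np.ndarray  # mol/L, float32
    n_clamped: int
    extrapolated: np.ndarray  # bool mask
    curve: CalibrationCurve


def fit_calibration(standards: Sequence[tuple[float, float]],
                    channel: str = "default") -> CalibrationCurve:
    """Ordinary least-squares affine fit of counts against concentration.

    Parameters
    ----------
    standards : sequence of (concentration mol/L, mean counts) pairs.
    channel : identifier stored on the curve.

    Raises
    ------
    InsufficientStandardsError : fewer than 3 standards or < 2 distinct
        concentrations.
    DegenerateCalibrationError : fitted slope <= 0.
    """
    standards = list(standards)
    if len(standards) < 3:
        raise InsufficientStandardsError(
            f"need >= 3 standards, got {len(standards)}")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    cnts = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise InsufficientStandardsError("need >= 2 distinct concentrations")
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(design, cnts, rcond=None)
    resid = cnts - (slope * conc + intercept)
    ss_tot = float(np.sum((cnts - cnts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    # degenerate when the predicted count change over the calibrated range
    # is not meaningfully positive (guards exact-zero slopes against float fuzz)
    span = slope * (conc.max() - conc.min())
    if span <= 1e-9 * max(1.0, float(np.abs(cnts).max())):
        raise DegenerateCalibrationError(
            f"fitted slope {slope:.4g} counts per mol/L is not positive")
    return CalibrationCurve(channel=channel, slope=float(slope),
                            intercept=float(intercept),
                            concentration_range=(float(conc.min()), float(conc.max())),
                            fit_r2=float(np.clip(r2, 0.0, 1.0)))


def counts_to_concentration(image: np.ndarray,
                            curve: CalibrationCurve) -> ConcentrationMap:
    """Invert the calibration per pixel: c = (counts - intercept) / slope.

    Negative estimates are clamped to zero (and counted, never hidden);
    pixels above the calibrated concentration range are flagged as
    extrapolated.
    """
    img = np.asarray(image, dtype=np.float64)
    conc = (img - curve.intercept) / curve.slope
    n_clamped = int(np.count_nonzero(conc < 0))
    np.clip(conc, 0.0, None, out=conc)
    extrapolated = conc > curve.concentration_range[1]
    return ConcentrationMap(values=conc.astype(np.float32),
                            n_clamped=n_clamped,
                            extrapolated=extrapolated,
                            curve=curve)


def accumulate_frames(frames: np.ndarray) -> np.ndarray:
    """Average accumulated photon-count frames to a per-frame count scale.

    Acquisitions accumulate 10-15 frames to collect enough photons from dim
    structures; calibration operates on the per-frame mean so that the count
    scale matches single-frame standards.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim < 3:
        return frames
    return frames.mean(axis=0)
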