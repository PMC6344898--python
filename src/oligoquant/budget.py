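"""Concentration -> absolute copy-number budgets for cellular compartments.

The headline arithmetic of the study: a measured molar concentration times a
compartment volume times Avogadro's number gives the absolute number of
oligonucleotide molecules in that compartment.  Default volumes follow the
values adopted for MCF-7 cells: whole cell 2000 fl, nucleus 1180 fl, single
endo-lysosomal vesicle 1.014 fl, with on average 52 vesicles per cell.

Headline numbers are reported rounded to two significant figures because the
chained per-cell figure (copies/vesicle x vesicles/cell) only reproduces
under round-then-multiply; exact values are always carried alongside.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: 2019 SI exact value, 1/mol.
AVOGADRO = 6.02214076e23

#: Default compartment volumes in litres.
DEFAULT_VOLUMES_L = {
    "cell": 2000e-15,
    "nucleus": 1180e-15,
    "vesicle": 1.014e-15,
}

#: Mean number of endo-lysosomal vesicles per cell.
DEFAULT_VESICLES_PER_CELL = 52

_UNIT_SCALES = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "μm": 1e-6, "nm": 1e-9, "pm": 1e-12,
    "l": 1.0, "ml": 1e-3, "ul": 1e-6, "μl": 1e-6, "nl": 1e-9,
    "pl": 1e-12, "fl": 1e-15,
}


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def parse_quantity(text: str) -> float:
    """Parse ``"296nM"`` or ``"1180fl"`` into SI units (mol/L or L).

    Molar units use a capital trailing ``M``; volumes a lower-case ``l``.
    A bare number is returned unchanged (assumed already SI).
    """
    text = text.strip()
    m = re.fullmatch(r"([0-9.eE+-]+)\s*([a-zA-Zμ]*)", text)
    if not m:
        raise ValueError(f"cannot parse quantity {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    if not unit:
        return value
    key = unit.lower() if unit.endswith(("M", "L", "l")) else unit
    key = key[:-1].lower() + key[-1].lower() if len(key) > 1 else key.lower()
    key = key.replace("µ", "u")
    if key not in _UNIT_SCALES:
        raise ValueError(f"unknown unit {unit!r} in {text!r}")
    return value * _UNIT_SCALES[key]


@dataclass
class CompartmentBudget:
    """Absolute copy number for a named compartment.

    ``copies`` is exact (concentration x volume x N_A, times ``n_units`` for
    aggregated compartments); ``copies_rounded`` is the 2-significant-figure
    headline value.
    """

    compartment: str
    concentration: float  # mol/L
    volume: float  # L
    copies: float
    copies_rounded: float
    n_units: int = 1
    avogadro: float = field(default=AVOGADRO, repr=False)


def copies(concentration: float, volume: float, sig: int = 2) -> tuple[float, float]:
    """Molecule count in a compartment: concentration x volume x N_A.

    Parameters
    ----------
    concentration : mol/L
    volume : L
    sig : significant figures for the rounded headline value.

    Returns
    -------
    (exact, rounded) copy numbers.
    """
    if concentration < 0 or volume < 0:
        raise InvalidParameterError("concentration and volume must be >= 0")
    exact = concentration * volume * AVOGADRO
    return exact, round_sig(exact, sig)


def compartment_budget(compartment: str, concentration: float,
                       volume: float | None = None, n_units: int = 1) -> CompartmentBudget:
    """Budget for one compartment, defaulting the volume by compartment name."""
    if volume is None:
        volume = DEFAULT_VOLUMES_L[compartment]
    exact, rounded = copies(concentration, volume)
    exact *= n_units
    return CompartmentBudget(compartment, concentration, volume,
                             copies=exact,
                             copies_rounded=round_sig(rounded * n_units, 2),
                             n_units=n_units)


def vesicle_budget(vesicle_concentration: float,
                   vesicle_volume: float = DEFAULT_VOLUMES_L["vesicle"],
                   vesicles_per_cell: int = DEFAULT_VESICLES_PER_CELL,
                   ) -> tuple[float, float]:
    """Copies per vesicle and per cell's endosomal compartment.

    The per-cell value chains the *rounded* per-vesicle count times the
    vesicle count, then rounds again to two significant figures, matching the
    study's reporting convention (e.g. 12 000 x 52 -> 620 000).
    """
    if vesicle_concentration < 0 or vesicle_volume < 0 or vesicles_per_cell < 0:
        raise InvalidParameterError("all inputs must be >= 0")
    _, per_vesicle = copies(vesicle_concentration, vesicle_volume)
    per_cell = round_sig(per_vesicle * vesicles_per_cell, 2)
    return per_vesicle, per_cell


def injection_summary(stock_concentration: float,
                      intracellular_concentration: float,
                      cell_volume: float = DEFAULT_VOLUMES_L["cell"],
                      ) -> tuple[float, float, float]:
    """Dilution ratio, injected volume and injected copy number.

    ``dilution_ratio`` is intracellular/stock; the injected volume follows as
    ratio x cell volume, and the copy number as intracellular concentration x
    cell volume x N_A.
    """
    if stock_concentration <= 0:
        raise InvalidParameterError("stock concentration must be > 0")
    if intracellular_concentration < 0 or cell_volume < 0:
        raise InvalidParameterError("inputs must be >= 0")
    ratio = intracellular_concentration / stock_concentration
    if ratio > 1:
        warnings.warn("intracellular concentration exceeds stock "
                      "(dilution ratio > 1 is physically implausible)",
                      stacklevel=2)
    injected_volume = ratio * cell_volume
    injected_copies, _ = copies(intracellular_concentration, cell_volume)
    return ratio, injected_volume, injected_copies
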