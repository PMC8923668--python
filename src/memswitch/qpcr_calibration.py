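"""Absolute qPCR quantification: standard curves and copies per cell.

The threshold cycle Ct is linear in log10(input copies):
Ct = intercept + slope * log10(copies), with slope near -3.32 for 100%
amplification efficiency.  A DNA dilution series pins the slope; the
RNA standard (known mass, molecular weight 126,060 g/mol by default)
then sets the intercept by a single-parameter fit.  Sample Ct values
convert to absolute copies, and to molecules per cell after dividing by
the cell count and the extraction recovery fraction (default 0.44, i.e.
56% of the RNA lost in extraction/purification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = [
    "QpcrStandardCurve",
    "AbsoluteQuantConfig",
    "fit_log_linear",
    "fit_fixed_slope",
    "ct_to_copies",
    "copies_to_ct",
    "mass_to_copies",
    "copies_per_cell",
]

AVOGADRO = constants.Avogadro


@dataclass(frozen=True)
class QpcrStandardCurve:
    slope: float  # Ct per log10(copies); < 0 for valid amplification
    intercept: float  # Ct at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class AbsoluteQuantConfig:
    molecular_weight_g_per_mol: float = 126060.0
    recovery_fraction: float = 0.44
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.molecular_weight_g_per_mol <= 0:
            raise ValueError("molecular weight must be > 0")
        if not (0.0 < self.recovery_fraction <= 1.0):
            raise ValueError("recovery_fraction must be in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _r_squared(ct: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((ct - fitted) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_log_linear(copies, ct) -> QpcrStandardCurve:
    """OLS of Ct against log10(copies) over a dilution series."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.size != ct.size:
        raise ValueError("copies and ct must have equal length")
    if copies.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("copies must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0.0:
        raise ValueError("dilution series is rank deficient (one level)")
    slope, intercept = np.polyfit(x, ct, 1)
    fitted = intercept + slope * x
    return QpcrStandardCurve(float(slope), float(intercept),
                             _r_squared(ct, fitted))


def fit_fixed_slope(copies, ct, slope: float) -> QpcrStandardCurve:
    """Single-parameter fit of the intercept with the slope held fixed."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.size == 0:
        raise ValueError("need at least one point")
    if np.any(copies <= 0):
        raise ValueError("copies must be positive")
    x = np.log10(copies)
    intercept = float(np.mean(ct - slope * x))
    fitted = intercept + slope * x
    return QpcrStandardCurve(float(slope), intercept, _r_squared(ct, fitted))


def ct_to_copies(ct: float, curve: QpcrStandardCurve) -> float:
    """Invert the standard curve: copies = 10^((Ct - intercept)/slope)."""
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_to_ct(copies: float, curve: QpcrStandardCurve) -> float:
    if copies <= 0:
        raise ValueError("copies must be positive")
    return curve.intercept + curve.slope * math.log10(copies)


def mass_to_copies(mass_g: float, mw_g_per_mol: float = 126060.0) -> float:
    """Molecule count in a known mass of the reference RNA."""
    if mass_g < 0 or mw_g_per_mol <= 0:
        raise ValueError("mass must be >= 0 and MW > 0")
    return mass_g / mw_g_per_mol * AVOGADRO


def copies_per_cell(
    total_copies: float, n_cells: int, recovery_fraction: float = 0.44
) -> float:
    """Absolute molecules per cell, corrected for extraction losses."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 < recovery_fraction <= 1.0):
        raise ValueError("recovery_fraction must be in (0, 1]")
    return total_copies / (recovery_fraction * n_cells)
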