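"""Derived memory statistics and smFISH spot-table analytics.

Works on tidy spot tables (one row per detected punctum, intensity in
C.U., compartment nuclear/cytoplasmic) that stand in for the output of
image analysis, plus bulk time series for slope-based statistics.

The Calibrated Memory Index (CMI) compares second-induction response
slopes: M_C in control cells, M_N under Nup98 depletion, M_I with a
transcription inhibitor present during the first induction.  With
F = 1 - M_N/M_C (the Nup98-dependent fraction of the response) and
R = M_C - M_N (its absolute dynamic range), the literal index is
CMI = F * M_I / R, which is exactly 1 whenever M_I = M_C.  Because the
literal form evaluates to M_N/M_C rather than 0 under depletion, the
normalized alternative (M_I - M_N) / R — exactly 0 at depletion and 1
at control — is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SPOT_COLUMNS",
    "CmiInputs",
    "cmi",
    "fit_induction_slope",
    "classify_nascent_sites",
    "active_loci_fractions",
    "cytoplasmic_fraction",
]

SPOT_COLUMNS = ["cell_id", "spot_id", "compartment", "intensity_cu"]
COMPARTMENTS = ("nuclear", "cytoplasmic")


@dataclass(frozen=True)
class CmiInputs:
    M_C: float  # control second-induction slope (mRNA/cell per min)
    M_N: float  # Nup98-depleted second-induction slope
    M_I: float  # inhibitor-treated second-induction slope

    def __post_init__(self) -> None:
        for v in (self.M_C, self.M_N, self.M_I):
            if not np.isfinite(v):
                raise ValueError("slopes must be finite")
        if self.M_C == self.M_N:
            raise ValueError("M_C == M_N: zero dynamic range for CMI")
        if self.M_C == 0:
            raise ValueError("M_C must be nonzero")


def cmi(inputs: CmiInputs) -> dict[str, float]:
    """Calibrated Memory Index and its building blocks.

    Returns F, R, the literal CMI = F * M_I / R, and the normalized
    alternative (M_I - M_N) / R.
    """
    F = 1.0 - inputs.M_N / inputs.M_C
    R = inputs.M_C - inputs.M_N
    return {
        "F": F,
        "R": R,
        "CMI": F * inputs.M_I / R,
        "CMI_normalized": (inputs.M_I - inputs.M_N) / R,
    }


def fit_induction_slope(series: pd.DataFrame) -> tuple[float, float]:
    """OLS slope of mRNA level vs time over one induction window.

    ``series`` needs columns time_min and mrna_per_cell (all replicates
    as rows).  Returns (slope, standard error).
    """
    t = series["time_min"].to_numpy(dtype=float)
    y = series["mrna_per_cell"].to_numpy(dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct time points for a slope")
    X = np.column_stack([np.ones_like(t), t])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = t.size - 2
    if dof > 0:
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[1, 1]))
    else:
        se = np.nan
    return float(beta[1]), se


def classify_nascent_sites(
    table: pd.DataFrame, threshold_cu: float = 3.0, seed=None
) -> pd.DataFrame:
    """Flag nuclear spots as nascent transcription sites.

    Nuclear spots at or above ``threshold_cu`` (3x the single-mRNA
    intensity by default) are flagged deterministically.  In nuclei with
    fewer than three supra-threshold spots, 1 or 2 of the remaining
    nuclear spots (count and identity drawn uniformly) are additionally
    flagged — asserting zero transcription in such nuclei would bias the
    activity estimate low.  Cytoplasmic spots are never flagged.
    Returns a copy with a boolean ``nascent_flag`` column; reproducible
    given ``seed``.
    """
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["nascent_flag"] = False
    nuclear = out["compartment"] == "nuclear"
    supra = nuclear & (out["intensity_cu"] >= threshold_cu)
    out.loc[supra, "nascent_flag"] = True
    for cell_id, grp in out[nuclear].groupby("cell_id"):
        n_supra = int(grp["nascent_flag"].sum())
        if n_supra >= 3:
            continue
        candidates = grp.index[~grp["nascent_flag"]]
        if candidates.size == 0:
            if n_supra == 0:
                logger.info("cell %r has no nuclear spots to flag", cell_id)
            continue
        n_extra = min(int(rng.integers(1, 3)), candidates.size)
        chosen = rng.choice(candidates.to_numpy(), size=n_extra,
                            replace=False)
        out.loc[chosen, "nascent_flag"] = True
    return out


def active_loci_fractions(flagged: pd.DataFrame) -> dict[str, float]:
    """Fractions of cells with 0, 1, 2, 3 or 4+ nascent sites."""
    if "nascent_flag" not in flagged.columns:
        raise ValueError("table must carry a nascent_flag column")
    counts = flagged.groupby("cell_id")["nascent_flag"].sum()
    n_cells = counts.size
    capped = np.minimum(counts.to_numpy(dtype=int), 4)
    fractions = np.bincount(capped, minlength=5) / n_cells
    keys = ["0", "1", "2", "3", "4+"]
    return dict(zip(keys, (float(f) for f in fractions)))


def cytoplasmic_fraction(
    table: pd.DataFrame, exclude_nascent: bool = True
) -> tuple[pd.Series, float, float]:
    """Per-cell fraction of (non-nascent) puncta in the cytoplasm.

    Returns (per-cell fractions, population mean, population SD).
    Cells without any eligible spot are excluded with a log note.
    The statistic depends only on compartments, never on intensities.
    """
    spots = table
    if exclude_nascent and "nascent_flag" in table.columns:
        spots = table[~table["nascent_flag"].fillna(False).astype(bool)]
    grouped = spots.groupby("cell_id")["compartment"]
    totals = grouped.size()
    cyto = grouped.apply(lambda c: int((c == "cytoplasmic").sum()))
    empty = totals[totals == 0].index
    if len(empty):
        logger.info("excluding %d cells without non-nascent spots",
                    len(empty))
    frac = (cyto / totals).dropna()
    return frac, float(frac.mean()), float(frac.std(ddof=0))
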