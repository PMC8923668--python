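"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: qPCR
time-series tables, qPCR standard-dilution tables, and smFISH-style
per-cell activity and spot tables.  Each generator returns a
``(data, truth)`` pair so downstream recovery tests consume only the
data and compare against the truth; all generators are deterministic
under a fixed seed.

The structural assumptions mirror the study design they emulate:
first-order promoter activation/conversion, footprint-limited Pol II
loading, elongation at 1500 nt/min, mixed ploidy (half 4-locus, half
8-locus cells), Poisson initial puncta counts, exponential mRNA
degradation, multiplicative log-normal qPCR replicate noise, and
log-normal single-mRNA spot intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bulk_models import BULK_COLUMNS, mean_model_curve
from .gene_model import GeneModel, make_uniform_gene
from .kinetics import (
    MEMORY_SWITCH,
    InductionProtocol,
    KineticParams,
    PromoterModelSpec,
    memory_fraction,
)
from .memory_metrics import SPOT_COLUMNS
from .simulator import CellPopulationActivity, simulate_population

__all__ = [
    "SyntheticScenario",
    "generate_qpcr_dataset",
    "generate_smfish_population",
    "generate_standard_dilution",
]


@dataclass
class SyntheticScenario:
    """Bundle of model, protocol and noise settings for generation."""

    spec: PromoterModelSpec = field(
        default_factory=lambda: PromoterModelSpec(MEMORY_SWITCH)
    )
    params: KineticParams = field(default_factory=KineticParams)
    protocol: InductionProtocol = field(
        default_factory=InductionProtocol.standard
    )
    gene: GeneModel = field(default_factory=lambda: make_uniform_gene(67, 4500))
    tau: float = 600.0  # mRNA lifetime, min
    qpcr_noise_cv: float = 0.10  # replicate coefficient of variation
    n_cells: int = 1000
    uninduced_mean_puncta: float = 2.0
    cytoplasmic_probability: float = 0.87
    spot_noise_sigma: float = 0.25  # log-normal sigma on spot intensity
    nascent_emit_threshold_cu: float = 0.5  # min locus C.U. to emit a spot
    n_loci_bulk: int = 6  # mean gene copies per cell for bulk curves
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qpcr_noise_cv < 0 or self.spot_noise_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0.0 <= self.cytoplasmic_probability <= 1.0):
            raise ValueError("cytoplasmic_probability must be in [0, 1]")


# ---------------------------------------------------------------------
# Bulk qPCR series
# ---------------------------------------------------------------------

def _protocol_mean(scenario: SyntheticScenario, times_abs: np.ndarray):
    """Piecewise mean mRNA/cell over the whole protocol.

    Returns (means, induction index per time).  Tracks the carried
    mature level and memory fraction across segments.
    """
    sc = scenario
    means = np.empty(times_abs.size)
    inductions = np.zeros(times_abs.size, dtype=int)
    m_cur = sc.uninduced_mean_puncta
    seg_of_sample = sc.protocol.segment_of_times(times_abs)
    t0 = 0.0
    induction = 0
    first_hormone = None
    for seg_i, seg in enumerate(sc.protocol.segments):
        t1 = t0 + seg.duration_min
        sel = seg_of_sample == seg_i
        offsets = times_abs[sel] - t0
        if seg.hormone_present:
            induction += 1
            if first_hormone is None:
                first_hormone = t0
                f_M0 = 0.0
            else:
                f_M0 = memory_fraction(
                    sc.params.k_C, t0 - first_hormone, seg.nup98_depleted
                )
            if seg.inhibitor != "none":
                vals = m_cur * np.exp(-offsets / sc.tau)
                m_end = m_cur * math.exp(-seg.duration_min / sc.tau)
            else:
                grid = np.unique(np.concatenate(
                    [offsets, [seg.duration_min]]
                ))
                curve = mean_model_curve(
                    sc.spec, sc.params, sc.tau, sc.n_loci_bulk, grid,
                    m0=m_cur, f_M0=f_M0,
                )
                vals = np.interp(offsets, grid, curve)
                m_end = float(curve[-1])
            means[sel] = vals
            inductions[sel] = induction
            m_cur = m_end
        else:
            means[sel] = m_cur * np.exp(-offsets / sc.tau)
            inductions[sel] = induction
            m_cur *= math.exp(-seg.duration_min / sc.tau)
        t0 = t1
    return means, inductions


def default_qpcr_times(protocol: InductionProtocol) -> np.ndarray:
    """0-240 min by 30 within each hormone-on segment (9 points each)."""
    times = []
    t0 = 0.0
    for seg in protocol.segments:
        if seg.hormone_present:
            times.append(t0 + np.arange(0.0, seg.duration_min + 1e-9, 30.0))
        t0 += seg.duration_min
    return np.unique(np.concatenate(times))


def generate_qpcr_dataset(
    scenario: SyntheticScenario,
    times: np.ndarray | None = None,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Noisy replicate qPCR series plus the noiseless ground truth.

    Replicates are the model mean multiplied by mean-one log-normal
    noise at the scenario's CV.  Columns follow the bulk schema
    (condition, induction, time_min, replicate, mrna_per_cell) with
    time_min measured within each induction.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    if times is None:
        times = default_qpcr_times(sc.protocol)
    times = np.sort(np.asarray(times, dtype=float))
    if times.size and times.max() > sc.protocol.total_duration_min:
        raise ValueError("times must lie within the protocol")
    means, inductions = _protocol_mean(sc, times)

    depleted = any(s.nup98_depleted for s in sc.protocol.segments)
    condition = "nup98_depleted" if depleted else "control"
    cv = sc.qpcr_noise_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    rows = []
    starts = {}
    t0 = 0.0
    ind = 0
    for seg in sc.protocol.segments:
        if seg.hormone_present:
            ind += 1
            starts[ind] = t0
        t0 += seg.duration_min
    for rep in range(1, n_replicates + 1):
        noise = (
            np.exp(rng.normal(0.0, sigma, times.size) - sigma * sigma / 2.0)
            if cv > 0 else np.ones(times.size)
        )
        rows.append(pd.DataFrame({
            "condition": condition,
            "induction": inductions,
            "time_min": times - np.array([
                starts.get(i, 0.0) for i in inductions
            ]),
            "replicate": rep,
            "mrna_per_cell": means * noise,
        }))
    data = pd.concat(rows, ignore_index=True)[BULK_COLUMNS]
    truth = {
        "params": sc.params.to_dict(),
        "spec": sc.spec.to_dict(),
        "tau": sc.tau,
        "n_loci": sc.n_loci_bulk,
        "times_abs": times,
        "mean_mrna_per_cell": means,
    }
    return data, truth


# ---------------------------------------------------------------------
# smFISH populations and spot tables
# ---------------------------------------------------------------------

def generate_smfish_population(
    scenario: SyntheticScenario, sample_times
) -> tuple[CellPopulationActivity, pd.DataFrame, dict]:
    """Simulated per-cell activity plus a rendered spot table.

    Each mature mRNA becomes one spot with log-normal intensity around
    1 C.U. and a Bernoulli compartment; each locus whose nascent signal
    reaches the emission threshold becomes one nuclear spot of that
    intensity (log-normal measurement noise applied).  The spot table
    carries a ``time_min`` column and an ``is_nascent_truth`` label.
    """
    sc = scenario
    pop = simulate_population(
        sc.spec, sc.params, sc.gene, sc.protocol, sc.n_cells,
        sample_times, sc.seed, tau=sc.tau,
        uninduced_mean_puncta=sc.uninduced_mean_puncta,
    )
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 1]))
    detail = pop.locus_detail
    cell_of_locus = detail["cell_of_locus"]
    sigma = sc.spot_noise_sigma
    frames = []
    for tm, grp in pop.table.groupby("time_min"):
        grp = grp.sort_values("cell_id")
        mature = grp["mature_count"].to_numpy(dtype=int)
        cells = grp["cell_id"].to_numpy()
        # mature mRNA puncta
        cell_rep = np.repeat(cells, mature)
        n_mat = cell_rep.size
        intensities = np.exp(rng.normal(0.0, sigma, n_mat))
        cyto = rng.random(n_mat) < sc.cytoplasmic_probability
        mat_df = pd.DataFrame({
            "cell_id": cell_rep,
            "compartment": np.where(cyto, "cytoplasmic", "nuclear"),
            "intensity_cu": intensities,
            "is_nascent_truth": False,
            "time_min": tm,
        })
        # nascent transcription sites, one per sufficiently bright locus
        nas = detail["nascent_by_time"][float(tm)]
        bright = nas >= sc.nascent_emit_threshold_cu
        loci = np.flatnonzero(bright)
        nas_df = pd.DataFrame({
            "cell_id": cell_of_locus[loci],
            "compartment": "nuclear",
            "intensity_cu": nas[loci] * np.exp(
                rng.normal(0.0, sigma, loci.size)
            ),
            "is_nascent_truth": True,
            "time_min": tm,
        })
        frames.append(pd.concat([mat_df, nas_df], ignore_index=True))
    spots = pd.concat(frames, ignore_index=True)
    spots = spots.sort_values(["time_min", "cell_id"]).reset_index(drop=True)
    spots["spot_id"] = spots.groupby(["time_min", "cell_id"]).cumcount()
    spots = spots[
        SPOT_COLUMNS + ["time_min", "is_nascent_truth"]
    ]
    truth = {
        "params": sc.params.to_dict(),
        "spec": sc.spec.to_dict(),
        "tau": sc.tau,
        "cytoplasmic_probability": sc.cytoplasmic_probability,
    }
    return pop, spots, truth


# ---------------------------------------------------------------------
# Standard dilutions
# ---------------------------------------------------------------------

def generate_standard_dilution(
    true_slope: float = -3.566,
    intercept: float = 40.0,
    decades: int = 6,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Dilution series table (copies, ct) spanning ``decades`` decades."""
    if decades < 3:
        raise ValueError("decades must be >= 3")
    rng = np.random.default_rng(seed)
    copies = 10.0 ** np.arange(0, decades + 1)
    ct = intercept + true_slope * np.log10(copies)
    if noise_sd_ct > 0:
        ct = ct + rng.normal(0.0, noise_sd_ct, ct.size)
    data = pd.DataFrame({"copies": copies, "ct": ct})
    truth = {"slope": true_slope, "intercept": intercept,
             "noise_sd_ct": noise_sd_ct}
    return data, truth
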