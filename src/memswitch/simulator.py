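"""Monte Carlo simulation of Pol II traffic in single cells.

Generates per-locus polymerase trajectories and per-cell observables
(total nascent activity in C.U., mature mRNA counts) under any promoter
model variant and induction protocol.  Cells are a 50/50 mix of G1 and
G2 (4 or 8 gene copies), so ``n_cells`` cells require ``6 * n_cells``
simulated loci; mature pools start Poisson at the uninduced mean and
decay with first-order kinetics.

The default engine is event-driven (exact; see ``_engine``).  The
fixed-step engine (one nucleotide per 1/1500-min tick) is the slow
reference implementation and is exposed for cross-validation.

The 24-hr recovery between inductions is never simulated at nucleotide
resolution: :func:`apply_recovery_shortcut` reassigns memory status
analytically from the first-order conversion fraction, resets active
promoters, clears the gene body, and decays the mature pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .gene_model import GeneModel, nascent_signal
from .kinetics import (
    FAST_K_A,
    MEMORY_SWITCH,
    MODEL1,
    MODEL2,
    InductionProtocol,
    KineticParams,
    PromoterModelSpec,
    memory_fraction,
)

__all__ = [
    "LocusTrajectory",
    "CellPopulationActivity",
    "PopulationState",
    "simulate_locus",
    "simulate_population",
    "apply_recovery_shortcut",
]

POPULATION_COLUMNS = [
    "cell_id", "condition", "induction", "time_min",
    "n_loci", "nascent_cu", "mature_count",
]


@dataclass
class LocusTrajectory:
    """One locus observed at a set of sample times."""

    sample_times: np.ndarray  # absolute minutes
    promoter_state: list[str]  # per sample: UD/UM/ID/IM or inactive/active
    polii_positions: list[np.ndarray]  # nt coordinates per sample
    completed_mrna_count: np.ndarray  # running total at each sample

    def nascent_cu(self, gene: GeneModel) -> np.ndarray:
        return np.array(
            [nascent_signal(p, gene) for p in self.polii_positions]
        )


@dataclass
class CellPopulationActivity:
    """Per-cell nascent activity and mature counts at sample times.

    Thin wrapper over a tidy DataFrame with columns
    cell_id, condition, induction, time_min, n_loci, nascent_cu,
    mature_count — the common currency between the simulator, the
    synthetic-data generators and the distribution fit.
    """

    table: pd.DataFrame
    #: optional per-locus detail: {"cell_of_locus": array,
    #: "nascent_by_time": {time_min: per-locus C.U. array}}
    locus_detail: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in POPULATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"population table missing columns: {missing}")

    def activity_at(self, induction: int, time_min: float) -> np.ndarray:
        t = self.table
        sel = (t["induction"] == induction) & np.isclose(t["time_min"], time_min)
        return t.loc[sel, "nascent_cu"].to_numpy(dtype=float)

    def activity_by_time(self) -> dict[tuple[int, float], np.ndarray]:
        out: dict[tuple[int, float], np.ndarray] = {}
        for (ind, tm), grp in self.table.groupby(["induction", "time_min"]):
            out[(int(ind), float(tm))] = grp["nascent_cu"].to_numpy(dtype=float)
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellPopulationActivity":
        return cls(pd.read_csv(path))


@dataclass
class PopulationState:
    """Internal per-locus / per-cell state carried between segments."""

    memory: np.ndarray  # bool per locus
    active: np.ndarray  # bool per locus
    mature: np.ndarray  # int per cell


# ---------------------------------------------------------------------
# Segment-level helpers
# ---------------------------------------------------------------------

def _segment_rates(
    spec: PromoterModelSpec, params: KineticParams, inhibited: bool
) -> tuple[float, float, float, float]:
    """(basal, low, high, k_conv) loading rates for one hormone segment."""
    if inhibited:
        return 0.0, 0.0, 0.0, params.k_C
    if spec.variant == MODEL1:
        return 0.0, params.k_pol, params.k_pol, 0.0
    if spec.variant == MEMORY_SWITCH:
        return params.k_polB, params.k_polL, params.k_polH, params.k_C
    raise ValueError(spec.variant)


def _run_hormone_segment_event(
    rng: np.random.Generator,
    spec: PromoterModelSpec,
    params: KineticParams,
    gene: GeneModel,
    duration: float,
    sample_offsets: np.ndarray,
    state_active: np.ndarray,
    state_memory: np.ndarray,
    tau: float,
    inhibited: bool,
) -> _engine.SegmentResult:
    n = state_active.size
    v = params.elongation_nt_per_min
    gap = params.footprint_nt / v
    k_act = FAST_K_A if spec.activation_is_immediate else params.k_A

    t_act = np.where(
        state_active, 0.0,
        rng.exponential(1.0 / k_act, n) if k_act > 0 else np.inf,
    )
    if spec.variant == MODEL2 and not inhibited:
        nascent, new_mat, mat_end, completed = (
            _engine.sample_accelerating_renewal(
                rng, duration, params.alpha, n, gap, sample_offsets,
                gene, tau, v,
            )
        )
        return _engine.SegmentResult(
            nascent, new_mat, mat_end, completed,
            t_act <= duration, state_memory.copy(),
        )

    k_B, k_L, k_H, k_conv = _segment_rates(spec, params, inhibited)
    if spec.variant == MEMORY_SWITCH:
        t_conv = np.where(
            state_memory, 0.0,
            rng.exponential(1.0 / k_conv, n) if k_conv > 0 else np.inf,
        )
    else:
        t_conv = np.full(n, np.inf)

    # piecewise-constant attempt rate per locus:
    #   before activation: basal; after: low until conversion, then high
    b1 = np.minimum(t_act, duration)
    b2 = np.minimum(np.maximum(t_conv, t_act), duration)
    rates = np.empty((n, 3))
    rates[:, 0] = k_B
    rates[:, 1] = np.where(t_conv <= t_act, k_H, k_L)
    rates[:, 2] = k_H
    if spec.variant == MODEL1:
        rates[:, 1] = k_L
        rates[:, 2] = k_L

    nascent, new_mat, mat_end, completed = _engine.sample_piecewise_renewal(
        rng, duration, b1, b2, rates, gap, sample_offsets, gene, tau, v
    )
    return _engine.SegmentResult(
        nascent, new_mat, mat_end, completed,
        t_act <= duration, state_memory | (t_conv <= duration),
    )


def _run_hormone_segment_fixed(
    rng: np.random.Generator,
    spec: PromoterModelSpec,
    params: KineticParams,
    gene: GeneModel,
    duration: float,
    sample_offsets: np.ndarray,
    state_active: np.ndarray,
    state_memory: np.ndarray,
    tau: float,
    inhibited: bool,
) -> _engine.SegmentResult:
    v = params.elongation_nt_per_min
    if spec.activation_is_immediate:
        k_act = 0.0
        state_active = np.ones_like(state_active)
    else:
        k_act = params.k_A

    if spec.variant == MODEL2 and not inhibited:
        alpha = params.alpha

        def rate_of_state(active, memory, t):
            return np.where(active, alpha * t, 0.0)

        k_conv = 0.0
    else:
        k_B, k_L, k_H, k_conv = _segment_rates(spec, params, inhibited)

        def rate_of_state(active, memory, t):
            return np.where(active, np.where(memory, k_H, k_L), k_B)

    return _engine.sample_fixed_step(
        rng, duration, state_active.astype(bool), state_memory.astype(bool),
        k_act, k_conv, rate_of_state, params.footprint_nt,
        sample_offsets, gene, tau, v,
    )


# ---------------------------------------------------------------------
# Recovery shortcut
# ---------------------------------------------------------------------

def apply_recovery_shortcut(
    state: PopulationState,
    k_C: float,
    recovery_min: float,
    elapsed_since_first_hormone: float,
    nup98_depleted: bool,
    tau: float,
    rng: np.random.Generator,
) -> PopulationState:
    """Analytic stand-in for simulating a hormone-free recovery period.

    Each locus is independently flagged as memory with probability
    ``memory_fraction(k_C, elapsed_since_first_hormone)`` — conversion
    keeps running after withdrawal, so the clock spans induction plus
    recovery.  Nup98-depleted cells revert (probability 0).  Active
    promoters reset, the gene body is cleared, and the mature pool is
    thinned binomially by exp(-recovery/tau).
    """
    if recovery_min < 0:
        raise ValueError("recovery_min must be >= 0")
    f_M = memory_fraction(k_C, elapsed_since_first_hormone, nup98_depleted)
    n_loci = state.memory.size
    memory = rng.random(n_loci) < f_M
    survive = math.exp(-recovery_min / tau)
    mature = rng.binomial(state.mature, survive)
    return PopulationState(
        memory=memory,
        active=np.zeros(n_loci, dtype=bool),
        mature=mature,
    )


# ---------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------

def simulate_population(
    spec: PromoterModelSpec,
    params: KineticParams,
    gene: GeneModel,
    protocol: InductionProtocol,
    n_cells: int,
    sample_times,
    seed,
    *,
    tau: float = 600.0,
    uninduced_mean_puncta: float = 2.0,
    engine: str = "event",
    condition: str | None = None,
) -> CellPopulationActivity:
    """Simulate ``6 * n_cells`` loci and combine them into cells.

    Half the cells carry 4 loci (G1) and half 8 (G2).  ``sample_times``
    are absolute minutes from protocol start; each produces one row per
    cell with the summed nascent C.U. over the cell's loci and the
    mature mRNA count (Poisson-seeded, produced by completed transcripts
    and degraded with lifetime ``tau``).  Bit-reproducible given
    ``seed``.
    """
    if n_cells % 2 != 0:
        raise ValueError("n_cells must be even (half G1, half G2)")
    sample_times = np.sort(np.asarray(sample_times, dtype=float))
    total = protocol.total_duration_min
    if np.any(sample_times < 0) or np.any(sample_times > total):
        raise ValueError("sample_times must lie within the protocol duration")
    if engine not in ("event", "fixed"):
        raise ValueError("engine must be 'event' or 'fixed'")

    rng = np.random.default_rng(seed)
    n_loci = 6 * n_cells
    # random partition of loci into cells of 4 and 8
    perm = rng.permutation(n_loci)
    cell_of_locus = np.empty(n_loci, dtype=np.int64)
    half = n_cells // 2
    cell_of_locus[perm[: 4 * half]] = np.repeat(np.arange(half), 4)
    cell_of_locus[perm[4 * half:]] = np.repeat(
        np.arange(half, n_cells), 8
    )
    n_loci_per_cell = np.where(np.arange(n_cells) < half, 4, 8)

    state = PopulationState(
        memory=np.zeros(n_loci, dtype=bool),
        active=np.zeros(n_loci, dtype=bool),
        mature=rng.poisson(uninduced_mean_puncta, n_cells),
    )
    nup98 = any(s.nup98_depleted for s in protocol.segments)
    if condition is None:
        condition = "nup98_depleted" if nup98 else "control"

    run_segment = (
        _run_hormone_segment_event if engine == "event"
        else _run_hormone_segment_fixed
    )

    rows: list[pd.DataFrame] = []
    nascent_by_time: dict[float, np.ndarray] = {}
    seg_of_sample = protocol.segment_of_times(sample_times)
    t0 = 0.0
    induction = 0
    first_hormone_start: float | None = None
    prev_hormone_end: float | None = None
    for seg_i, seg in enumerate(protocol.segments):
        t1 = t0 + seg.duration_min
        in_seg = seg_of_sample == seg_i
        offsets = sample_times[in_seg] - t0
        if seg.hormone_present:
            induction += 1
            if first_hormone_start is None:
                first_hormone_start = t0
            elif prev_hormone_end is not None:
                state = apply_recovery_shortcut(
                    state, params.k_C, t0 - prev_hormone_end,
                    t0 - first_hormone_start, seg.nup98_depleted, tau, rng,
                )
            res = run_segment(
                rng, spec, params, gene, seg.duration_min, offsets,
                state.active, state.memory, tau,
                inhibited=seg.inhibitor != "none",
            )
            for k, ts_abs in enumerate(sample_times[in_seg]):
                off = ts_abs - t0
                nascent_by_time[float(ts_abs)] = res.nascent_cu[k]
                cell_nascent = np.bincount(
                    cell_of_locus, weights=res.nascent_cu[k],
                    minlength=n_cells,
                )
                new_mat = np.bincount(
                    cell_of_locus, weights=res.new_mature[k].astype(float),
                    minlength=n_cells,
                ).astype(np.int64)
                base = rng.binomial(state.mature, math.exp(-off / tau))
                rows.append(_rows(
                    ts_abs, induction, condition, cell_nascent,
                    base + new_mat, n_loci_per_cell,
                ))
            end_mat = np.bincount(
                cell_of_locus, weights=res.mature_end.astype(float),
                minlength=n_cells,
            ).astype(np.int64)
            state = PopulationState(
                memory=res.memory_end,
                active=res.active_end,
                mature=rng.binomial(
                    state.mature, math.exp(-seg.duration_min / tau)
                ) + end_mat,
            )
            prev_hormone_end = t1
        else:
            # hormone off: promoters shut, gene body clears within L/v
            # minutes; nascent signal treated as zero, mature decays
            for ts_abs in sample_times[in_seg]:
                off = ts_abs - t0
                nascent_by_time[float(ts_abs)] = np.zeros(n_loci)
                mat = rng.binomial(state.mature, math.exp(-off / tau))
                rows.append(_rows(
                    ts_abs, induction, condition,
                    np.zeros(n_cells), mat, n_loci_per_cell,
                ))
            state = PopulationState(
                memory=state.memory,
                active=np.zeros(n_loci, dtype=bool),
                mature=state.mature,  # decay applied by the shortcut
            )
        t0 = t1

    table = (
        pd.concat(rows, ignore_index=True) if rows
        else pd.DataFrame(columns=POPULATION_COLUMNS)
    )
    return CellPopulationActivity(table, locus_detail={
        "cell_of_locus": cell_of_locus,
        "nascent_by_time": nascent_by_time,
    })


def _rows(
    time_min: float,
    induction: int,
    condition: str,
    nascent: np.ndarray,
    mature: np.ndarray,
    n_loci_per_cell: np.ndarray,
) -> pd.DataFrame:
    n = nascent.size
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "condition": condition,
        "induction": induction,
        "time_min": time_min,
        "n_loci": n_loci_per_cell,
        "nascent_cu": nascent,
        "mature_count": mature,
    })


# ---------------------------------------------------------------------
# Single-locus trajectories
# ---------------------------------------------------------------------

def simulate_locus(
    spec: PromoterModelSpec,
    params: KineticParams,
    gene: GeneModel,
    protocol: InductionProtocol,
    seed,
    sample_times=None,
    engine: str = "event",
) -> LocusTrajectory:
    """Simulate one locus and record states/positions at sample times.

    ``engine='event'`` samples loading instants exactly (renewal /
    time-rescaling); ``engine='fixed'`` runs the 1-nt-per-tick reference
    loop.  Defaults to sampling every 30 min of the protocol.
    """
    total = protocol.total_duration_min
    if sample_times is None:
        sample_times = np.arange(0.0, total + 1e-9, 30.0)
    sample_times = np.sort(np.asarray(sample_times, dtype=float))
    if np.any(sample_times < 0) or np.any(sample_times > total):
        raise ValueError("sample_times must lie within the protocol duration")
    rng = np.random.default_rng(seed)
    v = params.elongation_nt_per_min
    L = gene.transcript_length_nt

    states: list[str] = []
    positions: list[np.ndarray] = []
    completed_running: list[int] = []
    completed_total = 0

    active = np.zeros(1, dtype=bool)
    memory = np.zeros(1, dtype=bool)
    seg_of_sample = protocol.segment_of_times(sample_times)
    t0 = 0.0
    first_hormone_start = None
    prev_hormone_end = None
    for seg_i, seg in enumerate(protocol.segments):
        t1 = t0 + seg.duration_min
        in_seg = seg_of_sample == seg_i
        offsets = sample_times[in_seg] - t0
        if seg.hormone_present:
            if first_hormone_start is None:
                first_hormone_start = t0
            elif prev_hormone_end is not None:
                f_M = memory_fraction(
                    params.k_C, t0 - first_hormone_start, seg.nup98_depleted
                )
                memory[0] = rng.random() < f_M
                active[0] = False
            load_times, res = _locus_segment_loads(
                rng, spec, params, gene, seg, offsets, active, memory, engine
            )
            for off in offsets:
                dtl = off - load_times
                on_gene = (dtl > 0) & (dtl * v < L)
                positions.append(np.sort(v * dtl[on_gene]))
                n_done = int(np.sum(dtl * v >= L))
                completed_running.append(completed_total + n_done)
                states.append(_state_label(
                    spec,
                    bool(active[0]) or _activated_by(res, off),
                    bool(memory[0]) or _converted_by(res, off),
                ))
            dte = seg.duration_min - load_times
            completed_total += int(np.sum(dte * v >= L))
            active = np.array([res["active_end"]])
            memory = np.array([res["memory_end"]])
            prev_hormone_end = t1
        else:
            for _off in offsets:
                positions.append(np.empty(0))
                completed_running.append(completed_total)
                states.append(_state_label(spec, False, bool(memory[0])))
            active[0] = False
        t0 = t1

    return LocusTrajectory(
        sample_times=sample_times,
        promoter_state=states,
        polii_positions=positions,
        completed_mrna_count=np.asarray(completed_running, dtype=np.int64),
    )


def _locus_segment_loads(
    rng, spec, params, gene, seg, offsets, active, memory, engine
):
    """Loading times for one locus over one hormone-on segment."""
    if engine == "fixed":
        return _locus_segment_loads_fixed(
            rng, spec, params, gene, seg, active, memory
        )
    duration = seg.duration_min
    v = params.elongation_nt_per_min
    inhibited = seg.inhibitor != "none"
    k_act = FAST_K_A if spec.activation_is_immediate else params.k_A
    t_act = 0.0 if active[0] else (
        rng.exponential(1.0 / k_act) if k_act > 0 else np.inf
    )
    if spec.variant == MEMORY_SWITCH:
        t_conv = 0.0 if memory[0] else (
            rng.exponential(1.0 / params.k_C) if params.k_C > 0 else np.inf
        )
    else:
        t_conv = np.inf

    gap = params.footprint_nt / v
    loads: list[float] = []
    if spec.variant == MODEL2 and not inhibited:
        g = 0.0
        while True:
            t = math.sqrt(g * g + 2.0 * rng.exponential() / params.alpha) \
                if params.alpha > 0 else np.inf
            if t > duration:
                break
            loads.append(t)
            g = t + gap
    else:
        k_B, k_L, k_H, _ = _segment_rates(spec, params, inhibited)

        def rate_at(t: float) -> float:
            if t < t_act:
                return k_B
            return k_H if t >= t_conv else k_L

        def bound_at(t: float) -> float:
            for b in sorted((t_act, t_conv)):
                if t < b < duration:
                    return b
            return duration

        g = 0.0
        while g < duration:
            r = rate_at(g)
            b = bound_at(g)
            if r <= 0:
                g = b if b > g else duration
                if g >= duration and rate_at(g) <= 0:
                    break
                continue
            t = g + rng.exponential(1.0 / r)
            if t > b:
                g = b
                continue
            loads.append(t)
            g = t + gap

    res = {
        "t_act": t_act,
        "t_conv": t_conv,
        "active_end": t_act <= duration,
        "memory_end": bool(memory[0]) or t_conv <= duration,
    }
    return np.asarray(loads), res


def _locus_segment_loads_fixed(rng, spec, params, gene, seg, active, memory):
    """Scalar 1-nt-per-tick reference loop for a single locus."""
    duration = seg.duration_min
    v = params.elongation_nt_per_min
    dt = 1.0 / v
    inhibited = seg.inhibitor != "none"
    n_steps = int(round(duration * v))
    if spec.activation_is_immediate:
        k_act = 0.0
        is_active = True
    else:
        k_act = params.k_A
        is_active = bool(active[0])
    k_conv = params.k_C if spec.variant == MEMORY_SWITCH else 0.0
    for name, rate in (("k_A", k_act), ("k_C", k_conv)):
        if rate * dt > 0.1:
            raise ValueError(f"per-step probability {name}*dt > 0.1")
    is_memory = bool(memory[0])
    k_B, k_L, k_H, _ = (
        _segment_rates(spec, params, inhibited)
        if not (spec.variant == MODEL2 and not inhibited)
        else (0.0, 0.0, 0.0, 0.0)
    )
    accelerating = spec.variant == MODEL2 and not inhibited

    t_act = 0.0 if is_active else np.inf
    t_conv = 0.0 if is_memory else np.inf
    last_load = -10 * gene.transcript_length_nt
    loads: list[float] = []
    for s in range(n_steps):
        t = s * dt
        if not is_active and k_act > 0 and rng.random() < k_act * dt:
            is_active = True
            t_act = t
        if not is_memory and k_conv > 0 and rng.random() < k_conv * dt:
            is_memory = True
            t_conv = t
        if accelerating:
            rate = params.alpha * t
        else:
            rate = (k_H if is_memory else k_L) if is_active else k_B
        if rate * dt > 0.1:
            raise ValueError("per-step loading probability > 0.1")
        if (s - last_load) >= params.footprint_nt and rng.random() < rate * dt:
            last_load = s
            loads.append(t)
    if accelerating:
        t_act = 0.0
    res = {
        "t_act": t_act,
        "t_conv": t_conv,
        "active_end": t_act <= duration,
        "memory_end": is_memory,
    }
    return np.asarray(loads), res


def _activated_by(res: dict, offset: float) -> bool:
    return res["t_act"] <= offset


def _converted_by(res: dict, offset: float) -> bool:
    return res["t_conv"] <= offset


def _state_label(spec: PromoterModelSpec, active: bool, memory: bool) -> str:
    if spec.variant == MEMORY_SWITCH:
        return ("I" if active else "U") + ("M" if memory else "D")
    return "active" if active else "inactive"
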