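"""Vectorized sampling engines for per-locus Pol II traffic.

Two engines produce per-locus observables for one hormone-on segment:

* event-driven — exploits that elongation is deterministic, so the
  footprint constraint reduces to a refractory time s/v after each
  successful loading.  Successful loadings then form a renewal process
  (gap = s/v + Exp(rate)) with piecewise-constant rates set by the
  promoter state trajectory, or a gated non-homogeneous Poisson process
  for the accelerating-attempt model.  Exact, no time discretization.
* fixed-step — advances every Pol II by one nucleotide per tick of
  dt = 1/v min and performs Bernoulli draws per tick.  Slow; used as
  the reference implementation in tests.

Both operate on arrays over loci and accumulate, at each requested
sample offset, the nascent C.U. signal and the number of
segment-completed mRNAs surviving degradation to that instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_model import GeneModel


@dataclass
class SegmentResult:
    """Per-locus observables for one simulated segment.

    nascent_cu, new_mature: arrays of shape (n_samples, n_loci);
    ``new_mature`` counts mRNAs completed during this segment that
    survive degradation to the sample instant.  ``mature_end`` is the
    analogous count at segment end, ``completed`` the total number of
    completed transcripts, and ``active_end`` / ``memory_end`` the
    promoter coordinates at segment end.
    """

    nascent_cu: np.ndarray
    new_mature: np.ndarray
    mature_end: np.ndarray
    completed: np.ndarray
    active_end: np.ndarray
    memory_end: np.ndarray


def _accumulate_loads(
    rng: np.random.Generator,
    load_times: np.ndarray,
    loci: np.ndarray,
    sample_offsets: np.ndarray,
    gene: GeneModel,
    ride_time: float,
    tau: float,
    duration: float,
    nascent: np.ndarray,
    new_mature: np.ndarray,
    mature_end: np.ndarray,
    completed: np.ndarray,
    v: float,
) -> None:
    """Fold a batch of successful loading times into the accumulators."""
    for k, ts in enumerate(sample_offsets):
        dtl = ts - load_times
        on_gene = (dtl > 0) & (dtl < ride_time)
        if np.any(on_gene):
            counts = gene.probes_transcribed(v * dtl[on_gene])
            np.add.at(
                nascent[k], loci[on_gene], counts / gene.n_probes
            )
        done = dtl >= ride_time
        if np.any(done):
            p_survive = np.exp(-(dtl[done] - ride_time) / tau)
            kept = rng.random(p_survive.size) < p_survive
            np.add.at(new_mature[k], loci[done], kept.astype(np.int64))
    dte = duration - load_times
    done_end = dte >= ride_time
    if np.any(done_end):
        p_survive = np.exp(-(dte[done_end] - ride_time) / tau)
        kept = rng.random(p_survive.size) < p_survive
        np.add.at(mature_end, loci[done_end], kept.astype(np.int64))
        np.add.at(completed, loci[done_end], 1)


def sample_piecewise_renewal(
    rng: np.random.Generator,
    duration: float,
    b1: np.ndarray,
    b2: np.ndarray,
    rates: np.ndarray,
    gap: float,
    sample_offsets: np.ndarray,
    gene: GeneModel,
    tau: float,
    v: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample footprint-gated loadings under piecewise-constant rates.

    Per locus the attempt rate is ``rates[:, 0]`` before ``b1``,
    ``rates[:, 1]`` on [b1, b2) and ``rates[:, 2]`` after ``b2``
    (b1 <= b2).  ``gap`` is the refractory time s/v.  Returns the
    accumulator arrays (nascent, new_mature, mature_end, completed).
    """
    n = b1.size
    n_samp = sample_offsets.size
    ride_time = gene.transcript_length_nt / v
    nascent = np.zeros((n_samp, n))
    new_mature = np.zeros((n_samp, n), dtype=np.int64)
    mature_end = np.zeros(n, dtype=np.int64)
    completed = np.zeros(n, dtype=np.int64)

    g = np.zeros(n)  # earliest instant the next attempt may occur
    alive = np.ones(n, dtype=bool)
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        gi = g[idx]
        phase = (gi >= b1[idx]).astype(np.int64) + (gi >= b2[idx])
        rate = rates[idx, phase]
        phase_end = np.where(
            phase == 0, b1[idx], np.where(phase == 1, b2[idx], duration)
        )
        phase_end = np.minimum(phase_end, duration)

        tc = np.full(idx.size, np.inf)
        nz = rate > 0
        if np.any(nz):
            tc[nz] = gi[nz] + rng.exponential(1.0 / rate[nz])
        success = nz & (tc <= phase_end)
        if np.any(success):
            loc = idx[success]
            tl = tc[success]
            _accumulate_loads(
                rng, tl, loc, sample_offsets, gene, ride_time, tau,
                duration, nascent, new_mature, mature_end, completed, v,
            )
            g[loc] = tl + gap
        fail = ~success
        g[idx[fail]] = phase_end[fail]
        # a locus whose phase end is the segment end and whose draw
        # crossed it is finished; successes stay alive
        dead = fail & (phase_end >= duration)
        alive[idx[dead]] = False
        alive[idx] &= g[idx] < duration
    return nascent, new_mature, mature_end, completed


def sample_accelerating_renewal(
    rng: np.random.Generator,
    duration: float,
    alpha: float,
    n: int,
    gap: float,
    sample_offsets: np.ndarray,
    gene: GeneModel,
    tau: float,
    v: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Loadings when the attempt rate grows linearly, lambda(t) = alpha*t.

    Attempts form a non-homogeneous Poisson process; after a gate-open
    instant g the next attempt is at sqrt(g^2 + 2E/alpha), E ~ Exp(1)
    (inversion of the cumulative intensity alpha*t^2/2), and it always
    succeeds because the gate is already open.
    """
    n_samp = sample_offsets.size
    ride_time = gene.transcript_length_nt / v
    nascent = np.zeros((n_samp, n))
    new_mature = np.zeros((n_samp, n), dtype=np.int64)
    mature_end = np.zeros(n, dtype=np.int64)
    completed = np.zeros(n, dtype=np.int64)
    if alpha <= 0:
        return nascent, new_mature, mature_end, completed

    g = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    while True:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        e = rng.exponential(size=idx.size)
        tc = np.sqrt(g[idx] ** 2 + 2.0 * e / alpha)
        success = tc <= duration
        if np.any(success):
            loc = idx[success]
            tl = tc[success]
            _accumulate_loads(
                rng, tl, loc, sample_offsets, gene, ride_time, tau,
                duration, nascent, new_mature, mature_end, completed, v,
            )
            g[loc] = tl + gap
        alive[idx[~success]] = False
    return nascent, new_mature, mature_end, completed


def sample_fixed_step(
    rng: np.random.Generator,
    duration: float,
    active0: np.ndarray,
    memory0: np.ndarray,
    k_act: float,
    k_conv: float,
    rate_of_state,  # callable (active, memory, t) -> per-locus attempt rate
    footprint_nt: int,
    sample_offsets: np.ndarray,
    gene: GeneModel,
    tau: float,
    v: float,
) -> SegmentResult:
    """Reference fixed-step engine: one nucleotide per tick (dt = 1/v).

    Promoter transitions and loading attempts are Bernoulli draws with
    probability rate*dt per tick; a tick's loading attempt is vetoed
    while any Pol II sits within ``footprint_nt`` of the start site.
    Raises if any per-tick probability exceeds 0.1 (the guard on the
    Bernoulli approximation).
    """
    dt = 1.0 / v
    n_steps = int(round(duration * v))
    n = active0.size
    L = gene.transcript_length_nt
    for name, rate in (("k_A", k_act), ("k_C", k_conv)):
        if rate * dt > 0.1:
            raise ValueError(
                f"per-step probability {name}*dt = {rate * dt:.3g} > 0.1; "
                "rate too fast for the fixed-step engine"
            )

    active = active0.copy()
    memory = memory0.copy()
    last_load = np.full(n, -10 * L, dtype=np.int64)  # tick of last loading
    load_ticks: list[np.ndarray] = []
    load_loci: list[np.ndarray] = []
    sample_ticks = np.rint(np.asarray(sample_offsets) * v).astype(np.int64)

    for s in range(n_steps):
        t = s * dt
        if k_act > 0:
            inact = ~active
            if inact.any():
                flip = inact & (rng.random(n) < k_act * dt)
                active |= flip
        if k_conv > 0:
            nonmem = ~memory
            if nonmem.any():
                flip = nonmem & (rng.random(n) < k_conv * dt)
                memory |= flip
        rate = rate_of_state(active, memory, t)
        if np.any(rate * dt > 0.1):
            raise ValueError(
                f"per-step loading probability {np.max(rate) * dt:.3g} > 0.1"
            )
        can_load = (s - last_load) >= footprint_nt
        loads = can_load & (rng.random(n) < rate * dt)
        if loads.any():
            loc = np.flatnonzero(loads)
            last_load[loc] = s
            load_ticks.append(np.full(loc.size, s, dtype=np.int64))
            load_loci.append(loc)

    ticks = (
        np.concatenate(load_ticks) if load_ticks
        else np.empty(0, dtype=np.int64)
    )
    loci = (
        np.concatenate(load_loci) if load_loci
        else np.empty(0, dtype=np.int64)
    )
    n_samp = sample_ticks.size
    nascent = np.zeros((n_samp, n))
    new_mature = np.zeros((n_samp, n), dtype=np.int64)
    mature_end = np.zeros(n, dtype=np.int64)
    completed = np.zeros(n, dtype=np.int64)
    for k, st in enumerate(sample_ticks):
        d_ticks = st - ticks
        on_gene = (d_ticks > 0) & (d_ticks < L)
        if np.any(on_gene):
            counts = gene.probes_transcribed(d_ticks[on_gene].astype(float))
            np.add.at(nascent[k], loci[on_gene], counts / gene.n_probes)
        done = d_ticks >= L
        if np.any(done):
            p = np.exp(-(d_ticks[done] - L) * dt / tau)
            kept = rng.random(p.size) < p
            np.add.at(new_mature[k], loci[done], kept.astype(np.int64))
    d_end = n_steps - ticks
    done = d_end >= L
    if np.any(done):
        p = np.exp(-(d_end[done] - L) * dt / tau)
        kept = rng.random(p.size) < p
        np.add.at(mature_end, loci[done], kept.astype(np.int64))
        np.add.at(completed, loci[done], 1)
    return SegmentResult(
        nascent, new_mature, mature_end, completed, active, memory
    )
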