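# Methods

## Promoter models

All variants describe a single gene copy (locus). Times are minutes,
rates per minute.

**Two-state Model 1.** While hormone is present, an inactive locus
activates at rate k_A; deactivation is neglected (k_−A ≈ 0), so the
active fraction is f_A(t) = 1 − e^(−k_A·t). Active loci recruit Pol II
into productive elongation at a constant rate k_Pol. The mean
production rate per locus is k_Pol·f_A(t).

**Two-state Model 2.** Activation is effectively instantaneous (k_A set
to 1000/min) and the *attempt* rate grows linearly, λ(t) = α·t.
Attempts succeed only when no polymerase occupies the first *s*
nucleotides of the template (the Pol II footprint), which caps the
successful rate at v/s for elongation speed v.

**Memory switch.** The promoter state is the product of two independent
binary coordinates: induced/uninduced (rates k_A / k_−A, hormone
dependent) and memory/default (rates k_C / k_−C). Loading rates are
k_polB (uninduced), k_polL (induced·default) and k_polH
(induced·memory). Hormone makes both coordinates effectively
irreversible; conversion to memory continues after hormone withdrawal,
so the memory fraction a total time t after the first exposure is
f_M(t) = 1 − e^(−k_C·t). Nup98 depletion is modeled as instantaneous
reversion of the memory coordinate at hormone withdrawal (k_−C ≫ k_C):
depleted cells convert normally while hormone is present but start the
second induction with f_M = 0. At washout the active coordinate resets
immediately (transcription is minimal after 24 hr of recovery, so the
active-state lifetime without hormone is taken as short). Because the
two coordinates are independent, occupancies factorize and the mean
production rate is
f_A·[f_M·k_polH + (1−f_M)·k_polL] + (1−f_A)·k_polB.

Transcription inhibitors (flavopiridol, triptolide) zero all loading
rates for the duration of the treated segment but leave the k_A and k_C
dynamics untouched; an optional factor (< 1, default 1) can scale k_C
under triptolide.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| k_A | 17e-3 /min | activation rate (memory-switch fit) |
| k_C | 0.8e-3 /min | default→memory conversion rate |
| k_polL / k_polH | 0.3 / 4.5 Pol II/min | induced loading rates (15×) |
| k_pol | 2.0 Pol II/min | Model 1 loading rate |
| α | 11.7e-3 Pol II/min² | Model 2 attempt acceleration |
| s (footprint) | 150 nt | minimum Pol II spacing; a free parameter never pinned by mean curves, kept configurable |
| v | 1500 nt/min | elongation speed |
| τ | 600 min | mRNA lifetime (configurable; lifetimes are known only graphically) |
| k_polB | 5e-4 Pol II/min | basal loading; chosen so the basal steady state 6·k_polB·τ ≈ 1.8 matches the default uninduced mean puncta count of 2 |
| gene | 4500 nt, 67 uniform probes | only the relative probe layout matters, since all probes are exonic |

## Simulation engines

**Event-driven (default).** Elongation is deterministic, so the
footprint constraint is exactly a refractory time s/v after each
successful loading. Under a piecewise-constant attempt rate λ the
successful loadings therefore form a renewal process with gaps
s/v + Exp(λ); the long-run successful rate λ/(1+λ·s/v) is exact, not a
mean-field approximation. Per locus the rate timeline has at most three
phases (basal until activation, low until conversion, then high), whose
boundaries are drawn once per segment from exponentials — valid because
activation and conversion are first-order and, within a hormone-on
segment, irreversible. Model 2's accelerating attempts are a
non-homogeneous Poisson process sampled by inversion of the cumulative
intensity α·t²/2, gated by the same refractory time. Every sampled
loading contributes, at each requested sample instant, either a nascent
signal (probes transcribed / total probes, via the probe layout) or a
surviving mature mRNA (Bernoulli with probability e^(−age/τ)). The
engine is vectorized over loci and bit-reproducible given a seed.

**Fixed-step (oracle).** One nucleotide per tick (dt = 1/v min =
1/1500 min); promoter transitions and loading attempts are Bernoulli
draws per tick, with a hard error if any per-tick probability exceeds
0.1. Used as the reference implementation: the engines are required to
agree on population means within Monte Carlo error (tested), and
long-run occupancy must match the Little's-law value k_pol·L/v for an
unobstructed forced-active locus (tested with s = 1 nt).

**Populations.** n cells require 6n loci: half the cells carry 4
copies, half 8, assigned by random partition. Mature pools start
Poisson(uninduced mean, default 2) and evolve by completed transcripts
minus first-order decay. Mature snapshots at different sample times are
independent thinnings of the running pool — adequate for distribution
comparisons, not for tracking identified molecules through time.

**Recovery shortcut.** The 24-hr recovery is never simulated at
nucleotide resolution. At each hormone-off→on boundary every locus is
independently flagged memory with probability f_M(total time since the
first exposure) — 0 under Nup98 depletion — active states reset, the
gene body clears, and mature pools are thinned by e^(−recovery/τ).
Because conversion is first-order and memoryless, re-randomizing the
flags is distributionally identical to carrying per-locus conversion
times. Basal transcription during hormone-off periods is neglected in
the nascent channel (it contributes ≲ 1e-3 C.U.).

## Bulk fitting

Mean accumulation obeys dm/dt = production(t) − m/τ. Closed forms are
used for constant production, linear production and Model 1 (validated
against numeric integration to 1e-6 relative error); Model 2 and the
memory switch integrate numerically (RK45, rtol 1e-9). Fitting is
two-stage: τ is estimated once from a transcription-shutoff decay
series (nonlinear least squares of m0·e^(−t/τ)), then held fixed in the
accumulation fit, which assumes six gene copies per cell (tetraploid
line, half G1 / half G2). Confidence intervals are asymptotic
(1.96·SE from the Jacobian covariance). Non-decaying degradation input
returns a flagged fit with τ at the 1e6-min search bound rather than an
error. Model 2's footprint is weakly identified from 9-point mean
curves (saturation is mild at α·t ≤ 2.8 attempts/min) and is reported
as fitted without further interpretation; α recovers regardless.

## Histogram-overlap inference

Per-cell total nascent C.U. values are compared on a log10 axis with
identical-width bins (default 30 spanning [log10(0.5), pooled max])
plus an underflow pseudo-bin for cells below 0.5 C.U. (zeros included).
The score is the pooled Jaccard index: intersections summed over all
compared time points divided by summed unions. Bin edges are shared
between simulation and observation and exposed in configuration, since
the absolute score depends on them; only score comparisons between
identically binned distributions are meaningful.

The grid search is staged: a coarse log-spaced grid (8 points per free
parameter) over the search range, then a configurable number of
log-spaced zooms (7 points) each spanning one grid spacing of the
previous stage around the running optimum. The zoom is geometric rather
than a ±50% linear window so it can bridge coarse spacings larger than
2×. All evaluations share one simulation seed (common random numbers),
which keeps the score surface smooth in the parameters. A constraint
callback can veto combinations, e.g. requiring the analytic mean
production rate to track a previously fitted qPCR rate curve; a fully
vetoed grid raises an error naming the constraint. Bootstrap CIs
resample cells with replacement within each time point, rerun the
narrow search, and report mean ± 2 SD (default 1000 resamples; tests
use 50).

At the fitted operating point (k_A = 17e-3, k_C = 0.8e-3), a search
over k_A ∈ [1e-4, 1e-1] and k_C ∈ [1e-5, 1e-2] with 10,000-cell
populations (2,000 for the coarse stage), six sample times (1/2/4 hr of
each induction) and three zooms localizes both rates to a few percent
in about ten minutes on one CPU; these are the problem sizes used by
the acceptance script and tests.

## Memory statistics

CMI uses second-induction slopes (OLS over all time points of the
induction window, 0–240 min): with F = 1 − M_N/M_C and R = M_C − M_N,
the literal index F·M_I/R reduces algebraically to M_I/M_C — exactly 1
when the inhibitor has no effect, but M_N/M_C rather than 0 under Nup98
depletion. Since the stated anchoring ("zero under depletion") is
inconsistent with the literal algebra, both the literal form and the
normalized form (M_I − M_N)/R (exactly 0 at depletion, 1 at control)
are returned; choosing between them is left to the caller.

Nascent-site classification flags nuclear spots at ≥ 3 C.U. (three
single-mRNA equivalents); in nuclei with fewer than three such spots,
1 or 2 additional nuclear spots are flagged at random (count uniform on
{1, 2}, spots uniform without replacement — the source procedure does
not specify these distributions), because asserting zero transcription
in dim nuclei biases activity low. Cytoplasmic spots are never flagged.

## Synthetic data

Generators return (data, truth) pairs and are deterministic under a
seed. qPCR replicates multiply the model mean by mean-one log-normal
noise (default CV 10%; error models are not stated for the emulated
assay, and a multiplicative model matches SD bars that grow with the
mean). Spot intensities are log-normal around 1 C.U. (σ = 0.25);
compartments are Bernoulli (cytoplasmic probability 0.87); nascent
spots are emitted per locus above 0.5 C.U. without pairing or merging.
What the generators do **not** emulate: cell-to-cell extrinsic
variability beyond ploidy, cell division, partial-probe binding,
optical crowding/segmentation errors, and chromosome pairing of
homologous loci (loci are independent). Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Numerical notes

- Probes count binarily: a probe contributes once the polymerase
  reaches its (1-based) coordinate; partial transcription of a binding
  site contributes nothing.
- A new Pol II loads at position 0 and is evicted (mRNA completed) on
  reaching the gene end.
- Degenerate inputs: empty Pol II lists score 0 C.U.; constant
  degradation series return a flagged fit; rank-deficient dilution
  series and sub-3-point standard curves raise; grid searches with an
  empty feasible set raise.
- Seeds feed `numpy.random.default_rng`; derived seeds use
  `SeedSequence` and stay below 2^31.

## Limitations

- The recovery shortcut assumes the active state decays quickly after
  withdrawal; protocols ending in a hormone-off segment do not update
  memory flags at the very end (no consumer samples there).
- The Jaccard score is a heuristic overlap, not a likelihood; no
  posterior semantics attach to the bootstrap intervals.
- Bulk and single-cell fits share the six-loci-per-cell convention;
  per-locus parameters are only as good as that ploidy assumption.
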