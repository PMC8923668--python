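# memswitch

Kinetic modeling and single-cell inference for hormone-induced
transcriptional memory.

When *Drosophila* S2 cells are exposed to the steroid hormone ecdysone
(20E), re-exposed after a recovery period, they respond faster and more
strongly — a Nup98-dependent *transcriptional memory*. `memswitch`
implements the quantitative machinery needed to dissect this behavior
from bulk qPCR time series and single-molecule FISH (smFISH)
measurements of nascent transcription:

- **Promoter models.** Two-state (telegraph) variants — slow activation
  at rate k_A with constant Pol II loading k_Pol (Model 1), or
  immediate activation with a linearly accelerating loading-attempt
  rate α·t capped by the Pol II footprint (Model 2) — and the
  four-state **memory switch**: promoters occupy the product of
  induced/uninduced (k_A, k_−A) and memory/default (k_C, k_−C)
  coordinates, loading Pol II at k_polL in the induced-default state,
  k_polH in the induced-memory state, and a basal k_polB otherwise.
  Conversion to memory is slow (1/k_C ≈ 21 hr) and keeps running after
  hormone withdrawal; Nup98 keeps it irreversible.
- **Monte Carlo simulator.** Per-locus Pol II trajectories with
  deterministic elongation at v = 1500 nt/min and steric exclusion (a
  minimum spacing *s* between polymerases), rendered as smFISH
  observables: each polymerase contributes
  (probe sites transcribed)/(total probes) "cytoplasmic units" (C.U.),
  summed over the 4 or 8 gene copies of G1/G2 cells. The default engine
  is event-driven and exact; a 1-nt-per-tick fixed-step engine serves
  as the reference oracle.
- **Bulk accumulation models** dm/dt = production(t) − m/τ with
  closed forms, degradation-lifetime fits, and two-stage nonlinear
  regression of the promoter models against qPCR series.
- **Absolute qPCR calibration**: standard curves (fixed-slope or OLS),
  Ct ↔ copies conversion, mass → copies via the standard's molecular
  weight, and per-cell normalization with extraction-loss correction.
- **Simulation-based inference**: Jaccard-index overlap of log-C.U.
  histograms, staged seeded grid search, cell-level bootstrap CIs.
- **Memory statistics**: memory-state fractions, Calibrated Memory
  Index (CMI) from second-induction slopes, nascent-site classification
  on spot tables, active-loci fractions, cytoplasmic mRNA fraction.
- **Synthetic-data generators** for every input, with ground truth.

## Worked example

Simulate the standard memory assay (4 hr hormone → 24 hr recovery →
4 hr hormone) at the fitted operating point and inspect the per-cell
nascent activity:

```python
import numpy as np
from memswitch import (
    KineticParams, PromoterModelSpec, InductionProtocol,
    make_uniform_gene, simulate_population, memory_fraction,
)

gene = make_uniform_gene(67, 4500)          # 67 probes, 4.5 kb gene
params = KineticParams()                    # k_A=17e-3, k_C=0.8e-3,
                                            # k_polL=0.3, k_polH=4.5
pop = simulate_population(
    PromoterModelSpec("memory_switch"), params, gene,
    InductionProtocol.standard(), n_cells=2000,
    sample_times=[240.0, 1920.0], seed=7,
)
for (ind, t), cu in sorted(pop.activity_by_time().items()):
    print(f"induction {ind} @ {t:.0f} min: "
          f"mean {cu.mean():.1f} C.U., 90th pct {np.quantile(cu, 0.9):.1f}")
print(f"memory fraction after recovery: "
      f"{100 * memory_fraction(params.k_C, 1680.0):.0f}%")
```

```
induction 1 @ 240 min: mean 6.8 C.U., 90th pct 13.4
induction 2 @ 1920 min: mean 21.6 C.U., 90th pct 33.7
memory fraction after recovery: 74%
```

The second induction is ~3× stronger than the first because 74% of
loci converted to the memory state (loading at k_polH = 4.5 instead of
k_polL = 0.3 Pol II/min) during the induction-plus-recovery interval —
the signature of the memory switch.

A CLI mirrors the main workflows
(`memswitch simulate | fit-bulk | fit-dist | calibrate | metrics |
synth`); see `memswitch --help`.

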