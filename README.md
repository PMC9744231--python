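# ubiquifold

Quantitative analysis of chromatin-fiber folding by single-molecule FRET
and of Polycomb-regulated chromatin by spike-in-normalized genomics —
built for studies of H2A monoubiquitination (H2Aub1), the mark written by
PRC1 and erased by the PR-DUB deubiquitinase, which antagonize each other
across the *Drosophila* genome.

The package has two arms that meet in one question — how does H2Aub1
change chromatin structure?

**smFRET arm.** Immobilized 12-nucleosome arrays carry a donor dye on
nucleosome *n* and an acceptor on *n+2*, so FRET reports nucleosome
stacking in the folded fiber. From raw donor/acceptor intensities
(F_D, F_A) the corrected FRET efficiency is

```
E = (F_A − β·F_D) / (F_A − β·F_D + γ·F_D)
```

with donor-leakage fraction β and detection-efficiency ratio γ
(defaults β = 0.161, γ = 0.436). γ is calibrated from acceptor
photobleaching: γ = ΔF_A,bleach / ΔF_D,bleach, the ratio of the
acceptor step to the concurrent donor rise (steps found by
changepoint detection; the acceptor step is measured on the
leakage-corrected channel). Pooled per-frame E values form
time-averaged histograms that are decomposed into at most two Gaussians,
y = Σᵢ Aᵢ·exp(−½((x−cᵢ)/dᵢ)²), and components are labeled **open**
(c < 0.1, unfolded), **medium** (transient stacking intermediate,
c ≈ 0.34) or **high** (folded fiber, c ≈ 0.66).

**Genomics arm.** ChIP-seq/ATAC-seq coverage with spike-in chromatin is
placed on an absolute scale (scale factor = reference spike-in reads /
sample spike-in reads), then:
a three-state Gaussian HMM on log coverage segments H3K27me3 into
none/intermediate/high domains; a Poisson local-background test calls
Pho point peaks at PREs; domains and peaks combine into the four-class
chromatin annotation (**canonical** Polycomb domains = high H3K27me3 +
Pho, **noncanonical** = intermediate H3K27me3 without Pho, **active** =
H3K36me2-enriched, **neutral** = the rest); gene-body coverage,
mutant/wild-type fold changes with class medians, length-normalized
domain metaprofiles, and the joint ATAC-FC vs H2Aub1-FC region table
quantify the consequences of perturbing PRC1 or PR-DUB.

A synthetic-data module simulates both input kinds with known ground
truth (FRET forward model with Markov state switching, leakage,
detection ratio and single-step photobleaching; planted genomes with
Poisson/negative-binomial coverage and spike-in fractions), so every
stage is tested by recovery of planted parameters.

## Worked example

Simulate 40 folded-fiber molecules that toggle between an unfolded
(E = 0.05) and a stacked (E = 0.66) state, detect photobleaching, correct
with the calibrated (β, γ), and fit the pooled histogram:

```python
from ubiquifold import (CorrectionFactors, TraceSimParams, build_histogram,
    classify_populations, compute_efret, detect_bleach_steps, fit_gaussians,
    simulate_smfret_trace)

efret_traces = []
for i in range(40):
    params = TraceSimParams(state_efret_levels=[0.05, 0.66],
                            acceptor_bleach_frame=1500, seed=i)
    trace, _ = simulate_smfret_trace(params)
    events = detect_bleach_steps(trace, beta=0.161)
    efret_traces.append(
        compute_efret(trace, CorrectionFactors(), bleach_events=events))

hist = build_histogram(efret_traces)
fit = fit_gaussians(hist, k=2)
call = classify_populations(fit)
for comp, label, frac in zip(fit.components, call.labels, call.fractions):
    print(f"{label:>6}: center={comp.center:.3f} width={comp.width:.3f} "
          f"fraction={frac:.2f}")
```

prints

```
  open: center=0.051 width=0.045 fraction=0.47
  high: center=0.660 width=0.023 fraction=0.53
```

i.e. the two planted conformations are recovered at their true FRET
efficiencies, and roughly half the pooled frames sit in each state (the
simulated dwell times are symmetric). The same flow is available from
the shell: `ubiquifold simulate-trace ... | ubiquifold fret-analyze ...`;
the genomics arm is driven by `ubiquifold simulate-genome`, `segment`,
`call-peaks`, `classify`, `quantify`, `metaprofile` and `atac-scatter`.

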