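# signalome

Analysis toolkit for **multiplexed live-cell reporter screens** — experiments
in which a dozen clonal reporter lines, each tagged with a *visual barcode*
(a fluorescent protein targeted to a distinct subcellular compartment), are
pooled into the same wells and challenged with drug libraries. Reading the
barcode from each cell's image recovers which pathway that cell reports on,
so one well yields simultaneous single-cell activity measurements for 12
branches of signaling. The package is written for computational biologists
analyzing such screens (or building simulated ones to validate analysis
choices): it covers barcode calling from images, activity scoring,
signaling-state geometry, drug-target deconvolution, growth homeostasis, and
tumor-cohort comparisons, plus a synthetic-data generator that makes the
entire pipeline testable end to end without any external data.

## The statistics at the core

**Signed KS activity score.** For each (drug, reporter, timepoint) group the
per-cell readout distribution — cytoplasm/nucleus intensity ratio for kinase
translocation reporters, background-subtracted nuclear intensity for
transcriptional reporters — is compared against pooled time-matched vehicle
controls of the same clone by the two-sample Kolmogorov–Smirnov statistic
*D* = sup|*F*ₜ − *F*꜀|, signed by the direction of the median shift. The
score ranges from −1 (maximum inactivation) to +1 (maximum activation);
groups with fewer than 30 cells are not scored, and the significance
threshold is the 99.5th percentile of |score| over control-vs-control
comparisons (conventionally ±0.2).

**State geometry.** Drug × pathway score slices are clustered
(Euclidean/Ward.D2) and decomposed by PCA. Per drug, with PCᵢ the coordinate
on the *i*-th principal axis:

- conformity ψ = PC₁ / √(Σᵢ PCᵢ²) ∈ [−1, 1]
- adherence = |PC₁| / Σᵢ PCᵢ² (as conventionally printed; a normalized
  variant is available)
- strength = √(Σᵢ PCᵢ²)

and the persistence metric φ = Πₙ σ²(projection onto reference axis *n*) /
Πₚ σ²(pathway *p*) measures how well a *reference* coordinate system (e.g.
fitted pre-treatment) explains later correlation structure.

**Deconvolution.** Per-target effects are estimated from a compound × target
indicator design by ridge regression with an extra penalty on target-pair
interaction columns, Σᵢ(yᵢ − Σⱼxᵢⱼβⱼ)² + λΣⱼvⱼβⱼ², with vⱼ = 1 for
individual targets and vⱼ = v > 1 for interactions; λ and v are selected by
fivefold CV with v searched over 2⁰…2³⁰ and interactions dropped when no
interior optimum exists.

**Growth homeostasis.** Exponential fits give the division rate α (cycle
length τ = ln2/α) from cell counts and the per-cell mass accumulation rate γ
from bulk protein mass; control-normalized rates define the imbalance
log₂(γ̃/α̃), negative for growth-limited conditions and positive for
division-limited ones.

## Worked example

```bash
python examples/03_state_analysis.py
```

simulates a 40-drug screen with a planted two-state structure, scores it,
and prints:

```
cluster sizes: {'A': 16, 'B': 16, 'C': 8}
PC1 explains 83.9% of variance
|cos(PC1, planted state axis)| = 0.999

per-drug state metrics (first 5):
            PC1    psi  adherence  strength
drug
drug_001 -1.457 -0.956      0.627     1.524
drug_002 -1.820 -0.988      0.537     1.842
...

phi trajectory (persistence of the pre-treatment structure):
  phi(t=   0 h) = 1.309e-02
  phi(t=   1 h) = 1.513e-01
  phi(t=   6 h) = 1.458e-02
  phi(t=  12 h) = 1.166e-03
  phi(t=  24 h) = 9.589e-05
  phi(t=  48 h) = 2.359e-05
median |pathway correlation| at 48 h: 0.82
```

The clustering recovers the three planted drug groups; PC1 aligns with the
planted state axis, and ψ near ±1 marks drugs conforming to one of the two
anticorrelated signaling states. The φ trajectory shows homeostasis
dynamics: the pre-treatment coordinate system explains the 0-h structure,
briefly loses relevance at 1 h when compound-specific shocks scramble the
correlations, then regains and deepens as the shared stress state dominates.
The other scripts in `examples/` walk through barcode calling from images,
activity scoring and thresholds, target deconvolution, growth imbalance,
and cohort similarity, each printing the numbers it computes.

There is also a thin CLI over the same functions:
`signalome simulate|score|states|deconvolve|growth|similarity|run --help`.

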