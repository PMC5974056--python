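# Methods notes

## Scope and model

`lamethyl` implements a staged locus-by-locus differential-methylation
analysis over a three-group design (Normal, LA Type I, LA Type II; three
samples each by default).  The unit of analysis is the CpG probe; the
statistic is the pair (Δβ, DiffScore) and calling is purely thresholded —
no multiple-testing adjustment is applied by default, matching the
DiffScore-threshold procedure the pipeline reproduces.
Benjamini–Hochberg adjustment is available behind the `bh_adjust`
pipeline flag (it then additionally requires q ≤ 0.05); it is off by
default.

### β and detection

β = M/(M+U+α) with α = 100.  The detection p-value model is the
documented BeadChip convention: a one-sided upper-tail z-test of the
total signal M+U against the per-sample negative-control mean and
standard deviation (estimated from the control probes with ddof = 1).
Commercial scanner software uses a proprietary variant; the convention
used here is recorded in every `QCReport`.

### Per-site p-value and DiffScore

The per-site p is a two-sided Welch (unequal-variance) t-test on the
per-sample β values, the natural choice at n = 3 vs 3.  Degenerate
zero-variance cases are resolved explicitly: identical constant groups
return p = 1 (no evidence), separated constant groups are floored at
p = 10⁻³⁰⁰ so the log-scaled score stays finite.  DiffScore is
sgn(Δβ)·|10·log₁₀ p|; as printed in some sources the formula omits the
sign flip of log₁₀ p and would make hypermethylated sites negative,
contradicting its own sign convention, so the magnitude/sign reading is
used.  At Δβ = 0 the score is 0 by convention.  The significance rule is
conjunctive with |Δβ| ≥ 0.17 inclusive and |DiffScore| > 13 strict.
"Robust β median" is read as the plain sample median (robust relative to
the mean); no trimming.  An M-value (logit β) t-test variant was
considered and not implemented: at these thresholds the Δβ criterion
dominates calling, and the β-scale test keeps the statistic aligned with
the Δβ effect measure.

### QC order and definitions

Fixed order: (1) drop probes with bead count < 3 — in *any* sample by
default (conservative; `bead_rule="all"` relaxes this); (2) drop samples
whose detection success rate over the remaining probes is < 95%;
(3) mask β cells with detection p > 0.01 as missing; (4) drop sites with
> 1% missing cells.  The success rate is computed over the probes
surviving step 1, consistent with the sequential order.  This order
makes the filter idempotent: re-applying it to its own output removes
nothing.  Raw intensities are used without background correction or
normalization; an optional per-sample median-scaling toggle
(`normalize`) exists because the source protocol is self-contradictory
on this point, and it defaults to off.

### Stage trend regression

The genome-plot table regresses each probe's β on the ordinal stage code
(Normal = 0, Type I = 1, Type II = 2) by iteratively reweighted least
squares with Huber weights (tuning constant 1.345, statsmodels `RLM`).
Constant probes return p = 1; a zero robust scale (perfect fit) falls
back to OLS inference, floored at 10⁻³⁰⁰.  The regression runs on the
post-QC β matrix.

### Island annotation

Shore = within 2 kb of an island edge, shelf = 2–4 kb, open sea beyond —
the standard BeadChip convention (the source text names the categories
but not the distances).  N is the lower-coordinate flank.  Classification
is against the *nearest* island edge; exact distance ties (impossible at
≤ 4 kb when islands are ≥ 20 kb apart, as the simulator guarantees)
break to the N side of the higher island.  Coordinates are 1-based
inclusive throughout; BED export converts to 0-based half-open.
Summaries report proportions under two denominators (all sites, and
annotated-only — non-OpenSea for island context, non-Intergenic for
features) because both styles appear in published summaries of this
kind.  A probe counts once per category via its manifest record.

### Shared and specific gene sets

Sites map to genes through the manifest symbol; intergenic sites are
excluded and a gene's direction is hyper/hypo only when all supporting
probes agree, else `mixed`.  Mixed genes are excluded from shared-gene
classification with a logged count (the source procedure is silent on
them).  The stage-specific sets use
occurrence-specific = (overall ∩ occurrence) \ progression and
symmetrically for progression; the published set logic is ambiguous
between this reading and plain pairwise intersection, so the latter is
exposed as `exclude_other=False`.

### Integration

"Promoter" is TSS200 ∪ TSS1500 ∪ first exon.  Anti-correlation is the
direction rule (promoter ∧ ((hyper ∧ down) ∨ (hypo ∧ up))) — no
continuous methylation–expression correlation is computed, matching the
direction-level integration it reproduces.  The two external expression
profiles are not redistributable; the module consumes user TSVs or the
simulator's stand-ins.  2^−ΔΔCT is implemented directly from cycle
thresholds with a housekeeping gene and control sample.

## Synthetic data: what it emulates, and what it does not

The generator emulates a 9-sample 450K-style experiment: a probe
manifest with island/shore/shelf/open-sea context and gene features in
chip-like proportions; lognormal total intensities (σ = 0.25 around a
mean of 10,000); lognormal negative controls (200 values per sample,
mean 200); truncated-Poisson(14) bead counts with a configurable
fraction of planted sub-3 failures; Gaussian β-scale noise (default
sd 0.02, chosen to reflect the high technical replicability of array
β values); and a bimodal Beta-mixture baseline methylome.  Planted
effects are β offsets per group, clipped to [0, 1] with the clipped
value recorded as ground truth.

The intensity model inverts the β formula exactly: with
K = max(T+α, α/(1−β)), M = βK and U = (1−β)K − α reproduce the target β
to machine precision at zero noise (β = 1 is represented as U = 0 and is
deliberately unreachable, because the offset caps β below 1).

Not emulated: Infinium I vs II probe chemistry, dye bias, batch
effects, cell-composition structure, spatially correlated methylation,
SNP-overlapping or cross-reactive probes, and IDAT binaries.  Passing
recovery tests on these simulations therefore demonstrates correctness
of the calling logic under the stated noise model, not robustness to
array artefacts that real studies must additionally handle.

Planted-effect baselines leave headroom for the effect (e.g. base
β ∈ [0.12, 0.35] for +0.3 shifts) so clipping never attenuates the
planted contrast; recovery sensitivity is then a property of the caller,
not of the planting.

## Problem sizes and defaults

The real chip measures ~485k probes; the pipeline default is a
10,000-probe, 300-island simulation — the package's chosen desk-scale
stand-in that preserves all category structure.  Tests use 200–10,000
probes.  Recovery properties quoted in the test suite (sensitivity
≥ 0.80, false-discovery proportion ≤ 0.10 for planted |Δβ| = 0.30 at
noise 0.02, n = 3/group) are implementer-verified simulation properties
of this generator, not field results; observed values are ≈ 1.0 and
≈ 0.0 respectively.

## Known limitations

- The per-site t-test at n = 3 has low power; the pipeline inherits the
  threshold-based design it reproduces rather than improving on it.
- Gene direction via unanimity discards genuinely mixed genes from the
  shared-set classification (they are reported with a count).
- The fixture of published per-gene directions assigns the
  same-direction category for two genes (LOC255167, RAD51L1) whose
  individual directions are not printed in the source tables; the
  6/22/4 split and all classification counts are unaffected.
- No region-level (DMR) statistics, normalization beyond optional median
  scaling, or cell-composition adjustment.
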