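# Methods

## Hydrogen-bond accounting

Each base of a coding sequence is scored by the hydrogen bonds of the
Watson-Crick pair it forms in dsDNA: A = T = 2, G = C = 3.  A codon's
count is the sum over its three bases and lies in [6, 9]; over the 64
codons the counts are distributed {6: 8, 7: 24, 8: 24, 9: 8}.  Codons with
6–7 bonds are *cheap*, 8–9 *expensive*.  Within a synonym family the
count can be expressed relative to the family maximum or centred and
scaled by the family's sample standard deviation; single-codon families
(Met, Trp) have no scaled value.  The genetic code is NCBI translation
table 1 (via Biopython); stop codons carry bond counts and classes but are
excluded from family statistics.  RNA-alphabet input (U) is accepted and
mapped to T.

## Quality control and the codon matrix

A CDS enters the analysis iff its length is divisible by 3, it has at
least `n_positions + 1` codons (the start codon is removed before any
analysis), and no ambiguous base falls inside the analysis window.  The
"at least window + 1 codons" reading of the length filter is deliberate:
all positional outputs have exactly `n_positions` columns *after* start
removal, which the alternative reading (window codons in total) cannot
produce.  Retained CDSs are left-aligned into a matrix whose column j is
original codon position j + 2; every report labels positions in original
coordinates (start codon = position 1).  Ambiguity downstream of the
window is tolerated: such codons have no bond count, but they are
singleton families under shuffling and never enter the window.  Trailing
stop codons inside the window are ordinary codons (no stop-specific
filter).

## Positional profiles

For a per-codon valuation v (bond count, cheap indicator, RSCU, CAI, tAI,
structure probability) the profile is the per-column mean of v with a 95%
nonparametric bootstrap CI: whole CDS rows are resampled with replacement
(rows are the sampling units; resampling columns independently would
destroy within-CDS correlation), 1,000 times by default, and the 2.5th /
97.5th percentiles of the bootstrap means are reported together with the
bootstrap standard error.  Bootstrap means are computed as multinomial
resampling weights times the value matrix — distributionally identical to
index resampling for a mean, and fast enough to bootstrap a 2,000 × 100
matrix in well under a second.  All randomness flows through a single
seeded `numpy` Generator; identical seeds give bit-identical outputs.

## Codon-usage metrics

RSCU of codon c with k synonyms is its count divided by the mean count of
the family (family mean 1 by construction); CAI weights divide RSCU by
the family maximum.  Counts come from the whole input ORFeome (start
codons excluded); an optional reference usage table can be passed
instead.  Amino acids absent from the input get weight 1 ("no bias") and
are flagged, as are codons containing undetermined nucleotides.

tAI weights derive from tRNA gene copy numbers.  Codons are walked in
boxes of four sharing their first two bases; within a box the perfect
anticodon contributes (1 − s_WC)·tGCN and one wobble anticodon
contributes with its wobble constraint: G34:U3 for T-ending codons,
inosine (stored as A34) for C- and A-ending codons, U34:G3 for G-ending
codons.  ATG keeps only its dedicated anticodon, and with `sking=1`
(Bacteria/Archaea) ATA is read by the lysidine-modified tRNA with the
ninth s entry.  The default s-vector is
(0, 0, 0, 0, 0.41, 0.28, 0.9999, 0.68, 0.89); it is configuration, not
hard-coded, because published variants differ by domain of life.
Adaptiveness values are normalized over the 61 sense codons (including
ATG, so positional profiling has a value at every codon) and codons with
zero coverage receive the geometric mean of the nonzero weights.

mRNA secondary structure is *not* computed here.  An adapter parses the
per-position unpaired-probability tables produced by an external
partition-function folding tool (windowed, with span length up to u; the
study design used L = W = u = 40).  The table gives, for each end
position i, the probability that the stretch of length u ending at i is
unpaired.  "The probability of a base being unpaired" admits two
readings; the adapter exposes both: the default averages all finite
entries whose stretch *contains* the base, `mode="ending"` averages the
base's own row.  A codon's unpaired probability is the mean of its three
bases, and its structure-formation probability the complement.

## The ramp model

Three models are fitted to the positional bond-count means with x
re-indexed so the first analyzed position (original position 2) is x = 0
— this makes C exactly "the bond count at the first codon after the
start":

- uniform y = A (1 parameter),
- linear y = Bx + C (2),
- bounded exponential y = ACe^{Bx} / (A + C(e^{Bx} − 1)) (3), evaluated
  in the overflow-safe logistic form AC / (C + (A − C)e^{−Bx}).

Fits are weighted least squares; the default weight of a position is the
inverse bootstrap variance of its mean (uniform weights by flag — the
choice matters little in practice because positional variances are nearly
homoscedastic).  The exponential fit uses trust-region least squares with
the analytic Jacobian, parameter bounds A, C > 0, |B| ≤ 10, tolerances
1e−10 and at most 1,000 function evaluations.  Starting values come from
a logistic-style self-start: A₀ = max mean, C₀ = first mean, B₀ from the
early-position slope via the logistic ODE y′ = By(1 − y/A), clipped to
[10⁻³, 2].  Standard errors and two-sided Wald p-values use the
asymptotic covariance s²(JᵀWJ)⁻¹ with a t reference on n − p degrees of
freedom.  If the optimizer fails, the returned fit is flagged
unconverged and carries the fallback parameters: initial content = the
minimum positional mean, carrying capacity = the mean after trimming 10%
of positions from each end (10 + 10 for the standard 100-position
window); profiles shorter than 21 positions cannot be trimmed and raise.

AIC and BIC are computed from the weighted RSS with the Gaussian scale
counted as a parameter.  Model selection walks from simple to complex and
adopts a more complex model only when it improves **both** AIC and BIC.
This parsimony guard is a deliberate design choice: for nested Gaussian
fits, plain AIC prefers a spuriously complex model with probability
P(χ²_k > 2k) — about 14% per extra parameter, roughly 25% against the
uniform model across both alternatives — which would mislabel genuinely
flat profiles far too often to be useful as a ramp detector.  The joint
AIC+BIC rule keeps that false-complexity rate at the percent level while
leaving real ramps (which win both criteria by hundreds of units)
untouched.  A `guard="aic"` mode returns the plain AIC winner and flags
AIC/BIC disagreement for anyone wanting the unguarded behaviour.

A bounded-exponential fit is flagged `success` when it converged, is best
under both criteria, and its rate parameter B has Wald p < 0.001.  This
operational definition of a "successful ramp fit" is this package's own
and is labelled as such in reports.

## The shuffling null and selection statistics

The null asks what per-position bond totals the ORFeome would show if
each CDS scattered its synonymous codons at random along its own length.
For each simulated ORFeome, the codons of every amino acid within every
CDS are independently and uniformly permuted over that amino acid's
positions — the amino-acid sequence and per-CDS codon multiset are exact
invariants; stop codons form their own family and single-codon families
are fixed points.  Shuffling acts on full-length CDSs and the result is
re-windowed, so synonyms can migrate into and out of the analysis window
(a window-only mode exists as a sensitivity check).  200 simulations
yield E (mean) and σ (SD, ddof = 1) of the per-position totals.

The observed statistic O is the per-position **sum** of bond counts over
CDSs — a count, as a χ² framing requires; means would rescale z² only if
σ were rescaled identically.  Per position z² = ((O − E)/σ)², with σ = 0
positions contributing 0 and flagged (shuffling cannot move invariant
positions, so they carry no signal); Σz² is the χ²-type total.  The
χ-gram is (O − E)/E; a (O − E)/√E variant sits behind a flag because the
flattened rendering of the defining formula is ambiguous, and the /E
reading is the default and the literal one.  For cross-ORFeome displays
the z² profile is min-max normalized to [0, 1] and the χ-gram centred and
scaled.  The 5′ summary compares the first 15 analyzed positions against
the remainder and reports the sign of the 5′ mean χ-gram (negative =
selection toward fewer bonds).

Shuffles are drawn by a vectorized group permutation: positions are
sorted once by (CDS, family), and each draw orders the group's values by
iid 32-bit random keys packed into one int64 sort — one argsort per
simulated ORFeome, ~5 ms per 1,000 × 100 matrix.

## Strata comparisons

Operon membership is an input contract (TSV: cds_id, operon_id, 1-based
position; operons need ≥ 2 consecutive positions), not a computation.
CDSs grouped by within-operon position (1–3 by default) are compared on
per-CDS mean bond counts in five 20-codon windows across the analysis
window, over the whole window, and over the full CDS length: two-sided
Wilcoxon rank-sum tests for every pair (Benjamini–Yekutieli adjusted
across the whole report — valid under arbitrary dependence) and a
Kruskal–Wallis test per region.  Groups with fewer than two members are
skipped and flagged.

Expression strata intersect, across all experiments of a compendium, the
CDSs above the top or below the bottom abundance percentile; rank ties
break by stable input order for determinism.  The paired thresholds of
the study design — (5, 13), (10, 18), (15, 23), (20, 26), (25, 30),
(30, 35) — are the documented presets (the looser bottom cut makes the
two sets comparable in size).  Group profiles come with a LOESS smoother
(span 0.75 by default; the span is not dictated by anything and is
exposed).  Correlation analyses (profile networks, per-region
hydrogen-bond vs. structure-probability correlations) use Spearman's ρ
(Pearson optionally), BY-adjusted, significance at adjusted p < 0.01.

## The synthetic generator

The generator is the ground truth against which everything is tested.
For a target curve μ(x) — the bounded exponential, or a flat control —
each position draws an amino acid from the configured frequencies
(uniform over the 20 by default) and then a codon from its family under
the exponential tilt P(c | aa, θ) ∝ exp(θ·h_c), with θ_x solved by
bracketed root finding so the pool-expected bond count equals μ(x).
Exponential tilting is the maximum-entropy distribution satisfying a mean
constraint — exactly what the target curve asserts, and nothing more.
With uniform amino-acid frequencies the achievable means span
(6.9, 7.9) bonds/codon; requested curves outside that interval raise with
the feasible range, and targets are clamped 1e−6 inside it to keep the
root finding well-posed (the default carrying capacity 7.9 is the pool's
supremum and is reached via this clamp, which makes late positions nearly
deterministic in their codon choice).  A start ATG is prepended; beyond
the ramp window codons are drawn uniformly among synonyms (θ = 0).

Companion generators implant known effects: operon tables whose
leading CDSs are regenerated with μ(x) − δ over the first 20 analyzed
positions (δ shifts saturate at the feasible boundary rather than raise —
they are effect injections, not user curves), and log-normal expression
compendia whose abundance can be negatively coupled to a CDS's 5′ bond
content.  All outputs are bit-reproducible from (spec, seed).

What the generator does *not* emulate: real amino-acid usage, genomic GC
heterogeneity between CDSs, length variation, mutational processes, or
any correlation structure beyond the positional mean.  Passing tests
therefore demonstrate that the pipeline recovers a positional-mean signal
of the modelled form from sequence data — not that any particular
organism carries one.

## Problem sizes and test design

The acceptance-style checks run at desk scale, chosen once: 2,000 CDSs ×
101 codons and 20 seeds (0–19) for parameter recovery and model-selection
sanity; 1,000 CDSs × 101 codons with 200 shuffled ORFeomes per run for
the selection-test calibration.  At those sizes the recovery of the rate
parameter B is the binding constraint: its sampling SD is ≈ 2.5%
relative, so the median absolute error sits near 1.9% — an intrinsic
property of fitting positional means at this sample size, not of the
optimizer.  The exact-null oracle enumerates all synonymous permutations
of a three-CDS toy ORFeome and checks the Monte-Carlo E and σ at
n_sims = 200 against the enumeration within Monte-Carlo error; the
metric oracles check RSCU/CAI against brute-force recounts and tAI
against an independently coded wobble-pair enumeration.

## Known limitations

- Operon delineation, RNA folding, and tRNA inventories are inputs; the
  package parses and analyses but never computes them.
- The χ-gram denominator and the unpaired-probability averaging each have
  two defensible readings; both are implemented, the defaults documented
  above.
- CAI weights of codons never observed in the usage table are 0, which
  technically leaves the (0, 1] range; real ORFeomes rarely exercise
  this.
- The LOESS smoother reports no interval of its own; uncertainty is
  carried by the underlying bootstrap profile.
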