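# Methods

This note documents the models and procedures implemented in `satarray`,
the defaults they ship with, and the boundaries of what the synthetic
fixtures can and cannot demonstrate.

## Orientation inference

A transcript's strand is decided by majority vote.  Coding transcripts:
the sign of the reading frame among the (at most three) top-ranked
protein hits; a sign tie falls back to EST orientation counts.  Non-coding
transcripts: the EST 5′→3′ vs 3′→5′ majority directly.  Exact ties, or no
evidence, leave the orientation *unknown*, and unknown transcripts are
excluded from probe design rather than guessed — a missed transcript is
recoverable, a strand-flipped probe set is not.

## Probe composition filter

Candidates are 60-mers from both strands of the oriented transcript.
Window positions are indexed by `pos3`, the 1-based distance from the
transcript 3′ end to the window's 3′-terminal base; positional classes are
inclusive bands |pos3 − 50| ≤ 40 and |pos3 − 350| ≤ 40.  The 3′ anchoring
reflects the 3′ bias of oligo-dT-primed labeling.  Bounds:

| rule          | bound              | convention |
|---------------|--------------------|------------|
| %G            | < 50               | strict     |
| %GC           | [35, 55]           | inclusive  |
| Tm            | [68, 76] °C        | inclusive  |
| homopolymer   | ≤ 6 bp             | inclusive  |
| alphabet      | ACGT only          | any other base rejects the window |

Tm uses the salt-adjusted base-composition formula
Tm = 81.5 + 16.6·log₁₀[Na⁺] + 0.41·%GC − 600/L with [Na⁺] = 0.1 M by
default (configurable).  It is deterministic and parameter-light; for
fixed-length probes it is monotone in %GC, so the Tm bounds act as a
secondary %GC band (at 0.1 M, Tm ∈ [68, 76] ⇔ %GC ∈ [32.0, 51.5]).  A
nearest-neighbor model could be substituted behind the same interface if
hybridisation-temperature accuracy ever matters; for bounding a filter it
does not.

Positional selection takes, per transcript, the criteria-passing candidate
closest to each window centre (ties toward the smaller `pos3`, i.e. nearer
the 3′ end): one sense P50, one sense P350, one antisense P50.  All
criteria-passing sense candidates are additionally forwarded through the
specificity screen and recorded in the audit trail, so a platform wanting
deeper sense coverage can draw on them.

## Specificity screen

Cross-hybridisation risk is assessed with ungapped local alignment
(match +1, mismatch −3) of each probe against every database sequence on
both strands.  Raw scores are rescaled to bits with λ = 1.374, K = 0.711
(classic ungapped blastn parameters), under which a 21-bp perfect match
scores 42.1 bits.  A probe passes when its own transcript yields a
full-length 100%-identity hit and every other hit is strictly below 42.1
bits.  Gapped alignments are deliberately not modelled: a 60-mer duplex
bulge suppresses hybridisation enough that the ungapped score is the
relevant risk measure, and the threshold's 21-bp interpretation only holds
without gaps.

The scan is **exact**, not seeded: every diagonal of the probe × subject
comparison is evaluated with a reset-at-zero maximum-segment recurrence,
vectorised with numpy across diagonals (and across probes in the bulk
path).  A seed-and-extend heuristic was considered and rejected: under
+1/−3 scoring an alignment can reach the 42.1-bit threshold with a longest
exact run far shorter than any practical seed (score 21 is attainable with
runs of 4–8 bp), so no seeded scan can be guaranteed equivalent to the
exhaustive one.  At the scale this toolkit targets (thousands of probes ×
thousands of ESTs) the exact vectorised scan is fast enough that the
guarantee costs nothing.  Tests verify the scan against an independent
ungapped aligner (Biopython's `PairwiseAligner` with gaps forbidden) on
hundreds of randomised instances.

## Spot flags

A spot enters the analysis only if it is *well above background*:

1. a two-sided Welch two-sample *t* test of foreground vs background,
   computed from the per-spot summary statistics (means, SDs, pixel
   counts), rejects at α = 0.01 **and** the foreground mean is strictly
   greater (the test is directional in effect even though two-sided in
   form), and
2. the background-subtracted signal strictly exceeds 2.6 background SDs.

Welch's form was chosen because foreground and background pixel variances
are never comparable; α = 0.01 is conventional for per-spot screening.
All "greater than" comparisons are strict, so boundary values
(bg_sub = 2.6·SD exactly) fail.

## Normalization

Both channels of every array are normalized separately, in two steps:

1. **Global (linear)**: background-subtracted intensities of each
   array × channel are median-scaled to the experiment-wide median.
2. **LOWESS (non-linear)**: each channel's log₂ intensity deviation from a
   per-probe pseudo-reference (the probe's median log₂ intensity over all
   channels and arrays of the experiment) is smoothed against the
   reference with LOWESS (span 0.3, 3 robustness iterations) and the
   fitted trend subtracted.  This removes intensity-dependent dye bias
   while leaving genuine sparse fold changes in place.

M = log₂(experiment) − log₂(control) is then recomputed per spot from the
normalized channels, with each array's dye layout deciding which channel
is "experiment" (so dye-swapped arrays need no sign fix afterwards);
A is the mean of the two normalized log₂ intensities.  Spots failing the
background flags are excluded from M/A and from all majority denominators
— never imputed.  On noise-free, globally-scaled input the procedure is
the identity up to a constant and preserves within-channel rank order.

## Modified HTself calling

The credibility window is built from null (A, M) points.  Two null modes
are supported and logged: self-self spot pairs when the experiment
provides them, otherwise all spots of the comparison under the
most-genes-unchanged assumption (the default).  At each point of a
0.1-spaced A grid, the bounds are the empirical ((1−c)/2, 1−(1−c)/2)
quantiles of M among null points within ±window_width/2 in A (defaults
c = 0.90, width 1.0); windows holding fewer than 30 points widen
symmetrically until they qualify.  Bounds are linearly interpolated
between grid points and extrapolated by the nearest bound (with a logged
warning) outside the grid.

A spot is *up* when M strictly exceeds the upper bound at its A, *down*
below the lower bound, otherwise *within*.  A probe is called within one
biological replicate when ≥ 70% of its usable spots carry the same status;
the experiment-level call requires both replicates to agree on the same
direction.  Coverage of the window is calibrated: on 20,000 held-out
simulated null spots the 90% window covers 90 ± 1.5%
(`scripts/acceptance.py` recomputes this).

**Known limitation.**  With the all-spots null mode, the empirical
quantiles are only trustworthy while the contamination of each tail by
genuine fold changes stays below (1−c)/2 per tail (≈ 5% at c = 0.90)
*within each local A window*.  On small arrays where planted or real
changes concentrate in an intensity band, local windows inflate and
sensitivity drops — visibly so below a few hundred probes.  This is the
method's stringency, not an artifact; experiments expecting massive
regulation should supply self-self reference hybridisations instead.

## Pair patterns

Transcripts carrying both an accepted sense and antisense probe form one
pair each (sense P50 preferred, matching the antisense location).  At each
timepoint a member is *inside* when not above background, else *up*
(M > 0) or *down* (M < 0); M exactly zero maps to *inside*, since a zero
ratio carries no direction.  A member counts as above background when the
two-replicate rule admits it in at least one of the timepoint's two
samples (control or treatment) — the ratio compares both, so presence in
either suffices.  The 3×3 contingency per timepoint always partitions the
pairs.

## Enrichment

Category over-representation uses the upper-tail hypergeometric
probability P(X ≥ k) for k study members of a category with K population
members, computed via `scipy.stats.hypergeom` (verified in tests against
direct binomial-coefficient enumeration for every instance with N ≤ 20).
The e-score is Bonferroni: p times the number of categories tested
(those with k ≥ 1), capped at 1.  Genes may sit in several categories and
count once in each; uncategorized genes remain in N.  Because the statistic
is discrete, the null rate of p < 0.05 is conservatively *below* 5%
(≈ 3.6% for 100-gene categories in a 2,000-gene population with 200-gene
study sets); the test suite checks the empirical rate against the exact
discrete expectation rather than against 5% itself.

## Synthetic fixtures

The generators emulate, with known truth: transcript pools (default
300–900 bp, 45% GC, 70% coding, planted ORFs on the true strand);
orientation evidence whose majority matches truth with probability exactly
1 − error_rate (the majority's correctness is drawn first, then records
consistent with it — strict majorities, so generated evidence never ties);
and two-channel spot tables.  The signal model per spot is

    fg = baseline · 2^(±fold/2) · 2^(bias(A)) · lognormal(cv) + N(bg_mean, bg_sd/√n_px)

with the planted log₂ fold split symmetrically between the experiment and
control channels, a smooth quadratic dye bias on the red channel (so
LOWESS can provably remove it), log-normal multiplicative foreground
noise (default cv = 0.1), and Gaussian additive background (default
50 ± 10 intensity units) — typical mid-range two-color scanner behavior.
Each timepoint yields two biological-replicate arrays, the second
dye-swapped, each probe spotted in duplicate (defaults matching common
custom-array practice).  All randomness flows from a single seed, and all
generators are byte-deterministic for a fixed seed.

Not emulated: spatial artifacts, print-tip effects, scanner saturation,
carry-over between channels, pixel-level image statistics, and sequence-
dependent hybridisation efficiency.  Passing the recovery tests therefore
shows the *pipeline logic* is sound under a realistic noise geometry — it
does not certify performance on arrays with strong spatial or chemical
artifacts, which would need the flags and LOWESS span re-examined.

## Problem sizes and defaults used in validation

The test suite validates the composition filter on 10,000 generated
transcripts, scan exactness on 200 randomised probe/database instances
(5–50 subjects of 100–500 bp — sizes drawn across the range the screen
targets at desk scale), fold-change recovery on a 1,388-probe single-
timepoint experiment (sensitivity ≥ 0.90 and false-call rate ≤ 0.10 at
planted |log₂ fold| ≥ 2 under default noise), window coverage on 20,000
null spots, and enrichment calibration over 1,000 random study sets.
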