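# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices made where the
analysis left room for interpretation.  It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Conventions

Frames are 0-based; every interval is half-open `[start, end)`.  The
default frame rate is 25 Hz, so the 400 ms median bout is 10 frames and
the 5 s pre-contact window is 125 frames.  A bout is a maximal run of one
syllable; the missing label `-1` breaks a run, and bouts separated by a
missing gap are not adjacent for transition counting or syntax windows.
Proportions exclude missing frames from their denominators.

## Usage statistics and the DM set

Onset proportion counts bouts regardless of length; frame proportion
counts frames.  Syllables are retained when their pooled onset proportion
exceeds 0.5% (strict inequality; a value of exactly 0.005 is excluded).
The solitary/dyadic contrast is a per-syllable two-sided Mann-Whitney U
on per-animal onset proportions with Benjamini-Hochberg correction at
alpha 0.05 across the syllable family.  Syllables that are constant and
identical across every animal are skipped (the rank test is undefined)
and reported as such rather than failed.

Contact association uses, per syllable, the 2x2 table (onsets of this
syllable vs all others) x (onset frame inside vs outside active
contact), a chi-squared test without continuity correction, and
Bonferroni correction across the tested syllables.  An onset belongs to
a contact or distance bin through its bout's *first frame*; the analysis
does not split bouts that straddle a boundary.  The accompanying two-way
ANOVA (syllable x contact, and syllable x distance quartile) is a
standard fixed-effects linear model on per-animal proportion cells;
significance calls follow the per-syllable post-hoc tests, with the
ANOVA reported for completeness.  Distance-quartile edges come from the
pooled inter-mouse-distance distribution over all dyadic recordings, so
one global set of quartile values applies to every recording.

## Annotation pooling and clean onsets

Scored contact bouts of one type separated by a gap strictly shorter
than 6 s (150 frames) are merged.  The merge is gap-based because its
purpose is a clean 5 s pre-contact control window: a bout qualifies for
aligned analyses only if no same-type bout intersects the 125 frames
before its onset and the full aligned window fits inside the recording.
Overlapping active/passive annotations are left as scored; each type is
analyzed independently.  No minimum bout duration is imposed before
pooling.

## Transition networks and centrality

Transition counts come from consecutive adjacent bout pairs; rows are
normalized to 1 and the diagonal is structurally zero.  Centrality is
the dominant **left** eigenvector of the transition matrix (incoming
influence), L1-normalized, computed with the lazy power iteration
`v <- (v + vP)/2`, which has the same fixed points as `P` but also
converges for periodic chains; tolerance 1e-10, at most 1e5 iterations.
Every returned vector is checked against the stationarity identity
`cP = c` (for a row-stochastic matrix the left dominant eigenvector *is*
the stationary bout distribution — which also means usage and centrality
are mathematically coupled quantities).  If the support graph is not
strongly connected the computation restricts to the largest strongly
connected component with zeros elsewhere and emits a warning; we prefer
this over additive damping, which would distort the probabilities (the
right-eigenvector variant is available via `orientation="outgoing"`).

Per-edge context tests are limited to edges with a pooled count of at
least 10: testing all `n(n-1)` edges would make the Bonferroni family
statistically vacuous.  The edge table records the probability change,
its sign, and whether the edge targets a DM syllable.

## Composition divergence

`D_KL(p||q) = sum p ln(p/q)` in natural-log units (nats); the reference
q is smoothed with a 1e-6 pseudocount per category and renormalized so
its support covers p, and `0 ln 0 := 0`.  The contact-aligned
time-course collects, for each frame offset in `[-125, +250]`, the
syllable labels of both animals of every qualifying bout (pooled across
recordings — the pooled reference rather than per-animal references; a
per-animal variant is a flag) and scores each bin against the overall
dyadic composition.  Significance per bin compares the observed
divergence with a bootstrap null: 500 multinomial draws of the typical
bin size from the pooled baseline-window composition, p-values
`(1 + #{null >= obs}) / (B + 1)`, Benjamini-Hochberg across bins; bins
with fewer than 5 observations are masked, not tested.  A z-score
variant against the null mean/sd is also returned.  The joint (two-
mouse) time-course uses ordered syllable pairs (n^2 categories) with the
same machinery; occupancy is sparse, which is why the pseudocount and
the support mask matter there.  The negative control shuffles bout
order within each sequence (durations preserved, frames re-flattened),
destroying event alignment while keeping all marginal statistics.

## Syntaxes, families and kinematic classes

Length-3 syntaxes are overlapping windows (stride 1) over adjacent
bouts.  A syntax family is the set of triples within Hamming distance
<= 1 of its reference — substitutions only, no rearrangements.  (The
membership threshold is "at most one differing position"; the worked
membership example forces <=, not <.)  Onset-aligned syntax frequencies
are per onset (within an offset bin they sum to 1 over syntaxes);
z-scores use the baseline window, by default frames [-3, -1] (the
100-50 ms pre-onset band rounded outward — an interpretation, and
configurable).  Because a genuinely event-locked syntax can be absent
from a short baseline, the baseline standard deviation is floored at
one onset's worth of frequency (1/n) rather than masking the syntax
outright; with zero baseline activity and zero post-onset activity the
z-score is exactly 0, so the floor cannot create false positives.
Syntax onsets are assigned to the first frame of their first bout; the
default ranking keeps the top 4 by peak post-onset z.

Kinematic classification maps each syntax occurrence (or 30-frame
rolling window) to x = inter-mouse distance at its start and y = the
change of that distance.  The four primary classes partition the plane
at the 100 mm contact threshold (see README); boundary ties, a measure-
zero set, go to the stationary classes and are logged.  The control
classes — approach-control: y < 0 and x + y > 100 mm; leave-control:
y > 0 and x > 100 mm — are a declared reconstruction of "same distance
change, no contact involved"; their exact geometry cannot be fixed from
a verbal description and is documented as an interpretation.  The
shuffled inter-mouse-distance control permutes each animal's position
samples independently; the random control draws uniform point pairs in
the arena (1e5 pairs by default in tests; the scale is a parameter).

## PCA and context separation

PCA is computed on centered per-track proportion features via SVD with
a deterministic sign convention (largest-|loading| entry positive).
Features are *not* standardized by default — proportions share a scale —
but a `scale=True` flag divides by per-feature standard deviations.
The DM-vs-DU contrast is a one-sided Mann-Whitney U on absolute
loadings per component, Bonferroni over the tested components (5 by
default).  Context separation is summarized by the silhouette of the
grouping on the first two score components; the silhouette is an
artifact addition (the source analyses show, but do not quantify, the
separation).  On the synthetic data the planted context effect sits on
the low-frequency planted syllables, whose raw-proportion variance is
dwarfed by the between-animal variance of high-frequency syllables;
the planted structure is therefore recoverable by the standardized
variant, which the planted-recovery tests and the pipeline's scaled
summary fields use, while the unscaled decomposition remains the
default output.

## The synthetic-data model

The generator emulates the statistical structure the analyses assume,
not limb kinematics.  All randomness flows from one root seed through
named substreams (base matrix, per-animal usage, row noise, sequences,
tracks, events, contacts), so regeneration is byte-identical and
components can be rebuilt independently.

**Repertoire.**  A symmetric-Dirichlet base matrix is column-scaled to a
graded usage profile `u_i ∝ exp(-0.08 i)` (bout frequencies spanning
roughly 6.5% down to 0.5%, like a real 32-syllable repertoire) and
row-renormalized.  Animals differ by lognormal per-syllable usage
multipliers (sigma 0.6 — individual repertoires vary substantially, and
the value is chosen so that group contrasts at n = 20 per context are
powered but not saturated) plus Dirichlet row noise (concentration 150).
Multipliers are drawn independently per context: the two sessions of an
animal are weeks apart and are treated as fresh draws around the base.

**Planted context effect.**  In the dyadic base the planted set (default:
the 8 rarest syllables, ids 24-31) is modulated as a *redistribution*:
the first half gains incoming transition mass by the factor
`dm_effect x centrality_boost` (1.6 x 1.5) and the second half loses it
(factor 0.15), approximately balancing total mass so the 24 unplanted
syllables stay unmodulated — a repertoire where more stationary behavior
comes at the expense of specific locomotion, not of everything equally.
Because the left dominant eigenvector of a stochastic matrix is its
stationary distribution, usage and centrality effects are inherently
coupled; the two config parameters act through one column factor.

**Sequences.**  Bout labels follow the per-animal matrix; durations are
i.i.d. geometric with success probability `1 - 0.5^(1/(m - 0.5))` so the
sample median lands on m = 10 frames.  Explicit-duration (semi-Markov)
generation keeps duration and syntax structure independent, which the
bout-level analyses require.

**Locomotion and episodes.**  Each mouse performs a corner-seeking
waypoint walk (75% corner targets, exponential dwells, per-frame step
2.4 mm scaled by a per-syllable speed profile: planted syllables near
zero, traversal syllables fast).  Dyads run scheduled
approach-contact-leave cycles (one per 60 s): the partner holds its
position, the focal mouse travels to it (2 s), dwells in contact
(2.5 s), and retreats (2 s).  During the final approach and initial
leave frames the focal mouse's labels are overwritten with triples from
the configured families ((9,0,5) toward, (11,2,8) away), half of them
Hamming-1 members.  Proximity runs (inter-mouse distance < 100 mm) are
scored active with probability 0.7, else passive; during active runs
both animals' labels are redrawn from a contact composition
concentrated on the up-modulated planted syllables, and a stereotyped
greeting triple (24,25,26) opens each active run — the planted
event-locked syntax.  No quantitative contact-rate statistics exist to
calibrate against; the episode schedule is an order-of-magnitude choice
and is labeled as such.

**What the generator does not emulate.**  Realistic pose or limb
kinematics, scorer reaction-time jitter, overlapping active/passive
annotations, drift or grooming clusters below the onset filter, and any
coupling between light cycle and behavior (the light-cycle factor is
planted null).  Passing recovery tests therefore demonstrate that the
pipeline detects these planted effect classes at realistic noise — not
that real recordings contain them.

## Problem sizes in the test suite

Planted-recovery checks run the pinned default conditions (20 animals
per context, 20-minute recordings) over 20 replicate seeds.  Type-I
calibration uses the matched null configuration at a reduced size (10
animals per context, 10-minute recordings, 5 dyads) over 50 seeds —
type-I behavior of rank tests, Bonferroni families and bootstrap bands
does not depend on scale, and the reduced size keeps the suite quick.
Smoke-level fixtures use 8 animals per context, the smallest group for
which a two-sided rank test can survive a 32-way multiplicity
correction (the minimum two-sided Mann-Whitney p at n = 6 vs 6 is
2/924 ≈ 0.0022 > 0.05/32).

## Known limitations

* Eigenvector centrality on reducible supports silently concentrates on
  the largest component; with very short recordings this can zero out
  rarely visited syllables.
* The joint composition time-course is support-limited: with n^2 = 1024
  categories and a few hundred qualifying bouts, smoothing dominates
  rare cells, and its significance band is conservative.
* The two-way ANOVAs treat per-animal proportion cells as independent
  observations (per-animal aggregation is one of several defensible
  choices; the per-syllable post-hoc tests carry the inference).
* Syntax-family occupancy attributes a frame to a family if *any*
  member occurrence spans it; overlapping occurrences are not
  deduplicated, which is intentional for occupancy fractions but makes
  raw member counts non-additive.
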