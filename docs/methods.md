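# Methods

## Composition analysis

Each word *w* carries a set of typed semantic features; counts
*c*<sub>enc</sub>, *c*<sub>fun</sub>, *c*<sub>per</sub>, *c*<sub>tax</sub>
partition the set and proportions *p* = *c*/*total* sum to exactly 1 per
word. Totals are compared between parts of speech with a Welch
(unequal-variance) t test, reported in the noun − verb direction with
Welch–Satterthwaite degrees of freedom. If both groups are constant and
equal the test degenerates to t = 0, p = 1; constant groups with unequal
means raise an error (the df is undefined).

Proportions are modeled as proportion ~ FT × POS with each word
contributing four observations, fitted by OLS with sequential (type I)
sums of squares, feature type entered first. The design forces the POS
main effect to zero — every word's POS-marginal mean is 0.25 — so term
order cannot change the reported rows; residual df = 4·N − 8. Cell
standard errors are model-based, √(MSE/n<sub>pos</sub>), and the
noun-minus-verb contrast per feature type equals the cell-mean difference
(the within-word design is balanced) with an unadjusted 95% t-interval,
SE = √(MSE·(1/n_N + 1/n_V)). No multiplicity adjustment is applied to the
four contrasts. Treating the four within-word proportions as independent
observations understates within-word dependence; the structural results
used downstream (zero POS effect, residual df, contrast identity) are
exact regardless.

## Semantic networks

A child's network has their produced words as nodes, an edge wherever two
words share ≥ 1 feature of the restricted type, and edge weight = number
of such shared features ("all" counts every type, and equals the sum of
the four restricted weights). Isolated words stay in the graph and
contribute degree 0 to their part of speech's mean — an isolate is a real
datum about semantic structure. Words in a child's record but missing
from the norms are dropped with a warning rather than an error. Graphs
are `networkx` objects; the null-model simulations use an equivalent
word × word shared-feature count matrix (binary incidence product) for
speed, and the test suite checks the two routes against each other and
against brute-force pairwise set intersections.

## Random-network normalization

Normalized degree answers: *how connected is this child's vocabulary
compared with a random selection of the same number of nouns and verbs?*

- **Space sampling.** The distinct (n_nouns, n_verbs) points observed
  across children are PCA-decomposed (raw, unstandardized axes by
  default; standardization is available). A point is interior when its
  score on each principal axis is within 2 SD of that axis's scores.
  The simulated subset is: ⌈15%⌉ of interior points uniformly without
  replacement, every exterior point, and every edge point (per observed
  noun size, the min and max observed verb size, and symmetrically).
  Fewer than three points, or a collinear set, degenerates to sampling
  everything.
- **Null simulation.** At each sampled point, `reps` random networks are
  built from uniform draws without replacement; the per-replicate mean
  weighted degree per part of speech is recorded. Replicates at points
  with zero words of a part of speech contribute nothing to that POS's
  histograms. RNG substreams are derived per point from the top-level
  seed, so results are independent of execution order.
- **Histograms.** Replicate means are binned into 64 equal-width bins
  (default; configurable) with edges shared across the whole space per
  restriction × POS, spanning [0, max·(1 + 1/n_bins)]. Columns are
  probability-normalized. Unsampled points are covered by
  piecewise-linear (Delaunay) interpolation of each bin's mass across the
  size plane, with nearest-sampled-point fallback outside the convex
  hull, then renormalized.
- **Smoothing.** A Gaussian kernel along the degree axis with σ = 2 bin
  widths (reflected at the boundaries, renormalized) is available to
  polish binning and interpolation artifacts. The end-to-end builder
  applies it adaptively (`smooth="auto"`): only when σ is at most one
  third of the median column standard deviation, i.e. when smoothing
  inflates the column sd by < 6%. This guard matters: the degree scale
  spans the whole space (means from ~35 at the smallest sizes to ~680 at
  the largest in a default lexicon) while per-point null spread is ~5–20,
  so at 64 shared bins a column occupies only a few bins and a 2-bin
  kernel would roughly double the null spread — compressing every
  percentile toward 50 and destroying the probability-integral-transform
  calibration that defines a percentile normalization (measured: KS
  statistic 0.18 against Uniform(0,100) with forced smoothing vs 0.026
  without; at 256–1024 bins the kernel is slight and is applied). The
  sub-bin rule below already removes discretization artifacts at coarse
  resolution.
- **Percentile.** Normalized degree = 100 × (mass of bins entirely at or
  below the raw value + a linear share of the containing bin); values
  below/above the bin range map to 0/100. Linear apportioning within the
  containing bin reduces discretization bias and keeps the transform
  monotone.

Calibration is verified two ways: children whose vocabularies are
uniform random draws get normalized degree with mean 50 and pass a KS
test against Uniform(0,100); and at sampled points the histogram
percentile agrees with the direct empirical at-or-below proportion over
the raw replicates to well under 5 percentile points.

## Cluster-based permutation testing

Within-child condition pairs (noun vs verb normalized degree within a
network type; encyclopedic vs perceptual within a part of speech) are
grouped into vocabulary-size bins of 20 words, labeled by the right edge
of the half-open interval ((k−1)·20, k·20]; vocabulary size is
n_nouns + n_verbs, and children missing either condition are excluded
from that pairing. Per bin, a paired t on the differences (positive when
A > B); bins with n < 2 or zero-variance nonzero differences are skipped
and break cluster contiguity. Clusters are maximal same-sign runs with
|t| ≥ 3.29 (two-tailed p ≈ .001 at large df); cluster mass is the sum of
member t values. The null shuffles condition labels independently within
each child (each child occupies exactly one bin, so this is a per-child
sign flip of the difference), recomputes the full pipeline, and keeps the
maximum |cluster mass| per permutation — the max-statistic construction
that controls family-wise error. Empirical p = (1 + #{null ≥
|mass|})/(1 + n_perm), never zero. Verified: family-wise error under the
exchangeable null falls in [0.02, 0.09] at nominal .05, and a global
label swap negates every t and mass while leaving p unchanged.

## Synthetic data generator

The generator's defaults are the study conditions the analyses assume:

- **Lexicon.** 359 nouns, 103 verbs. Per-word totals ~ round(Normal),
  noun mean 13.15 / SD 3.42, verb mean 12.41 / SD 3.97, truncated at ≥ 3.
  Type counts ~ Multinomial over per-POS profiles: nouns (enc .27,
  fun .20, per .41, tax .12), verbs (.55, .03, .28, .14). Feature labels
  are drawn without replacement from per-type shared pools (enc 400,
  fun 200, per 400, tax 120) with Zipf-like reuse, P(rank r) ∝ r^−s,
  s = 1 by default. Pool sizes and the exponent are free design knobs
  chosen so that typical word pairs share 0–2 features of a type (dense
  enough for connected networks, sparse enough for isolates); the true
  sharing distribution of published norms is not reproduced, only its
  heavy-tailed character.
- **Population.** Ages uniform over 16–30 months; child ability ~
  Normal(0, 1); word difficulty ~ Normal(0, 2) plus a verb offset of
  1.25 (nouns earlier). A word is produced iff logistic(ability +
  0.35·(age − 23) − difficulty) exceeds a uniform draw. These values
  were set once so that surviving vocabularies span roughly 20–460 words
  with a strong early noun bias (noun:verb ≈ 4–6 in small vocabularies).
  Percentiles are average ranks of vocabulary size within age-month
  groups × 100/n; children at or below the 20th percentile are removed,
  mirroring the late-talker exclusion.
- **Effect injection.** `inject_effect` scales the Zipf exponent of
  chosen (POS, feature type) cells; multiplier 1 is exactly inert, 0
  makes draws uniform over the pool. Because the normalization's random
  networks are drawn from the *same* lexicon, inflating a cell's sharing
  uniformly moves raw degree but not normalized degree; the observable
  phenomenon is that *early-learned* words are disproportionately
  connected. The population model therefore couples injection to
  acquisition: for cells with multiplier m ≠ 1, a word's difficulty is
  reduced by 0.75·log(m)·z, where z is the standardized within-POS
  type-restricted weighted degree of the word in the full lexicon. With
  m = 3 this yields verb-encyclopedic normalized degree near the upper
  percentiles and a detected V > N cluster in essentially every seed;
  with no multipliers the term vanishes and the population is
  connectivity-neutral.

What the generator does *not* emulate: real acquisition-order norms,
word frequency, semantic category structure, caregiver report noise, or
any fitted relationship to published feature norms. Passing tests
therefore demonstrate that the pipeline is correct and calibrated under
its stated assumptions, not that the developmental findings themselves
are reproduced from real data — the proprietary norms and checklist
database those findings require are out of scope by design.

## Numerical and scale choices

- Degree histograms: 64 bins default; ≥ 8 required. Columns must sum to
  1 within 1e-9 after every stage.
- Interpolation falls back to the nearest sampled column outside the
  convex hull and for degenerate (collinear, < 3 point) spaces.
- Per-point RNG substreams: `default_rng([seed, point_index])`.
- Desk-scale defaults (reps = 200 per point, 1000 permutations) keep a
  full 500-child run to a few seconds per restriction; the `full`
  preset (reps = 1000, 10000 permutations) matches the full-scale
  procedure. Calibration and recovery suites run at desk scale with
  500 children, 200 reps/point, 64 bins, 1000 permutations, 20 seeds.
- All tabular outputs are TSV written with `%.10g` floats; identical
  seeds and inputs reproduce byte-identical analysis outputs.

## Known limitations

- The ANOVA's independence assumption across a word's four proportions
  is a modeling convention, inherited by the contrast intervals.
- Normalized degree for very small parts of speech (e.g. one verb) rests
  on discrete null distributions; sub-bin interpolation keeps it
  monotone but granular.
- Whole samples of real (non-uniform) children drift together away from
  the 50th percentile because children share vocabulary; the calibration
  guarantee applies to the null generative model, and between-sample
  comparisons should rely on the permutation test, not on absolute
  percentile levels.
- The "edges of the space" rule (per-size min/max) can sample most
  points when the observed space is thin; this costs computation, not
  correctness.
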