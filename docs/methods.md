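# Methods

`nwstress` re-implements, as a tested pipeline, the statistical analysis
of a maize transcriptome experiment crossing nitrogen supply with a
drought-and-recovery water series. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## The experimental design being modelled

Thirty conditions: organ (leaf, root, stem) x nitrogen supply (optimal,
limiting) x five ordered water conditions — optimal supply (1), mild
stress (2), severe stress (3), rewatered 2 h (4), rewatered 5 h (5) —
each with three replicate arrays (90 samples; the original experiment
lost two arrays, so the code accepts unbalanced replicate counts of at
least two per condition). The chip carries 46,784 probe-set entities.
Because the five water conditions are ordered (mild sits between optimal
and severe; the rewatering points follow severe stress), a per-entity
expression vector over them is treated as a longitudinal profile rather
than five exchangeable measurements.

## Preprocessing

The pipeline starts from a summarized entity x sample intensity matrix;
probe-level summarization (e.g. RMA) is upstream and out of scope, since
it is an established external algorithm and no raw data accompany the
study. Steps, in order:

1. **Detection filter** (raw scale): keep an entity iff its raw signal
   exceeds 20 intensity units (strictly greater; switchable) in *every*
   replicate of at least one condition.
2. **log2 transform** with a floor of 1.0 intensity unit.
3. **Baseline transformation**: subtract each entity's median log2
   value across all arrays (per-entity centring; `baseline="none"`
   disables it). Within-entity contrasts — fold changes, t statistics,
   ANOVA terms — are invariant to this centring, so the dialect choice
   only affects profile plots and cluster mean locations.
4. **Condition profiles**: the replicate **median** per water condition
   (medians resist a single outlying array better than means; an even
   replicate count uses the midpoint of the two central values),
   yielding one ordered 5-vector per entity per organ x nitrogen
   stratum. Profiles are computed after baselining.

## Differential expression

Per organ, three comparisons: limiting vs optimal nitrogen at optimal
water, and mild / severe water stress vs optimal water at optimal
nitrogen. The screening order is **filter-then-test**: the |mean log2
difference| >= log2(2) fold-change filter defines the family, and the
Benjamini–Hochberg step-up correction (FDR 0.05) is applied to unpaired
equal-variance t-tests within that family only. Fold changes are means
of log2 signals, not ratios of linear means. A zero pooled variance with
equal means returns p = 1 by convention; with unequal means it is an
error (only noise-free synthetic input can produce it). Per-organ Venn
partitions of significant sets use exhaustive membership tallies.

## Interaction screening (2x2 subdesign)

Only the four cells {optimal, limiting N} x {optimal water, severe
drought} enter. Entities are prescreened on the maximum of the four
pairwise cell fold changes (nitrogen at fixed water, water at fixed
nitrogen) at FC >= 2. Retained entities get a per-entity **two-way ANOVA
with type-III sums of squares** under sum-to-zero effect coding; in the
2x2 layout each term has one degree of freedom, so each type-III SS is
the residual-SS increase from dropping that term's column from the full
design. This reduces to ordinary sequential ANOVA on balanced data and
handles dropped arrays otherwise. BH correction runs separately per term
family (N, W, NxW) within an organ.

Classification: nitrogen-/water-/interaction-responsive means the
corresponding BH-adjusted ANOVA p <= 0.05. **Exclusively
interaction-responsive** additionally requires that neither
single-factor t-test within the subdesign (all optimal-N vs all
limiting-N samples; all optimal-water vs all severe-water samples) is
significant. We read the t-tests as these two marginal tests rather
than the four cell-pair tests: any 2x2 interaction pattern necessarily
shows up in some cell-pair contrast, so a cell-pair reading could never
label a pure cross-over entity "exclusive", whereas the marginal tests
are exactly the quantities a pure interaction leaves silent. The
original report of this analysis contains a small internal
inconsistency in the leaf interaction count (1904 vs 1905 between text
and table); nothing here depends on it.

## Longitudinal model-based clustering

The core method. Profiles x_i (5-vectors of log2 expression) are
modelled as a G-component Gaussian mixture whose component precisions
use the **modified Cholesky decomposition**

    Sigma_g^{-1} = T_g' D_g^{-1} T_g,

with T_g unit lower-triangular (generalized autoregressive coefficients
regressing each condition on its predecessors in the water ordering) and
D_g a positive diagonal of innovation variances. Densities are evaluated
without matrix inversion: the quadratic form is ||D^{-1/2} T (x-mu)||^2
and log|Sigma| = sum log D_kk. Fitting is by EM:

- E-step in log space with log-sum-exp normalization; responsibilities
  sum to one exactly.
- M-step: weighted means and scatters, then modified-Cholesky
  factorization; innovation variances floored at 1e-6.
- Convergence by Aitken acceleration on the log-likelihood sequence,
  relative tolerance 1e-8, at most 1000 iterations. The observed-data
  log-likelihood is nondecreasing every iteration (asserted in tests at
  1e-9 relative).
- 10 restarts, each initialized from a seeded k-means-style hard
  partition softened by 10% uniform mass, followed by one M-step. A
  restart whose smallest component weight drops below 1/n is discarded
  as collapsed; the best surviving log-likelihood wins.

The number of components is chosen by **BIC = 2 loglik − k log n**
(larger is better; stated because sign conventions differ across
software) over G = 1..8; the unconstrained model has k = (G−1) + 5G +
15G free parameters. The default covariance family is unconstrained per
component; tied and diagonal variants exist behind a flag but are not
default, since no constraint is prescribed by the source analysis.
Entities enter clustering only if |W2−W1| or |W3−W1| clears a
fold-change prescreen: 3-fold under optimal nitrogen, a relaxed 2-fold
under limiting nitrogen. The mixture is symmetric — mirrored
trajectories share a component — so an a-posteriori up/down split is
applied for display: up iff the profile at the split pair's first
condition exceeds the second (pair (2,1) for optimal-N runs, (3,2) for
limiting-N runs; ties go down).

## Trend comparison across nitrogen regimes

Entities passing **both** prescreens contribute two observations each
(their optimal-N and limiting-N profiles). Within each optimal-N cluster
group, a two-component mixture is fitted to the stacked observations; an
entity whose two observations receive different MAP components is
flagged as following a different trend. A `--global` mode fits one model
over all qualifying entities instead — the source analysis is ambiguous
between the two readings; per-cluster is the default because the
grouping language ("entities that belonged to a particular group")
suggests it. Flags come from MAP labels; an optional confidence gate
requires both max responsibilities >= 0.7. Strata with fewer than two
entities are passed through unflagged with a warning. Flagging is
invariant to component relabelling, and cloned profiles can never be
flagged (identical observations cannot straddle a MAP boundary).

## Synthetic data generator

The generator emulates the factorial design so that every stage is
testable against known truth. On the log2 scale,

    value = baseline + cluster shape (nitrogen-specific for trend-change
            entities) + nitrogen main effect + interaction term
            + N(0, sigma) replicate noise,

with raw-scale export 2^value clamped at a floor (default 1.0) so the
detection filter has something to reject when the baseline is set low.
Default conditions: 2000 entities, 3 organs x 2 N x 5 W x 3 replicates
(90 samples), 4 trajectory shapes of amplitude 3 log2 units, replicate
noise sigma = 0.25 log2 units (a typical between-replicate SD for
log-scale microarray intensities), 5% interaction entities with effect
1.5 log2 units, 10% trend-change entities, baseline 8 log2 units. The
shape library is flat, monotone-down, monotone-up,
stress-peak-with-recovery and stress-trough-with-recovery, scaled to the
amplitude with pairwise L2 separation >= amplitude/2; counts beyond five
come from seeded smooth quadratic perturbations. Trend-change entities
*swap* shape between nitrogen regimes (never merely rescale), making
their truth unambiguous. Interaction and trend-change sets are disjoint
so the planted interaction contrast is exact. Two planting styles:

- `cell` (default): a bump on the (limiting N, severe water) cell only.
- `crossover`: ±effect/4 on the optimal/severe-water cells with opposite
  signs per nitrogen level — zero marginal means within the 2x2,
  i.e. a pure interaction invisible to the single-factor t-tests.

In both styles the 2x2 cell-mean contrast equals `interaction_effect`
exactly at sigma = 0. One RNG stream is seeded once with a fixed draw
order, so equal seeds give bit-identical matrices. The planted signal is
shared across organs (organ contributes no planted effect), and the
noise model is i.i.d. Gaussian on the log2 scale: the generator does not
emulate probe-level effects, intensity-dependent variance, array batch
effects, or correlated replicate structure, so passing tests demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those real-data artefacts.

## Validation problem sizes

The suite validates the pipeline at sizes chosen to make the planted
truth decisively recoverable while keeping each run a desk-scale
computation: model selection and partition recovery on 1200 profiles
with 4 shapes over 20 simulation seeds; mean recovery on 1000 profiles
over 10 seeds; trend detection on 300-entity designs over 20 seeds; DE
sensitivity/FDR on 2000-entity designs (a ~5% responsive cluster with a
4-fold response against flat nulls); null calibration of the t and F
tests on 100k draws each; and one full end-to-end run at the default
2000 x 90 design. The original study's gene counts are not reproducible
because its raw data were never deposited; the worked-example
percentages recomputed from its printed counts are exact arithmetic and
are checked as such.

## Known limitations

- Only 2-level nitrogen and the fixed 5-condition water series are
  supported; no three-way organ model (organs are analysed separately by
  design).
- No moderated/shrinkage t statistics, no missing-timepoint imputation,
  no t- or skew-mixtures.
- The EM can in principle find a degenerate high-likelihood solution on
  tiny strata (the two-component trend fit with very few entities);
  variance floors and collapse-triggered restarts guard this, and
  too-small strata are skipped rather than fitted.
- Whether the original fold-change screens used replicate means or
  medians, and whether medians were taken before or after baselining,
  is unstated there; this implementation fixes means for DE screens,
  medians for profiles, and baseline-then-median order.
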