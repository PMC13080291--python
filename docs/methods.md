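# Methods

This note documents the statistical procedure `personakit` implements, the
conventions chosen where the procedure is genuinely underdetermined, what
the synthetic-data generator does and does not emulate, and the problem
sizes used by the test suite.

## Survey model

A survey is a table of respondents by variables. Each variable is declared
in a schema with a kind (categorical or numeric), a category vocabulary,
an analysis role — demographic, technological, or outcome — and a
clustering weight. The default weighting is 5:1: demographic variables get
weight 1, technology/opinion variables weight 5, so that clustering
differentiates respondents chiefly on technology adoption rather than
demographics. Alternative emphases (e.g. 3:1 or 10:1) are a one-call
schema rewrite (`SurveySchema.reweighted`) intended for sensitivity
sweeps, not a default.

Two derived variables are produced by explicit recode rules rather than
taken from raw answers:

- **Technological readiness** (Higher/Lower) combines self-rated device
  confidence with agreement that help is needed for new device tasks.
  Convention: *Higher* iff confidence is in the top half of its scale
  **and** the needs-help response is in the bottom half of its scale.
  The exact wording and length of the source scales vary between survey
  instruments, so both thresholds are configurable in the rule builder;
  the top-half/bottom-half default is monotone in both items and
  reproduces a binary split.
- **Digital vaccine-record usage** (Yes/Willing/Not willing): *Yes* if the
  usage question is affirmative; otherwise willingness at or above the
  scale midpoint maps to *Willing* and below to *Not willing*.
- **Race/ethnicity** is collapsed to five levels: anyone indicating
  Hispanic ethnicity is *Hispanic*; otherwise a single selection of White,
  Black, or Asian keeps that label; every other pattern (multiple races or
  another label) is *Other*. Both sources missing yields missing.

Missing answers use a single sentinel (NaN/None). Respondents missing any
clustering variable are excluded from the fit (counts logged and reported
on the model) but retained for segmentation and validation tabulations.
"Prefer not to respond" for sex is treated as missing for clustering and
segmentation, and nonbinary/transgender respondents are held out of the
main clustering entirely; they are represented by the supplemental
cluster (below) instead of being absorbed noisily into majority clusters.

## Distance

The weighted Gower dissimilarity sums per-variable contributions
δ_v ∈ [0, 1] (categorical: 0/1 mismatch; numeric: |x−y|/range) with the
schema weights in **both** numerator and denominator, keeping every
distance in [0, 1] and making it invariant to rescaling all weights.
Numeric ranges are frozen when the `DistanceSpec` is built from a dataset;
a constant variable has range 0 and contributes δ = 0 (it carries no
information, and this avoids a 0/0).

Missing policy: under the default pairwise deletion, a variable missing in
either record leaves both sums; a pair with no jointly observed variable
has undefined distance (an error for a single pair, a flagged NaN entry
plus warning in a matrix). The alternative `penalize` policy counts any
missing comparison as a full mismatch. The source procedure does not state
its missing-data handling; pairwise deletion is this package's documented
convention.

## Clustering

K-prototypes is run directly under the weighted Gower distance:

- assignment to the nearest prototype, ties to the lowest cluster index;
- prototype update by per-variable mode (ties broken by schema category
  order) and numeric mean;
- initialisation by sampling K distinct records (seeded RNG); default 10
  restarts, 100 iterations; the best-objective restart is returned;
- empty clusters are repaired by reseeding the empty prototype with the
  record farthest from its current prototype;
- returned clusters are relabelled 1..K by descending size so outputs are
  comparable across seeds;
- the objective (total distance to assigned prototypes) is recomputed from
  scratch on the returned model, and the per-iteration trajectory is kept
  so the non-increase invariant can be asserted.

Everything is deterministic given (seed, n_restarts).

## Choosing K: cross-validated silhouette

The in-sample silhouette width of point i is s(i) = (b−a)/max(a, b), with
a the mean distance to co-members (excluding self) and b the smallest mean
distance to another cluster's members; points in singleton clusters score
0 by convention.

The cross-validated score shuffles respondents (seeded) into near-equal
folds; for each fold the model is fitted on the complement, held-out
respondents are assigned to their nearest prototype, and their widths are
computed against the *training* members' clusters; per-point widths are
pooled across folds. This scores each K on data not used to build the
clusters. K* is the argmax of the pooled mean over the candidate range,
ties to the smallest K. Whether b should use distances to members or to
prototypes is underdetermined; member-based is the default, a
prototype-based variant sits behind `reference="prototypes"`. The default
fold count is 50, configurable.

## Segmentation

Per cluster, the three-way table over age group × sex × race/ethnicity
(axes configurable) covers the full category product; respondents missing
an axis value are excluded and tracked. With N counted respondents,
cluster size n_c, full-sample cell count s and in-cluster count o:

- expected count e = n_c · s / N,
- O/E percentage = round(100 · o / e), rounding half away from zero
  (this convention reproduces all printed reference values), 0 when o = 0.

Flagging: one-sided exact binomial tail P(X ≥ o), X ~ Bin(n_c, s/N). A
cell is flagged if p < α and o ≥ min_count, keeping at most
max_per_cluster lowest-p cells (ties: smaller p, then larger o, then cell
position in axis order — making the result invariant to row order).
Defaults α = 0.05, min_count = 5, max_per_cluster = 4. The published
reference table marks cells without stating its criterion and leaves some
high-O/E tiny-count cells unmarked; this (p, min_count) pair separates the
marked cells from the unmarked small-count cells and is a documented
convention, not a recovered rule. No multiple-testing correction is
applied by default, mirroring the source analysis; the policy object makes
one easy to add upstream.

Flagged cells become segments (members are the cluster respondents in the
cell). A cluster with no flagged cell yields a single whole-cluster
segment whose descriptive cell is the modal joint cell; its member set is
the entire cluster — for such segments the "members match the cell" rule
is deliberately relaxed, because the persona should summarise the whole
cluster, not only its modal cell.

## Personas

One persona per segment: axis demographics from the cell; the remaining
profile characteristics (region, language at home, parental status,
education) and all outcome variables by segment mode, ties broken by
schema category order. The rule for non-axis characteristics is chosen for
consistency with the stated modal-outcome rule. The supplemental cluster
(predicate-defined, e.g. sex ∈ {Nonbinary, Transgender}) becomes one
standalone persona from its aggregate modal summary.

Manual judgment enters only via the overrides configuration (YAML list of
value substitutions and removals); every override stores the automatic
value, the final value, and a nonempty reason, and removals keep the
persona with status `removed`, so active personas = assembled − removals
is auditable.

Validation: the exact-match group agrees with the persona on all 7 profile
characteristics; when it is smaller than `small_group_threshold`
(default 10 — small enough to respect exact matches, large enough to avoid
degenerate tabulations), the relaxed group (≥ 6 of 7) is tabulated
instead. Four outcomes are tabulated (technological readiness, pandemic
policy opinion, health-portal use, activity-tracking use) and a
discrepancy is flagged where the persona's value differs from the matched
group's modal value. Whether to change or retain a discrepant value is a
human decision; the package only reports and records resolutions applied
through overrides.

## Synthetic data

The generator emulates the statistical shape this pipeline assumes:

- 15 categorical variables (7 demographic, 8 technology/opinion) with the
  category vocabularies of the reference survey;
- K planted clusters with sizes (272, 223, 302, 57, 249) by default, plus
  an 8-person nonbinary/transgender subgroup (5/3), total N = 1111;
- per-cluster, per-variable prototypes; each answer copies the prototype
  with probability `adherence` (default 0.9) and is otherwise uniform over
  the categories — an independent mixture under which K-prototypes
  recovery is well defined;
- prototypes are redrawn until every pair disagrees on at least half the
  variables, so a "planted cluster" is genuinely separated;
- demographic cells can be planted as overrepresented inside one cluster
  by a multiplicative boost of the cell probability (a configuration error
  if the boosted probability reaches 1);
- uniform missingness at a configurable rate (default 0: the reference
  analysis clustered complete records; missing-data behaviour is tested
  explicitly where it matters).

What it does **not** emulate: correlation between variables beyond cluster
membership, realistic marginal frequencies of any real population, ordinal
structure in education/age, or free-text answers. Passing recovery tests
therefore shows the machinery is correct under the assumed mixture model —
not that five clusters exist in any particular real survey.

Two printed reference tables ship as checksummed CSV fixtures (the
Cluster 1 three-way table and the six-cluster summary) for exact
reproduction tests. Three printed cells contradict their own printed
counts (one O/E cell duplicating its neighbour's value, one count/percent
pair off by one count, one percentage implying a different denominator);
the fixtures carry the printed values together with erratum flags, and the
tests assert the arithmetically consistent recomputation for those cells.

## Problem sizes and numerical conventions in the test suite

- Oracle equivalence for the distance kernel: exhaustive double-loop
  re-implementation, entrywise tolerance 1e−12, on 10- and 100-record
  datasets (with missingness).
- Global-optimality check for the fit: exhaustive enumeration of all 254
  bipartitions of 8 records, 20 seeded instances, 50 restarts each.
- Planted-K recovery: 20 replicates at the default generator conditions
  (sizes 272/223/302/57/249, adherence 0.9), selection over K = 2..8 with
  10-fold cross-validated silhouette and 3 restarts per fit, then a
  5-restart fit at K = 5 scored by adjusted Rand index against the planted
  labels (≥ 0.9 required in ≥ 18/20). Ten folds and small restart counts
  keep the full sweep to roughly a minute on one CPU while leaving the
  selection problem intact; the fold count is configurable up to the
  50-fold default for production runs.
- Goodness of fit of generated marginals: one 10,000-record cluster,
  chi-square per variable at α = 0.01, fixed seed.
- All stochastic tests fix their seeds; hypothesis-based property tests
  run derandomised.

## Known limitations

- The clustering objective is a local-search optimum; global optimality is
  only guaranteed (and only asserted) on instances small enough to
  enumerate.
- The flagging policy is a calibrated convention (see Segmentation); other
  defensible policies mark slightly different cell sets.
- The silhouette-based choice of K inherits silhouette's known bias toward
  well-separated spherical-ish clusters; for heavily overlapping survey
  populations the score surface can be flat and K* unstable.
- Personas are summaries of modal behaviour; the pipeline deliberately
  leaves every judgment that trades statistical fidelity for diversity or
  relatability to the explicit, audited overrides configuration.
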