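# Methods

`gfsrisk` implements a genetic fuzzy system for stratifying unstable-angina
(UA) patients into three ordinal risk levels (low / medium / high) from
routinely recorded clinical features.  This note documents the model, the
parameter choices that matter, the synthetic cohort generator that stands in
for the original (undeposited) hospital data, and the numerical and design
decisions a maintainer should know about.

## The model

The pipeline has three stages.

**1. Fuzzy partitioning of numerical features.**  For each numerical feature
the observed values are clustered by hierarchical agglomerative clustering
with the average-linkage distance

    d(c1, c2) = (1 / |c1||c2|) Σ_{x∈c1} Σ_{y∈c2} |x − y| ,

starting from singletons and merging the closest pair until the smallest
inter-cluster distance exceeds a threshold ε.  The surviving cluster
centroids `v¹ < … < v^m` become the midpoints of a triangular fuzzy
partition on `[v₀, v_{m+1}] = [min, max]`: a left semi-trapezoid (1 below
`v₀`, falling linearly to `v¹`), one triangle per interior midpoint, and a
right semi-trapezoid.  The memberships `μ_{a,j}` form a partition of unity
on the observed domain, which the suite asserts to 1e−9 on dense grids.

Implementation note: for one-dimensional data the average-linkage distance
between clusters occupying disjoint value ranges reduces to the difference
of centroids, and the globally closest pair is always adjacent in sorted
order.  The implementation therefore merges adjacent sorted blocks in
O(n²) total; a brute-force all-pairs trace serves as test oracle.

*Parameters*: ε defaults to 0.15 × the observed range per feature
(overridable per feature); the set count is capped at 5 (merging continues
past ε if exceeded); midpoints within 1e−9 × range of a bound are dropped
so the set count stays `m + 2`.  Ties in merge distance go to the pair with
the lower left centroid.

**2. GA mining of fuzzy association rules.**  A rule has the form

    IF a₁ is (l₁ OR l₃) AND a₅ is l₄ THEN <risk level>,

encoded as one chromosome: a concatenation of per-feature bitmasks (one bit
per linguistic term or categorical token) in schema order; a segment of all
zeros or all ones marks its feature irrelevant.  Rule quality on a labelled
cohort `D` uses the antecedent part compatibility

    APC(σ, r) = (1/n) Σ_{relevant features} max{μ over selected terms} ,

with categorical memberships 0/1 and missing values contributing 0 while
still counting in `n`; `Supp(σ, r) = APC(σ, r)` when σ's label equals the
rule's class, else 0; `Support(r) = Σ Supp / |D|`;
`Confidence(r) = Σ Supp / Σ APC`; and the mining objective

    Fitness(r) = (Support(r) + Confidence(r)) / 2 .

Averaging over *antecedent* features (not all schema features) is the
reading under which the teaching example's printed support/confidence
values reproduce exactly; the all-features variant remains available as
`apc_denominator="all"` for sensitivity analysis.

The GA is run once per risk class with the consequent fixed (Michigan
style): binary-tournament selection, one-point crossover (rate 1.0),
mutation events that invert one uniformly selected bit (event probability
0.2 per offspring), elitism (2), generational replacement, and a fixed
generation count as the stopping criterion.  Defaults: population 100,
1000 generations.  Three search-design choices deserve explanation:

- *Single-bit mutation events.*  Independent per-bit flipping at rate 0.2
  was tried and rejected: on a ~70-bit cohort chromosome it rewrites ~14
  bits of every child, the search degenerates into random sampling, and the
  miner stalls far below optima that are trivial to verify by enumeration.
  A rate-0.2 chance of flipping one bit makes the GA a well-behaved
  stochastic hill-climber over the rule lattice.
- *Sparse initialisation.*  Each feature's segment starts all-zero
  (irrelevant) with probability 0.75, otherwise Bernoulli(0.5) bits.
  Dense random initialisation makes essentially every feature relevant,
  and single-bit mutation cannot cross the fitness valley between a
  one-bit mask and an empty segment, so short rules would never be
  reached.  With sparse starts, crossover recombines feature subsets and
  the miner reliably finds single- and two-feature optima.
- *An archive, not just the final population.*  Every distinct chromosome
  evaluated anywhere in the run is recorded with its quality measures; the
  returned rules are the best distinct, non-redundant archive entries.
  Selecting from the converged final population alone returns the best
  rule plus its random one-bit mutants, which makes the second- and
  third-ranked rules unstable across seeds.

Rule-base assembly: candidates below a minimum support of 0.02 are
discarded (the standard association-rule floor; without it a rule covering
one or two — typically noise-labelled — cases scores confidence 1.0 and
fitness ≈ 0.5, outranking every genuine rule).  Candidates are ranked by
fitness (ties: higher confidence, fewer antecedent features, bit-string
order), then pruned of redundant rules: a rule is redundant w.r.t. a more
general rule of the same class whose masks contain its own and whose
support agrees within `REDUNDANCY_TOL = 0.01`.  Exact support equality
essentially never occurs on continuous cohorts, so a strict test would
make the pruning step vacuous; one support point is the resolution at
which two rules "have the same support" at these cohort sizes.  The top
2 rules per class are returned (`rules_per_class=2`), matching the size of
the rule bases this kind of system reports; larger values make the
additive scoring (below) favour whichever class accumulates the most
near-duplicate rules, which is dominated by class prevalence rather than
evidence.

**3. Confidence-weighted classification.**  For a case σ each class scores

    v_class = Σ_{rules r of that class} Confidence(r) · β(r, σ) ,
    β(r, σ) = Σ_{antecedent features} max{μ over selected terms} ,

note β is a *sum* (it may exceed 1), unlike the APC average.  The
predicted level is the arg-max of `(v_low, v_medium, v_high)`; ties break
toward the higher risk level (clinically conservative), and an all-zero
score vector falls back to a configured class (default medium-risk) with
an explicit `no_rule_fired` flag.

## Evaluation

One-vs-rest sensitivity `TP/(TP+FN)` and specificity `TN/(TN+FP)` per
class, with `None` reported when a class has no positives (negatives) in
the evaluated set; exact-match agreement against physician labels; and a
rounds-of-stratified-k-fold cross-validation in which each episode
re-derives the fuzzy partitions and re-mines the rule base from its
training split only (no leakage).  Fold assignment deals each class's
shuffled indices round-robin, so classes smaller than the fold count land
in a subset of folds instead of aborting the protocol — with the study's
16/33/5 class mix, 10-fold splitting must tolerate a 5-case class.
Resubstitution (train and test on the full cohort) is implemented and
labelled separately; reports never mix the two modes.

## The synthetic cohort generator

The original 54-case hospital cohort is not public, so the package ships a
generator with the same feature structure: 9 numerical features (age,
systolic/diastolic pressure, creatinine, AST, LDH, CK, CK-MB, troponin)
drawn from truncated normal distributions over conventional clinical
spans, and 17 categorical features drawn from weighted tokens.  Feature
values are drawn independently; all structure enters through the labels.

Labels come from a *planted* fuzzy rule set scored by the package's own
classifier, so every pipeline stage has a ground-truth oracle.  The
planted world mirrors how UA risk presents clinically:

- **high** — the ischaemic-ECG stratum: `st_change = yes` (confidence
  1.0), reinforced by an ST-gated rule on strongly elevated CK-MB and LDH
  (0.8);
- **low** — a quiet history: no recent heart events, no coronary history
  and a quiet ECG (0.4), or younger age (0.35);
- **medium** — the broad remainder, expressed through deliberately weak
  rules: a base-rate rule on a near-universal token (`bleeding = no`,
  0.45), recent heart events (0.45), advanced age (0.40).

The confidence weights were chosen so that the planted scoring assigns
each case exactly one stratum: an ST change always wins; youth or a quiet
history beats the medium base rules; and partial marker firings cannot
claim high risk on a quiet ECG (the marker booster uses narrow top sets
and is ST-gated precisely to prevent that leak).  Two structural facts,
found the hard way, shaped this design: under additive firing-strength
scoring (i) the majority class must not possess a crisp necessary token,
because that token becomes a ~0.9-confidence rule that outvotes the rare
class on every shared case, and (ii) planted partitions should sit where
clustering of the marginals puts knots, so the terms the planted rules
speak match the terms a fitted partition offers the miner.

Class mix is enforced exactly (largest-remainder quotas, stratified
rejection over at most 10 × n draws) with the study's 16:33:5 imbalance as
default; each label then flips to a uniformly different class with
probability `label_noise` (default 0.05) to emulate physician
disagreement.  Everything is determined by the seed.

What the generator does *not* emulate: correlated features (no copulas —
marker elevation co-occurs with ECG change only through the labels),
missing values, longitudinal structure, or realistic biomarker joint
distributions.  Passing recovery benchmarks therefore demonstrates that
the pipeline can re-discover rule-structured signal at realistic size,
imbalance and label noise — not that it matches any particular hospital
population.

## Recovery benchmark

The headline check: generate 500-case cohorts at 5% label noise, run
5-fold cross-validation with default GA settings (one round per seed,
five seeds), and score held-out folds against the *noise-free* planted
labels.  Noise-free truth is the only coherent target for sensitivity:
with 5% symmetric flips, roughly one in six labelled-high cases is an
ordinary case wearing a high label, capping noisy-label high-risk
sensitivity near 0.8 regardless of model quality.  Measured on seeds 1–5,
cross-validated agreement is ≈ 0.90 and high-risk sensitivity ≥ 0.95;
the suite asserts ≥ 0.85 and ≥ 0.90 per seed.  The problem sizes
(n = 500, 5 folds, 1 round, 5 seeds) are the package's benchmark
configuration; the evaluation module itself defaults to the classical
10 × 10-fold protocol.

## The teaching example

A six-case cohort (ages {74, 81, 74, 71, 76, 67}, three binary features,
physician labels) ships as a fixture together with its six-rule teaching
rule base over the age partition [30, 87] with midpoints {56, 74}.  Under
that partition the quality measures of the teaching rules reproduce
exactly (e.g. the old-nonsmoker medium rule scores support 0.339,
confidence 0.465), and classifying the first case with the teaching base
yields medium-risk with scores (0.33, 1.96, 1.74).  Mining the fixture
from scratch is also exercised, with one caveat documented here: the
teaching rules are *not* the fitness-maximal rules of this toy problem
(exhaustive enumeration of all 2¹⁰ antecedents shows higher-fitness
alternatives), so a correct maximiser returns a different base under which
the first case scores high-risk.  The acceptance suite therefore checks
the worked classification with the teaching base, and checks the miner
against the exhaustively verified optimum separately.

## Numerical choices and degenerate inputs

- Memberships are evaluated by linear interpolation over the knot vector
  `[v₀, midpoints…, v_max]`; boundary sets saturate at 1 outside the
  domain; missing values (NaN) have membership 0 in every set.
- A feature whose observed values are all identical raises a
  degenerate-partition error naming the feature (treat it as categorical).
- Confidence is undefined (rule fires nowhere) → the rule scores fitness
  0 and can never enter a rule base.
- Categorical token matching is case-insensitive after trimming.
- Per-class GA streams are seeded `seed + class rank`; cross-validation
  derives per-episode seeds from `(seed, round, fold)` via a seed
  sequence, all below 2³¹.
- Population-scale evaluation precomputes, per feature, a lookup table
  from every possible segment mask to the per-case max-membership vector,
  making a generation's evaluation a handful of fancy-indexed sums; the
  scalar implementations remain the reference path and the suite asserts
  the two agree to 1e−12.

## Known limitations

- The additive score (sum of confidence-weighted firing strengths) has no
  prevalence correction; rare-class detection depends on the rule base
  containing confident rules anchored on that class's stratum.
- Fitness is length-blind (APC averages over antecedent features) while
  the firing strength rewards longer matched antecedents; maximal-fitness
  rules are therefore often shorter than the rules that classify best.
- Redundancy pruning uses a fixed support tolerance; at cohort sizes far
  from a few hundred cases the 0.01 default may be too loose or too tight.
- The generator's independence assumption understates how informative
  correlated markers would be on real data.
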