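# gfsrisk

A genetic fuzzy system for unstable-angina (UA) risk stratification.

Unstable angina is an acute coronary syndrome whose patients carry widely
varying risk; early stratification into **low / medium / high** risk drives
management.  Classical scores handle the vagueness of clinical variables
poorly ("age 74" is not crisply *old*).  `gfsrisk` implements an
interpretable alternative for clinical-informatics researchers: clinical
features are described by fuzzy linguistic terms, IF–THEN rules over those
terms are mined from a labelled cohort by a genetic algorithm, and the
mined rule base classifies new cases by confidence-weighted voting.

The pipeline, in the field's standard notation:

1. **Fuzzy partitioning** — each numerical feature is discretised by
   average-linkage agglomerative clustering of its values
   (`d(c₁,c₂) = (1/|c₁||c₂|) ΣΣ |x−y|`, merge while the minimum distance
   ≤ ε); cluster centroids become midpoints of a triangular partition
   whose memberships satisfy `Σⱼ μ_{a,j}(x) = 1` on the observed domain.
2. **Rule mining** — rules `r: Cond → Class` with per-feature term
   disjunctions are encoded as bitmask chromosomes and evolved per class
   to maximise `Fitness(r) = (Support(r) + Confidence(r))/2`, where
   `Support = Σ_σ Supp(σ,r)/|D|`, `Confidence = Σ Supp / Σ APC`, and
   `APC(σ,r)` is the mean over antecedent features of the maximal
   selected-term membership.
3. **Classification** — `v_class = Σ_r Confidence(r)·β(r,σ)` with firing
   strength `β` the *sum* of per-feature maxima; the predicted level is
   `argmax(v_low, v_medium, v_high)` (ties break toward higher risk).

Because the study cohort this method was developed on is not publicly
deposited, the package ships a synthetic cohort generator with the same
feature structure (9 numerical + 17 categorical clinical features) whose
labels are produced by a known, planted fuzzy rule set — giving every
stage a ground-truth oracle.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Fit the model on the six-case teaching cohort that ships with the package:

```python
from gfsrisk import GAConfig, UARiskModel, table1_fixture

model = UARiskModel(
    table1_fixture(),
    ga_config=GAConfig(population_size=50, generations=1000,
                       crossover_rate=0.5, mutation_rate=0.2, seed=0),
)
results = model.fit()
print(results.summary())
```

prints

```
Unstable-angina genetic fuzzy risk model
========================================================================
Cases: 6   low-risk: 1  medium-risk: 3  high-risk: 2
Features: 4 (1 numerical, 3 categorical)
GA: pop 50, gens 1000, cx 0.5, mut 0.2, seed 0

Fuzzy partitions
------------------------------------------------------------------------
age: [67, 81] midpoints [71, 74.6667] -> 4 sets (low, low-medium, high-medium, high)

Mined rules
------------------------------------------------------------------------
low-risk: 2 rules
  S=0.167 C=0.500 F=0.333  IF heart_events_recently is (no) THEN Risk is low-risk
  S=0.167 C=0.500 F=0.333  IF sex is (female) THEN Risk is low-risk
medium-risk: 2 rules
  S=0.333 C=0.905 F=0.619  IF age is (low OR high) THEN Risk is medium-risk
  S=0.167 C=1.000 F=0.583  IF age is (low) THEN Risk is medium-risk
high-risk: 2 rules
  S=0.197 C=0.867 F=0.532  IF age is (low-medium) THEN Risk is high-risk
  S=0.265 C=0.593 F=0.429  IF age is (low-medium) AND heart_events_recently is (yes) THEN Risk is high-risk

Training agreement: 5/6 (83.3%)
```

Reading the output: the six observed ages induce four fuzzy age sets;
each mined rule is shown with its support `S` (how much of the cohort it
fuzzily covers with the right label), confidence `C` (class purity of its
coverage) and fitness `F = (S+C)/2`; the fitted base reproduces the
physician's label on 5 of the 6 training cases.  `results.predict(...)` /
`results.predictions_frame(...)` score new cases, and
`model.cross_validate(folds=10, rounds=10, seed=0)` runs the full
leakage-free evaluation protocol.

The same stages are available from a shell:

```bash
gfsrisk simulate --n 500 --noise 0.05 --seed 1 --out cohort.csv
gfsrisk partition --data cohort.csv --schema cohort.schema.json --out parts.json
gfsrisk mine --data cohort.csv --schema cohort.schema.json --seed 1 --out rules.json
gfsrisk predict --rules rules.json --data cohort.csv --schema cohort.schema.json --out preds.csv
gfsrisk evaluate --data cohort.csv --schema cohort.schema.json --folds 5 --rounds 1 --seed 1 --out report.json
```

Every command writes a `*.manifest.json` (settings, seed, version, input
checksums) next to its output so runs can be reproduced exactly.

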