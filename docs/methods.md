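# Methods

## The screening problem and the model

Beta-thalassemia trait produces a characteristic but mild CBC signature:
microcytosis (low MCV), a relatively preserved or elevated red-cell count,
and modestly reduced hemoglobin.  Because carriers are a small minority of
a screening population and the cost of misclassification is asymmetric,
the package classifies with a dominance-based rough set model rather than
a rebalanced discriminative one: the data are never normalized or
resampled, the preference order of the attributes is made explicit, and
every prediction is justified by the rules that fired.

A decision table is Objects × Criteria with a binary ordered decision
(0 = non-carrier ≺ 1 = carrier).  Every criterion carries a mandatory
preference direction: *gain* (larger values point toward the carrier
class) or *cost* (smaller values do).  Object `x` dominates `y` on subset
`P` when `x` is at least as good as `y` on every criterion of `P`
(`>=` on gain, `<=` on cost); ties on all criteria count as mutual
dominance, with exact native comparison and no tolerance, since inputs
are finite-precision laboratory values.

For the upward union Cl≥t and downward union Cl≤t:

- `x ∈ lower(Cl≥t)` iff every object dominating `x` lies in Cl≥t;
  `x ∈ upper(Cl≥t)` iff `x` dominates some member of Cl≥t;
- mirrored with the dominated-cone for downward unions;
- boundary = upper − lower; quality of approximation
  γ_P = |U − ∪ boundaries| / |U|; per-class accuracy α = |lower|/|upper|
  of the class's characteristic union (upward for the top class, downward
  for the bottom), with α undefined (reported as such, not 0) when the
  upper approximation is empty.

The cone labelling deserves a note: the defining equations of the
dominance cones are written inconsistently across sources (the `D⁺`/`D⁻`
superscripts do not always match the accompanying prose).  This package
fixes the semantics operationally — `dominating_set(x) = {y : y dominates
x}`, `dominated_set(x) = {y : x dominates y}` — and uses them exactly as
above; that convention reproduces the packaged worked example, which is
treated as ground truth.

Cone computation is the literal O(n²·m) pairwise comparison, evaluated
with NumPy in 256-row blocks so peak memory stays O(n·block) rather than
O(n²).  Published heuristics exist that avoid redundant comparisons; they
change the constant, not the contract, and are not implemented here.

### Preference directions and the worked example

The worked-example fixture declares **all twelve condition criteria as
gain**.  This was a genuine design decision: one might instead assign
"carrier-indicative" directions from the index screening ranges (Mentzer,
Green & King and RDWI cost; Ricerca, MCH/MCV and BTD gain).  Under those
directions, however, patient x2 dominates patient x5 on all twelve
criteria while carrying the opposite label, so the table is *not*
dominance-consistent (γ = 0.8) and the published exact analysis of this
table cannot be reproduced.  Under the all-gain convention the table is
consistent (γ = 1) with lower(Cl≥1) = upper(Cl≥1) = {x5, x9} — evidently
the convention under which the example was originally computed.  The
package therefore makes directions mandatory, ships the fixture with
all-gain directions, and uses carrier-indicative directions for the
synthetic CBC profiles where they are semantically meaningful.

The fixture also carries two columns exactly as printed even though their
names are misleading; this was verified by recomputation over all ten
rows: the column labelled `gk` numerically equals (RBC/HGB) × 100 — the
BTD index, to 5 decimals — not the Green & King formula, and `greenking`
equals MCV² × gk.  `compute_gki` implements the actual Green & King
formula MCV²·RDW/(Hb·100); the fixture columns are not silently
redefined.

## Reducts

A reduct is a γ-preserving, removal-minimal criteria subset.  Because γ
is monotone under criterion addition, minimality only needs single-removal
checks.  Two strategies:

- `exhaustive` — size-ordered subset enumeration, skipping supersets of
  already-found reducts; exact, refused above 15 criteria;
- `greedy` — backward elimination dropping the criterion whose removal
  costs the least γ (ties broken lexicographically by name, so the result
  is deterministic without any randomness), iterated to a fixpoint so the
  returned set is genuinely minimal.

## Rule induction (DOMLEM family)

Rules are induced per class union from its (variable-consistency)
positive region, most-preferred upward union first.  The VC positive
region of an upward union admits member `x` when at least a fraction
`l` of its dominating cone lies in the union; at `l = 1` it is exactly
the lower approximation, and `l` is exposed as configuration (default
1.0) because published uses of the variable-consistency variant rarely
state the threshold employed.

Sequential covering: while uncovered positive-region objects `G` remain,
grow one rule by repeatedly adding the elementary condition maximizing
the covering ratio |cover ∩ G| / |cover|, with ties broken by larger
|cover ∩ G|, then criterion name, then the less extreme threshold.
Candidate thresholds are values observed among still-uncovered objects
inside the current cover, so thresholds always come from the data;
relations follow the union and the direction (`>=` on gain criteria for
`Class >=` rules, etc.), so every rule is monotone by construction.
Growth stops when the rule's cover lies inside the positive region; each
condition that can be dropped without breaking that inclusion is then
pruned, so every emitted rule is condition-minimal.  Numerically, the
candidate scoring is vectorized per criterion by sorting the covered
values once and counting with binary search, which keeps induction at
n ≈ 2,000 under a second per class union.

Two degenerate situations are handled explicitly: a rule must contain at
least one condition even when the whole table already lies inside the
positive region (single-class tables), and at `l < 1` the required
inclusion can be unattainable (e.g. value-identical objects straddling
the region boundary), in which case the grower stops at the best
achievable cover and the rule keeps its measured consistency.  At
`l = 1` the inclusion is always attainable and induced rule sets
re-classify consistent training tables with zero error.

Classification consults only `Class >= 1` rules: a record is a carrier
iff one fires, class 0 being the default conclusion — the natural policy
for a two-class screening problem where published rule lists contain only
carrier-side rules.  The continuous score for ROC/PR analysis is the
maximum training confidence among fired carrier rules (0 when none
fires); it is the simplest score monotone in the set of firing rules.
Strength-weighted alternatives would slot into the same interface.

Rules serialize one per line as `(attr>=v)&(attr<=v)=>(Class>=t)` and
parse back to identical rules (training metadata — support, consistency
— is intentionally outside rule equality).  Some published rule listings
print thresholds as ×10⁸–10⁹ fixed-point integers; this package writes
plain decimals and makes no attempt to guess an undocumented scale
factor.

## Synthetic CBC generator

The generator emulates the screening-lab population the analysis assumes:

- carrier prevalence 0.17 (Bernoulli labels);
- truncated-normal red-cell profiles per class — carriers MCV 63 ± 5 fL
  on [50, 78], RBC 5.5 ± 0.6 on [4.2, 7.2] ×10⁶/µL, HGB 10.5 ± 1.2 on
  [7.5, 13.5] g/dL; non-carriers MCV 88 ± 6 on [76, 102], RBC 4.7 ± 0.5
  on [3.6, 6.0], HGB 13.5 ± 1.3 on [10.5, 17.0];
- HCT, MCH and MCHC derived from the simulated RBC/HGB/MCV so each
  record is internally coherent; the white-cell differential and platelet
  parameters are class-independent reference-range draws (means and
  bounds chosen from standard adult reference intervals);
- all draws flow through one PCG64 generator seeded from the config, so
  a fixed seed reproduces the table bit-for-bit.

These defaults separate the classes well but not perfectly: the class
bounds overlap at MCV 76–78 fL and the index panel mislabels a small
fraction of records, so γ on a simulated cohort is high but below 1
(≈ 0.99 at n = 2,000) and boundaries/VC thresholds remain exercised.
Two controlled corruption mechanisms exist for harder tests:
`overlap_noise` draws a fraction of records from the other class's
profile while keeping the label, and `inject_inconsistency` clones
attribute values across the class line (each clone/source pair then
mutually dominates with opposite labels, forcing γ < 1 by a computable
amount).  `planted_rules` relabels records from a known rule set, giving
ground truth for rule-recovery tests.

What the generator does **not** emulate: real analyzer measurement error
structure, iron-deficiency and other microcytic confounders, demographic
covariates, or the moments of any particular laboratory's population.
Passing tests on this data demonstrate the correctness of the machinery
and the qualitative behavior of the method under imbalance, not clinical
performance; accuracies near 99% on the synthetic cohort reflect its
relative cleanliness, and real-data accuracy will be lower.

## Ingest and cleaning

Raw exports are cleaned by an ordered first-match rule sequence (missing
RBC/HGB, missing remark, lab-flagged inconclusive, ambiguity-lexicon
match or unknown wording, then exact-duplicate removal and dropping of
age/gender), with every drop attributed to exactly one rule so the report
reconciles with row arithmetic.  The remark lexicon is configurable;
unknown remark wording is conservatively dropped as ambiguous rather than
guessed.  Missingness is checked on the HGB column; hemoglobin-variant
electrophoresis values are not modeled separately.  Column names are
normalized case/punctuation-insensitively with a small synonym map,
because laboratory export headers vary.

## Evaluation harness

Train/test splits are random 80/20 by default (stratification available
but off by default), deterministic per seed.  Metrics are pure functions
of the confusion matrix (per-class precision, recall, F1, specificity,
FPR, FNR, support; accuracy; macro and support-weighted averages), ROC
AUC is the trapezoidal area over unique score thresholds, and the model
comparison uses the classical two-sided paired t-test on seed-aligned
accuracy vectors, with zero-variance differences reported as degenerate
(t = 0, p = 1 on an exact tie) rather than raised.  Because the rule
classifier's score construction is a package choice, its AUC values are
comparable within this package but not directly against AUCs computed
under other score constructions.

## Problem sizes and defaults used in the shipped analyses

The acceptance script analyses a 10,000-record cohort for the
prevalence/Mentzer structure checks, a 2,000-record cohort (80/20 split)
for rule induction and test metrics, and 8 seed-aligned splits for the
paired t-test; rule induction there uses the five-criterion panel
{HGB, MCHC, RDWCV, MI, BTD} with carrier-indicative directions and
`l = 1`.  These sizes give stable estimates (binomial SE of the
prevalence ≈ 0.4 pp at n = 10,000) while keeping a full run in seconds.

## Known limitations

- Strict `l = 1` induction is brittle to label noise: a single
  mislabeled record removes its whole dominance cone from the lower
  approximation, and carrier recall degrades quickly (this is the
  motivation for the VC variant).  Under heavy overlap noise the
  cover-inside-region contract fragments the rule set; rule-consistency
  based stopping would trade purity for compactness and is not
  implemented.
- Only binary, totally ordered decision classes are supported end to
  end; no missing values, interval attributes, or cost-sensitive
  thresholds.
- Exhaustive reduct search is exponential and capped at 15 criteria;
  the greedy search returns a single reduct with no optimality guarantee
  on its size.
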