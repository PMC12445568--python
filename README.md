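# thalscreen

Interpretable screening for **beta-thalassemia carriers** from complete
blood count (CBC) data, built on the **dominance-based rough set approach
(DRSA)** with **DOMLEM-style decision-rule induction**.

Beta-thalassemia trait is usually asymptomatic; carriers show only mild
microcytic red-cell changes (low MCV, relatively elevated RBC, mildly
reduced hemoglobin).  Screening populations are strongly imbalanced —
carriers are a small minority — and clinicians need predictions they can
audit.  `thalscreen` targets exactly this setting: it classifies CBC
records with human-readable `if`-rules induced from dominance-consistent
regions of the data, without rebalancing or normalizing the classes.  It
is aimed at biostatisticians and ML researchers working on ordinal /
monotone clinical classification, and at anyone who needs a reproducible
rough-set rule pipeline with a synthetic data generator for benchmarking.

## The model

A decision table holds objects (patients) × criteria (CBC parameters and
derived indices), each criterion with an explicit preference direction
(gain/cost), and ordered decision classes (0 = non-carrier ≺ 1 = carrier).
Object *x* **dominates** *y* on criteria subset *P* when *x* is at least
as good as *y* on every criterion of *P*.  With the upward union
Cl≥t = {objects of class ≥ t}, the approximations are

- lower: P̲(Cl≥t) = {x : D⁺(x) ⊆ Cl≥t}, where D⁺(x) is the set of objects
  dominating x,
- upper: P̄(Cl≥t) = {x : D⁻(x) ∩ Cl≥t ≠ ∅}, where D⁻(x) is the set x
  dominates,

(mirrored for downward unions), the boundary is Bn = P̄ − P̲, and the
**quality of approximation** γ_P is the fraction of objects outside every
boundary.  A **reduct** is a minimal criteria subset preserving γ.
Rules are induced from the (variable-consistency) lower approximations by
sequential covering: conjunctions of `(criterion ≥ v)` / `(criterion ≤ v)`
conditions concluding `Class >= t` or `Class <= t`, grown greedily by the
covering ratio |cover ∩ G| / |cover| and pruned to condition-minimality.
A record is predicted a carrier iff at least one `Class >= 1` rule fires.

The hematological indices implemented (with their published
carrier-suggestive ranges): Mentzer MCV/RBC (≤ 13), Green & King
MCV²·RDW/(Hb·100) (≤ 65), MCH/MCV (> 0.35), RDWI MCV·RDW/RBC (≤ 220),
Ricerca RDW/RBC (> 4.4), and the red-cell/hemoglobin ratio index
**BTD = (RBC/HGB) × 100**.

## Worked example

The package ships a ten-patient decision table with twelve condition
criteria whose full dominance analysis is exact:

```python
from thalscreen import (fixture_worked_example, approximation_report,
                        induce_rules, serialize_rules)

table = fixture_worked_example()
report = approximation_report(table)
print(f"quality of approximation (gamma): {report.gamma}")
up1 = report.union("upward", 1)
print(f"lower(Cl>=1): {up1.lower}   upper(Cl>=1): {up1.upper}")
print(serialize_rules(induce_rules(table)))
```

prints

```
quality of approximation (gamma): 1.0
lower(Cl>=1): ['x5', 'x9']   upper(Cl>=1): ['x5', 'x9']
(rbc>=5.46)=>(Class>=1)
(rdwi>=342.9825)&(gk>=46.21622)=>(Class>=1)
(gk<=45.49451)=>(Class<=0)
(hct<=23)=>(Class<=0)
```

γ = 1 means the table is dominance-consistent: the criteria fully
determine the classification.  The two carriers (x5, x9) are certainly
carriers (lower = upper = the carrier class), both class accuracies
(|lower|/|upper|) are 1.0, and the induced rules re-classify all ten
patients exactly.

The sklearn-style estimator wraps the same train path:

```python
from thalscreen import DominanceRuleClassifier, SimulationConfig, generate_dataset
from thalscreen.indices import add_index_columns

frame = generate_dataset(SimulationConfig(n=2000, seed=1))
y = frame.pop("decision")
frame = add_index_columns(frame)
panel = {"hgb": "cost", "mchc": "cost", "rdwcv": "gain", "mi": "cost", "btd": "gain"}
clf = DominanceRuleClassifier(directions=panel, criteria=list(panel)).fit(frame, y)
print(clf.gamma_, len(clf.ruleset_.rules))   # e.g. 0.9965 19
```

A CLI mirrors the pipeline stage by stage
(`thalscreen simulate | indices | approx | reduce | induce | classify |
evaluate | run`).

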