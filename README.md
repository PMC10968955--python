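# exponet

Exposome scoring and mixed-graphical-model network analysis of
psychopathology domains.

## The problem

Environmental exposures — winter season of birth, obstetric complications,
advanced paternal age, non-right-handedness, childhood trauma (emotional
neglect, emotional abuse, bullying, sexual abuse), problematic cannabis use
and urban upbringing — raise the risk of psychopathology transdiagnostically.
A common way to study their cumulative burden is the **exposome score (ES)**:
each exposure is binarized and weighted by the natural-log odds ratio from
meta-analyses of its association with psychotic disorders,

```
ES = ( Σ_k  x_k · ln OR_k ) / K,     x_k ∈ {0, 1},  K = 10 components,
```

and the score is then related to symptom dimensions (depressive, anxiety,
manic, ADHD, obsessive–compulsive symptoms and psychotic-like experiences,
measured as questionnaire sum-scores) through a **pairwise mixed graphical
model (MGM)**: a Markov random field over continuous nodes (symptom scores,
ES, age) and binary nodes (education, gender, employment) estimated by
nodewise L1-penalized regression with EBIC penalty selection, AND-rule edge
aggregation, strength centrality, per-node predictability, and bootstrap
stability analysis (non-parametric and case-drop, with the
correlation-stability coefficient, CS-C).

`exponet` implements this pipeline end to end for epidemiologists and
psychometric-network researchers.  Because survey cohorts of this kind are
rarely public, the package includes a first-class synthetic-cohort
generator calibrated to realistic marginals, and an exact Gibbs sampler
for MGMs with known structure, so every stage can be validated against
ground truth.

## Worked example

```python
import exponet as e

# 1. a synthetic cohort of 1100 respondents with realistic marginals
cohort = e.generate_cohort(e.CohortSpec(n_respondents=1100, seed=7))

# 2. exposome scores (fixed denominator of 10 components)
scored = e.score_cohort(cohort)
print(round(scored["es"].mean(), 2))          # 0.24

# 3. the 11-node network: ES + 6 symptom scales + age + 3 binary covariates
data = e.prepare_network_data(cohort.assign(es=scored["es"]))
net = e.estimate_network(data)
report = e.network_summary(net)
print(report.possible_edges)                  # 55

# 4. the packaged published worked-example network
ref = e.load_reference_network()
print(e.network_summary(ref).edge_count)      # 22
print(round(e.strength(ref, "D"), 3))         # 0.904  (depressive symptoms)
print(round(e.strength(ref, "ES"), 3))        # 0.481  (exposome score)
```

The mean ES of 0.24 is what the weighted formula produces under the default
exposure prevalences (e.g. 52.4% emotional neglect, 6.5% problematic
cannabis use); the reference network has 22 non-zero edges out of 55
possible (40.0%), with depressive symptoms the most central node.

A command-line interface wraps the same pipeline:

```bash
exponet estimate --seed 7 --out run1       # simulate → score → estimate → report
exponet bootstrap -B 200 --seed 7 --out run1   # …plus bootstrap stability
exponet report                             # centrality report of the packaged network
```

Bootstrap iterations default to the conventional 1000 (`-B` lowers them for
desk-scale runs).

Each run writes a manifest (config hash, seed, library versions); re-running
with the same config and seed reproduces byte-identical outputs.

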