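# readmit-bn

Discrete Bayesian-network analysis of **unplanned hospital readmissions
(HRAs)** in gastrointestinal-cancer patients with breakthrough cancer pain
(BTcP) and complex care needs.

Unplanned readmissions degrade quality of life and drive cancer-care costs.
This package implements, as a tested and reusable pipeline, a
knowledge-constrained probabilistic analysis of which clinical factors —
cancer site, BMI class, bone metastasis, serum albumin, nutritional
support, BTcP predictability, radiotherapy — bear directly on the
readmission count class (≤10 / 11–22 / >22 accesses). It is aimed at
biostatisticians and clinical data scientists who want the whole chain —
clinical discretization, chi-square association screening, BIC-scored
structure learning under whitelist/blacklist constraints, and exact
posterior inference — runnable end to end, with or without patient data.

## The model

A multinomial Bayesian network on eight categorical variables: a DAG G
encodes P(X₁,…,X₈) = Π P(Xᵢ | pa(Xᵢ)), one conditional probability table
per node. Structures are selected by the Bayesian Information Criterion,

    BIC = k·ln n − 2·ln L(θ̂)    (minimized; equivalently maximize ln L − (ln n/2)·k)

with k the number of free multinomial parameters and n the number of
complete cases; the per-parameter penalization coefficient is ln n/2
(≈ 2.28 at n = 96). Search is greedy hill climbing over single-arc moves,
with clinically forced arcs (e.g. albumin → nutritional support) and
forbidden arcs (e.g. nothing causes the tumor type) as hard constraints,
validated against an exhaustive-enumeration oracle. Posterior queries are
answered exactly by variable elimination. The selected structure factorizes
as

    P(BMI)·P(ALB)·P(CANCER)·P(MTX|CANCER)·P(NUTR|ALB)·P(BTcP|MTX,BMI)·P(RADIO|MTX)·P(HRA|NUTR,RADIO)

so readmissions depend directly on nutritional support and radiotherapy
only. Because the study's per-patient table sits behind a data deposit, the
package ships a documented synthetic ground-truth network whose exact
marginals match the published cohort table; every pipeline stage is
exercised against it. See `docs/methods.md` for the full account.

## Worked example

Simulate a cohort, then ask how nutritional support without radiotherapy
moves the readmission class:

```sh
$ readmit-bn simulate -n 500 --seed 11 -o demo.csv
wrote 500 patients to demo.csv
$ readmit-bn query --cohort demo.csv -t HRA -e NUTR=Yes -e RADIO=No
level  marginal  posterior   shift_pp
  ≤10  0.247424   0.465116  21.769207
11–22  0.405031   0.383721  -2.130970
  >22  0.347545   0.151163 -19.638237
```

Reading: unconditionally, about 24.7% of simulated patients fall in the
lowest readmission class (≤10 accesses). Conditioning on nutritional
support without radiotherapy raises that to 46.5% — a +21.8
percentage-point shift — while the heaviest class (>22) drops from 34.8% to
15.1%: supported patients are far less likely to keep returning to
hospital, mirroring the direction of the clinical finding.

The full pipeline — screening, constrained structure learning, scoring,
queries — runs from a YAML config:

```sh
$ readmit-bn run -c config.yaml    # e.g. {synthetic_n: 10000, synthetic_seed: 1, seed: 1, output_dir: out}
load: simulated 10000 patient(s) from the ground-truth network (seed 1)
select: 8 analysis variable(s)
screen: 28 chi-square test(s), 12 significant at alpha=0.05
constraints: 4 whitelist / 11 blacklist arc(s)
learn: 3 accepted move(s), final score -51602.584, 7 arc(s)
score: lnL=-51496.666 k=23 n=10000 penalization=4.6052 bic=103205.169
query: answered 6 posterior query(ies)
artifacts written to out
```

At this sample size the search recovers exactly the 7-arc generating
structure; `out/graph_indicators.csv` then reports its structural summary
(average Markov-blanket size 2.25, neighborhood 1.75, branching 0.88)
alongside the 11-arc knowledge-based model (2.75, 1.38). All artifacts
(cohort CSV, association matrix, DOT graphs, search trace, scores, query
tables) land in the output directory, byte-identical across runs with the
same seeds.

The same machinery works from Python:

```python
from readmit_bn import study, hill_climb, fit_cpts, eliminate_query, sample_cohort
from readmit_bn.synthetic import default_ground_truth_network

cohort = sample_cohort(default_ground_truth_network(), 10_000, seed=1)
dag, trace = hill_climb(cohort, study.study_constraints())
bn = fit_cpts(cohort, dag, alpha=1.0)
print(eliminate_query(bn, "HRA", {"NUTR": "Yes", "RADIO": "No"}).to_frame())
```

If you hold a per-patient table in the deposited layout (five categorical
columns plus numeric BMI, ALB, HRA), `readmit_bn.pipeline.reproduce_study`
fits the published structure to it and reports the clinical-interest
queries at both smoothing settings.

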