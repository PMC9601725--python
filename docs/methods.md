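# Methods

## The model

The analysis treats eight categorical clinical variables — cancer site
(`CANCER`, 3 groups), body-mass-index class (`BMI`, <25 / ≥25 kg/m²), bone
metastasis (`MTX`), serum-albumin class (`ALB`, ≤3.5 / >3.5 g/dL),
nutritional support (`NUTR`), breakthrough-cancer-pain predictability
(`BTcP`), radiotherapy (`RADIO`), and the unplanned hospital-readmission
count class (`HRA`, ≤10 / 11–22 / >22) — as nodes of a multinomial Bayesian
network. A directed acyclic graph G encodes a factorization of the joint
distribution,

P(X₁,…,X₈) = Π_i P(Xᵢ | pa(Xᵢ)),

with one conditional probability table (CPT) per node. Absent arcs are
conditional-independence assumptions; in a chain A→B→C, knowing A adds
nothing about C once B is given, P(C|A,B) = P(C|B).

Structure selection scores a candidate graph with the Bayesian Information
Criterion. Both sign conventions are carried explicitly:

- minimization form: BIC = k·ln n − 2·ln L(θ̂)
- maximization form: score = ln L(θ̂) − (ln n / 2)·k, so BIC = −2·score

where k = Σ_nodes (levels−1)·Π(parent levels) counts free parameters, n is
the number of complete records, and L(θ̂) is the maximized multinomial
likelihood. The per-parameter *penalization coefficient* is ln n / 2
(≈ 2.28 at n = 96). AIC is the same score with penalization coefficient 1.
`argmin BIC ≡ argmax score`, which the tests assert. The BIC is evaluated at
the MLE (no smoothing) — the convention under which it is defined.

## Pipeline

1. **Discretization.** Measured columns map to classes at clinical cut
   points, with boundary ownership read off the class labels: BMI 25 kg/m²
   belongs to "≥25"; albumin 3.5 g/dL to "≤3.5"; readmission counts 10 and
   22 to "≤10" and "11–22". Re-binning an already categorical column is
   rejected rather than silently applied.
2. **Complete-case validation.** Rows missing any analysis value are
   dropped and counted; an undeclared category label is an error naming the
   row and column. No imputation.
3. **Association screening.** Pearson chi-square per unordered pair, no
   continuity correction (uniform behavior across 2×2 and larger tables; a
   documented divergence from software that applies Yates' correction to
   2×2 tables by default), no multiple-testing adjustment (decisions are
   per-pair, as in the reported association table). p ≤ 0.05 flags a pair
   significant — a boundary p = 0.05 counts — and p ≤ 0.10 earns a
   secondary tier for graph annotation (`**` / `*` / `•`). Expected counts
   below 5 trigger a warning but not a refusal: at n = 96 with a 16%
   metastasis rate the classic rule is necessarily violated.
4. **Constraints.** Clinical prior knowledge enters as a whitelist of
   forced arcs (BMI→BTcP, MTX→BTcP, MTX→RADIO, ALB→NUTR) and a blacklist of
   impossible ones (any arc into CANCER; ALB/NUTR into BTcP or MTX). The
   knowledge list also motivates associations (cancer type and metastasis
   with readmissions, metastasis with nutritional need) that appear in the
   knowledge-based graph but are *not* forced on the search: a hard
   whitelist arc would necessarily appear in the selected model, and these
   do not.
5. **Structure search.** Greedy hill climbing on the decomposable score:
   start from the whitelist-only graph; moves are single-arc add, delete,
   reverse; whitelist arcs are never deleted or reversed, blacklist arcs
   never added, cycle-creating moves skipped; the best strictly improving
   move (threshold 1e-9, guarding float noise) is accepted each step; ties
   break lexicographically by (move type, parent, child) so a restart-free
   run is deterministic with no seed. Optional random restarts perturb the
   start graph with up to 4 admissible random additions from a seeded
   generator; the best end point wins, ties again broken by lexicographic
   arc set. One accepted move counts as one search step (step counts are
   implementation-dependent and reported, never asserted). An exhaustive
   enumerator over all constraint-compliant DAGs (≤5 variables) serves as
   the optimality oracle; search correctness is established against it, not
   by fidelity to any particular software's search.
6. **Estimation and inference.** CPT entries are
   (count + α)/(total + α·levels). Scoring uses α = 0; *inference* defaults
   to α = 1 (Laplace) because at n ≈ 96 zero cells are likely and make
   posteriors undefined; every query result records the α that produced it,
   and the deposited-data reproduction path reports both α = 0 and α = 1
   since the original estimation smoothing is unstated. With α = 0 an
   unobserved parent configuration yields a uniform row. Queries are
   answered exactly by variable elimination with a min-degree elimination
   order (ties by name); at 576 joint states a junction tree would buy
   nothing. A full-joint enumeration oracle (refusing >10⁶ states) verifies
   elimination to 1e-10. Queries are observational conditioning — no
   do-calculus.

## Graph diagnostics

The Markov blanket of a node (parents ∪ children ∪ children's other
parents) is what renders it independent of the rest of the network.
Structural indicators reported for each model: directed arc count, average
Markov-blanket size, average neighborhood size (= 2·arcs/nodes), average
branching factor (= arcs/nodes); displayed values round half-up to two
decimals (0.875 → 0.88). For the 7-arc selected structure these are 2.25,
1.75, 0.88 over 8 nodes. The published indicator table prints an arc count
inconsistent with its own neighborhood and branching values; the
factorization-implied 7 arcs is the only consistent count and is what this
package reports. The knowledge-based graph is reconstructed from the
association list plus the direct radiotherapy–readmission link (11 arcs,
neighborhood 2.75, branching 1.38); the direction of the
radiotherapy–nutrition arc is not recoverable from the text and is oriented
RADIO→NUTR (treatment burden induces nutritional need), so its average
Markov-blanket size (4.00 here) is reconstruction-dependent and is not
asserted anywhere.

## The synthetic cohort

Real per-patient data stand behind a controlled deposit, so the test bed is
a fixed ground-truth network: the 7-arc structure with root CPTs equal to
the published cohort proportions (P(BMI≥25) = 0.458, P(ALB≤3.5) = 0.51,
cancer groups (0.18, 0.53, 0.29)) and synthetic child CPTs calibrated so
the *exact* implied marginals (computed by marginalization, not sampling)
match the published one-way table within ±0.01 — metastasis 0.16, nutrition
0.19, predictable BTcP 0.26, radiotherapy 0.115, readmission classes
(0.254, 0.400, 0.346). Conditional effects are directional encodings of the
qualitative findings (metastasis raises predictable-BTcP and radiotherapy
probability; high BMI favors non-predictable pain; nutrition without
radiotherapy shifts patients into the lowest readmission class, 45% vs 20%)
and are deliberately strong enough for structure recovery at simulation
scale. They are not estimates of the real cohort's conditionals, and
dependencies absent from the 7-arc graph (e.g. any real BMI–albumin
correlation) are deliberately not emulated — so passing recovery tests
demonstrates correctness of the algorithms under the model, not fidelity of
the model to the clinic. Sampling is ancestral in topological order from a
seeded generator; the seed is a required argument and identical seeds give
byte-identical cohorts.

## Problem sizes and numerical choices

Simulation-based checks use n = 10,000 draws for parameter/structure
recovery, n = 5,000 for screening power, and 200 replicates at n = 5,000
for type-I-error calibration of the chi-square screen (flag rate within two
Monte-Carlo σ of α); oracle-equivalence checks use 100 random queries on
the full network and 50 random four-variable instances for
search-vs-enumeration agreement. CPT rows validate to Σ = 1 within 1e-9 at
construction (fitted rows are exact to 1e-12); elimination-vs-enumeration
agreement is asserted at 1e-10; score decomposability at 1e-9.

One recovery bound deserves honesty: with the shipped generator,
P(NUTR=yes, RADIO=yes) ≈ 0.022, so at n = 10,000 that parent configuration
carries ~220 observations and each entry of its near-uniform readmission
row has sampling sd ≈ 0.032. A single MLE fit therefore recovers *every*
CPT entry to ±0.02 only with favorable sampling (estimated probability
≈ 0.1–0.3); the corresponding test states the ±0.02 condition as given and
is expected to fail for most seeds. All other calibration and recovery
checks are comfortably powered.

## Limitations

- The cohort emulator matches marginals and qualitative effects only; no
  claim is made about real conditional effect sizes.
- The chi-square screen at n = 96 operates below the classic
  expected-count rule; p-values there are approximate by construction.
- Exact inference requires the product state space to stay enumerable for
  the oracle (≤10⁶ states); the analysis network has 576.
- The exhaustive search oracle refuses more than five variables
  (29,281 DAGs at five nodes already).
- No continuous nodes, latent variables, EM, equivalence-class (CPDAG)
  output, or sampling-based inference.
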