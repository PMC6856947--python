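# Methods

## The semantic model

All meanings live on a finite domain of `n` objects (default `n = 4`, the
size of the experimental displays) and are represented extensionally as the
set of counts `k ∈ {0..n}` of predicate-satisfying objects at which the
positive sentence is true. *Some* denotes `{k ≥ 1}`, *all* denotes
`{k = n}`; context labels map deterministically (`all ⇔ k = n`,
`none ⇔ k = 0`, `gap ⇔ 0 < k < n`, realised as `k = n/2` in displays).

Exhaustification `exh(p, A)` conjoins the prejacent with the negations of
its *innocently excludable* alternatives: an alternative not entailed by the
prejacent is excluded iff it belongs to every maximal subset of candidates
whose joint negation leaves the prejacent non-empty. On entailment scales
this reduces to negating the strictly stronger alternatives, but the general
criterion is implemented (and exercised by a symmetric-alternatives test).
Recursive exhaustification `exh(exh(p))` exhaustifies the prejacent against
the raw alternatives and then negates the *exhaustified* alternatives; an
alternative may carry its own scale (the definite's sole alternative *some*
carries *all*), which is how the existential literal `{k ≥ 1}` strengthens
to the universal `{k = n}` for every domain size.

Trivalent evaluation assigns TRUE/FALSE/GAP per reading. The homogeneous
reading is true iff `k = n`, false iff `k = 0`, and a gap otherwise — equal
to the supervaluation over the existential and universal construals, a
property the tests check. Negation is trivalent negation for the low-scope
readings; the wide-scope universal construals (`ws`, `pt`) parse the negated
definite as `∀¬` (true iff `k = 0`), and the wide-scope existential pattern
(`wse`, binary only) as `∃¬` (true iff `k < n`).

### Response templates

Binary: accept iff the sentence evaluates TRUE and (for `+si` groups) carries
no false implicature; the gap maps to rejection, matching the operational
definition of homogeneity in a yes/no task. The implicature flag only ever
touches sentences with lexical *some*: it is implemented semantically, by
evaluating the positive *some* sentence against its exhaustified meaning, so
`some-all-pos` flips for `+si` groups while `some-gap-pos` (strengthened
meaning still true) does not, and the definite is never affected.

Ternary: TRUE/GAP/FALSE map to +1/0/−1; a literally-true sentence with a
false implicature earns the intermediate reward; the scope-ambiguity
strategy (`sa`) gives the intermediate response to the negated definite in
gap contexts; the partial-truth strategy (`pt`) upgrades "partially true"
falsity (a failed positive universal claim with `k > 0`, or a failed
wide-scope negative universal with `k < n`) to the intermediate response.
Three ternary cells — how `sa`/`ws`/`pt` respond to the negated universal
control `all-gap-neg` — are not fixed by any of these principles; they
default to the published prediction table (1/0/0) and are exposed as a
`ternary_overrides` argument.

One printed cell of the published binary prediction table (the positive gap
target under the universal reading) contradicts the verbal definition of the
universal pattern; the derivation follows the verbal definition and treats
the printed cell as a typo. Likewise the printed ternary table's `sa`/`ws`
gap-target cells disagree with the prose definitions of those strategies;
the prose wins.

## The synthetic-data generator

The generator emulates the two designs: 24 binary trials (3+3 definite gap
targets, 8 definite controls, 3+3 universal controls, 4 implicature targets)
and 26 ternary trials (3+3 definite gap targets, 8 definite controls, 3
implicature targets, 3 incomplete-description, 3 partial-truth and 3
scope-ambiguity controls). Every third trial is a definite control. The
original studies chose control targets *dynamically* in reaction to the
child's answers, purely to prevent response-sequence biases; since a
simulator has no such biases to counter, controls are instead balanced
(half clearly true, half clearly false) and randomly ordered.

Subjects are drawn i.i.d. from configurable group weights; responses equal
the subject's template value except with probability ε (the lapse rate), in
which case they are uniform over the *other* response option(s). Defaults:
`n_subjects = 24` (the experimental cohort size), binary group weights
6:10:7:1 over hom/−si, hom/+si, exi/−si, exi/+si (the canonical child
distribution), ε = 0.05 — a small symmetric noise level standing in for the
unmodelled response variability visible in group-level data. A single master
seed feeds three independent streams (trial order, group draws, lapses), so
changing the cohort size never perturbs the trial list.

What the generator does *not* emulate: age as a covariate,
condition-specific infelicity (e.g. children's reluctance to reward negative
descriptions of `none` displays), sequential or fatigue effects, and any
real-data lapse structure beyond a single symmetric ε. Passing recovery
tests therefore show that the estimators invert *this* generative process,
not that real children satisfy its assumptions.

## Descriptive categorization

Inclusion requires ≥ 6 of 8 correct definite controls (ternary: maximal on
clearly-true, minimal on clearly-false). Binary homogeneity categories come
from majority (≥ 2/3) responses per polarity and partition all 2⁶ profiles;
ternary categories check existential and universal (which need extreme
rewards) before homogeneous (non-maximal on ≥ 2/3 of each polarity), with
`inconsistent` as the remainder — the three rules are mutually exclusive on
three trials, so no tie-break is needed. The ternary implicature rule is a
design choice (the source studies leave it implicit): majority of three with
any non-maximal reward counting as implicature-driven rejection. The
chi-square helper computes the plain Pearson statistic without continuity
correction and refuses tables with zero expected cells.

## Random-responder enumeration

With three trials per polarity, a fair binary responder lands in each of the
four homogeneity patterns with probability 1/4; four fair implicature trials
give +si/−si/mixed probabilities 5/16, 5/16, 6/16. Scenario A (random on
homogeneity only) is a binomial tail in exact rationals. Scenario B (random
on both) is an exact multinomial tail over the joint cells; children with
mixed implicature behaviour in allowed homogeneity rows are unconstrained by
the event (remainder mass 22/64). The stricter reading that confines the
remainder to the existential row is available as `constrain_mixed`; it can
only shrink the tail, and tests verify the published bound under both
readings. The Monte-Carlo cross-check generates genuinely uniform responses
*through the simulator* (binary lapse rate 1/2 makes the response uniform
regardless of template) and categorizes them with the real majority rules,
so it also exercises the categorizer.

## The latent-group mixture

Given group `g` with template value `t(g, c)` for condition `c`:

* binary: `y ~ Bernoulli(logistic(α + β·t))`;
* ternary: cumulative logit, `P(y ≤ j) = logistic(c_j − β·t)` with ordered
  cutpoints `c₁ < c₂` and no separate intercept (the cutpoints absorb it —
  the standard identifiability convention for proportional-odds models).

`β > 0` is enforced so that larger template values push toward acceptance /
higher rewards, which anchors the group labels. Each subject's discrete
group is marginalized out of the likelihood; the per-subject prior over
groups is uniform (matching a flat prior on a subject-varying group
parameter). Priors on the continuous parameters are weakly informative:
`α ~ N(0, 2.5)`, `β ~ half-N(0, 4)`, cutpoints `N(0, 3)` (ordered). Scales
were chosen on the logit scale so that template effects up to near-determinism
(|η| ≈ 10) stay in support.

Two inference backends share all downstream code:

* **grid** (default): a deterministic tensor-product quadrature over
  (α, β) or (c₁, c₂, β) — 13 nodes per binary axis, 7 per ternary axis —
  with prior-weighted nodes renormalized by the marginal likelihood. Mixing
  weights stay at their uniform prior value. Everything downstream (group
  probabilities, LOO) is then an exact finite sum: runs are reproducible
  bit-for-bit and fast enough for CI-scale simulation studies.
* **mcmc**: the emcee ensemble sampler over unconstrained parameters
  (log-transformed β and cutpoint gap, softmax-transformed mixing weights
  with a flat Dirichlet prior). Used when one wants the weights sampled or
  prior sensitivity checked; acceptance fractions and Pareto-k diagnostics
  are reported, never swallowed.

### Leave-one-out elpd

Within a subject, observations are dependent once the group is marginalized,
so the pointwise quantity is the *conditional* predictive
`f_i(θ) = p(y_i | y_{s,−i}, θ)`; its reciprocal is exactly the importance
weight for removing observation `i` from the posterior. On the grid this
gives LOO as an exact finite sum (verified against a refit-per-observation
oracle to machine precision); on MCMC draws the weights are Pareto-smoothed
(arviz `psislw`) with the usual `k̂ > 0.7` warning threshold. Inventory
comparisons report each model's elpd and SE plus the difference to the best
inventory with its *paired* pointwise SE. `Δelpd = 0` for identical
inventories by construction.

A consequence of the flat per-subject group prior is that admitting an
unpopulated group costs a small but non-zero amount of elpd (prior mass is
spent on templates nobody follows). The tests therefore check the
qualitative asymmetry that matters for the scientific question: dropping a
*populated* group costs several times more than carrying an empty one.

### Analysis presets

The ternary analyses ship as named configurations: `analysis1` restricts the
conditions to the definite sentences plus `some-all-pos`, admits `hom/+si`
as the only implicature-computing group, and explores the seven non-empty
combinations of hom/−si, ws/−si, sa/−si (always alongside exi/−si);
`analysis2` adds sa/+si and ws/+si throughout; `analysis3` adds pt/−si and
the `all-gap-pos` condition needed to separate partial truth from
homogeneity. `exi/+si` is excluded from every ternary inventory, following
the near-absence of that profile in the binary experiment.

## Numerical choices and degenerate inputs

Enumeration uses `fractions.Fraction` throughout, converting to float only
for reporting. Ternary category probabilities are clipped at 1e−300 before
logs. Argmax group assignment breaks exact ties toward the lowest inventory
index and flags them. Cohorts of size 0, single-group inventories, missing
conditions, out-of-range responses and malformed CSVs raise structured
errors naming the offending label, subject or cell.

## Problem sizes

Simulation-based checks use experiment-sized cohorts (24 subjects) for
recovery and comparison tests, 200 subjects per lapse level for the
noise-monotonicity study, and 1.2 × 10⁵ Monte-Carlo cohorts for the
enumeration cross-check — sizes at which the binomial error of every
reported rate is a few percent or less, while the whole suite stays
desk-scale. The exact enumerations and template derivations involve no
sampling at all.

## Known limitations

The model inherits the source design's identification limits: with binary
responses, a truly homogeneous reader and a wide-scope universal reader are
indistinguishable, and `uni/+si` vs `uni/−si` differ only on the four
implicature trials. The grid backend fixes mixing weights at uniform; if the
scientific question is about the weights themselves, use the MCMC backend.
The lapse model is shared across conditions and subjects; heterogeneous
lapse rates would be absorbed partly into β and can bias posterior group
probabilities toward over-confidence. Real-data fits from the source studies
are not reproduced here — the deposited data are an external download — so
all quantitative claims are about synthetic cohorts.
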