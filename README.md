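# plurhom

Latent-group analysis of **homogeneity** in plural definite descriptions.

Sentences like *The trucks are blue* and *The trucks aren't blue* are both
neither true nor false when some of the trucks are blue and some are not — a
truth-value **gap**. In a truth-value-judgment task, a participant's paired
responses to the positive and negative sentence in such gap displays reveal
which construal they assign to the definite plural: **homogeneous** (reject /
non-maximal on both), **existential** (accept the positive, reject the
negative), **universal** (the reverse), or, with a three-point reward scale,
finer-grained wide-scope and response-strategy variants. Because the
homogeneous reading can be analysed as a *recursive scalar implicature* over
an existential literal meaning, the same design probes whether participants
also compute the ordinary *some ⇝ not all* implicature.

`plurhom` is a pipeline for such data, aimed at developmental
psycholinguists who want to classify participants by interpretive profile and
quantify the evidence for each latent subgroup:

* **Trivalent semantics** (`plurhom.semantics`) — finite-model meanings over
  the number `k` of matching objects, an innocent-exclusion exhaustification
  operator `exh`, and the recursive strengthening
  `exh(exh(the-NP))` that turns the existential literal `{k ≥ 1}` into the
  universal `{k = n}`. From the evaluation rules it derives, for every group
  `g = (reading, ±si)`, the predicted response template over all design
  conditions (labels `"<determiner>-<context>-<polarity>"`, e.g.
  `the-gap-pos`), for both the binary (accept/reject) and ternary
  (reward −1/0/+1) paradigms.
* **Synthetic cohorts** (`plurhom.simulate`) — trial lists replicating both
  designs (24 binary trials, 26 ternary trials, every third trial a
  clearly-true/false control), subjects drawn from a mixture of groups, and
  template responses corrupted by a symmetric lapse rate ε.
* **Descriptive categorization** (`plurhom.categorize`) — the majority-rule
  scheme: 6-of-8 control inclusion, 2-of-3 homogeneity rules, 3-of-4 (binary)
  or 2-of-3 (ternary) implicature rules, ternary bias flags, and Pearson
  chi-square comparisons of group distributions.
* **Random-responder enumeration** (`plurhom.enumeration`) — exact rational
  tail probabilities that an observed group configuration arose from children
  answering at chance, plus a Monte-Carlo cross-check through the real
  simulate-and-categorize path.
* **Latent-group mixture model** (`plurhom.mixture`) — a Bayesian finite
  mixture with a per-subject latent group: binary responses follow
  `P(accept) = logistic(α + β·t)` with template value `t ∈ {0,1}`; ternary
  responses follow a cumulative-logit model with linear predictor `β·t`,
  `t ∈ {−1,0,1}`, and ordered cutpoints `c₁ < c₂`. The group is marginalized
  per subject; inference runs on a deterministic quadrature grid or by MCMC
  (emcee), and inventories of admissible groups are compared by leave-one-out
  expected log predictive density (elpd).
* **Pipeline + CLI** (`plurhom.pipeline`, `plurhom` console command) —
  simulate or load a cohort, run every stage, and write tidy report tables
  with a manifest and log.

## Worked example

Simulate a 24-child binary cohort with known groups (9 hom/+si, 6 hom/−si,
9 exi/−si after the mixture draw) and a 10% lapse rate, then categorize and
fit the mixture:

```python
import plurhom as ph

cfg = ph.SimulationConfig(
    experiment="EXP1", n_subjects=24,
    group_weights={"hom/-si": 6/24, "hom/+si": 10/24, "exi/-si": 7/24, "exi/+si": 1/24},
    lapse_rate=0.1, seed=1,
)
records = ph.simulate_cohort(cfg)

summary = ph.summarize_subjects(records)
print(ph.group_counts(summary))

model = ph.LatentGroupMixture(
    paradigm="binary", groups=["exi/+si", "exi/-si", "hom/+si", "hom/-si"]
).fit(records)
print(ph.assignment_counts(model))
print(f"elpd = {model.elpd_:.2f} (se {model.elpd_se_:.2f})")
```

```
si_category           minus_si  plus_si  mixed
homogeneity_category
homogeneous                  7        6      1
existential                  5        0      0
universal                    0        1      0
si       -si  +si
reading
exi        8    0
hom        7    9
elpd = -239.75 (se 16.32)
```

The majority rules misplace several noisy subjects (one lands in `universal`,
one in `mixed`), while the model-based argmax assignment recovers 23 of the
24 latent groups (96% versus 88% exact matches for the descriptive scheme);
at lapse rate 0 both recover every subject. `model.group_probs_` holds the
per-subject posterior probabilities behind the counts.

How unlikely is such a configuration under random responding? The exact
enumeration from the command line:

```
$ plurhom enumerate --scenario A --n-max 9
scenario  n_random  tail_probability
       A         6          0.000244
       A         7          0.000488
       A         8          0.000565
       A         9          0.000496
```

i.e. even the loosest case (n = 8) has probability below 0.001 of producing a
configuration as extreme as the observed one by chance.

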