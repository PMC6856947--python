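"""Exact tail probabilities for the random-responder null.

Could the observed configuration of interpretive groups have arisen from
children answering at chance?  With three homogeneity trials per polarity, a
random binary responder lands in each of the four homogeneity patterns with
probability 1/4; with four fair implicature trials the 3-of-4 rule yields
+si with probability 5/16, −si with 5/16 and mixed with 6/16.  The module
computes, in exact rational arithmetic, the probability of configurations at
least as extreme as the observed one under two scenarios:

* Scenario A — implicature answers are non-random; of ``n`` random
  homogeneity responders, at least six fall in the homogeneous pattern and
  the rest all in the existential pattern.
* Scenario B — responses are random on homogeneity *and* implicature trials;
  at least six children land in homogeneous/−si, none in any universal or
  wide-scope-existential cell, and at most one in existential/+si.

A Monte-Carlo cross-check pushes uniformly random responses through the real
simulate-then-categorize pipeline.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd

from .categorize import categorize_homogeneity, categorize_implicature
from .simulate import SimulationConfig, sample_population, simulate_responses

HOMOGENEITY_PATTERNS = ("homogeneous", "existential", "universal", "wide_scope_existential")
SI_PATTERNS = ("plus_si", "minus_si", "mixed")


def _majority_prob(n_trials: int) -> Fraction:
    """P(majority of fair binary trials on one side); requires odd n."""
    if n_trials % 2 == 0:
        raise ValueError("majority categorization requires an odd trial count")
    hits = sum(comb(n_trials, k) for k in range(n_trials // 2 + 1, n_trials + 1))
    return Fraction(hits, 2**n_trials)


def _si_probs(n_trials: int = 4, need: int = 3) -> dict[str, Fraction]:
    """Category probabilities for fair responses on the implicature trials
    under the >=``need``-of-``n_trials`` rule."""
    tail = sum(comb(n_trials, k) for k in range(need, n_trials + 1))
    p = Fraction(tail, 2**n_trials)
    return {"plus_si": p, "minus_si": p, "mixed": 1 - 2 * p}


def random_cell_probs(
    scenario: str = "A",
    n_pos: int = 3,
    n_neg: int = 3,
    n_si: int = 4,
    si_need: int = 3,
) -> dict:
    """Probability of each category cell for a random responder.

    Scenario A returns the four homogeneity patterns; scenario B the joint
    (pattern, si) cells as a dict keyed by ``(pattern, si_category)``.
    """
    p_pos, p_neg = _majority_prob(n_pos), _majority_prob(n_neg)
    hom_probs = {
        "homogeneous": p_pos * p_neg,
        "existential": (1 - p_pos) * p_neg,
        "universal": p_pos * (1 - p_neg),
        "wide_scope_existential": (1 - p_pos) * (1 - p_neg),
    }
    if scenario == "A":
        return hom_probs
    if scenario == "B":
        si = _si_probs(n_si, si_need)
        return {(h, s): hp * sp for h, hp in hom_probs.items() for s, sp in si.items()}
    raise ValueError(f"unknown scenario: {scenario!r}")


def tail_prob_scenario_a(n_random: int, threshold: int = 6) -> Fraction:
    """P(at least ``threshold`` of ``n_random`` random responders fall in the
    homogeneous pattern and every other one in the existential pattern, the
    two remaining patterns staying empty)."""
    if n_random < threshold:
        raise ValueError(
            f"event impossible: need at least {threshold} random responders, got {n_random}"
        )
    cells = random_cell_probs("A")
    p_h, p_e = cells["homogeneous"], cells["existential"]
    return sum(
        comb(n_random, k) * p_h**k * p_e ** (n_random - k)
        for k in range(threshold, n_random + 1)
    )


def tail_prob_scenario_b(
    n_random: int,
    threshold: int = 6,
    max_exi_plus: int = 1,
    constrain_mixed: bool = False,
) -> Fraction:
    """Exact multinomial tail for the joint homogeneity-and-implicature null.

    Children in homogeneous or existential rows with uninformative (mixed or
    unnamed) implicature categories are unconstrained by the event; setting
    ``constrain_mixed`` restricts the remainder to the existential row only
    (the strictest reading of the event), which can only shrink the tail.
    """
    if n_random < threshold:
        raise ValueError(
            f"event impossible: need at least {threshold} random responders, got {n_random}"
        )
    cells = random_cell_probs("B")
    p_h = cells[("homogeneous", "minus_si")]
    p_e = cells[("existential", "plus_si")]
    allowed_rest = [
        ("homogeneous", "plus_si"),
        ("homogeneous", "mixed"),
        ("existential", "minus_si"),
        ("existential", "mixed"),
    ]
    if constrain_mixed:
        allowed_rest = [("existential", "minus_si"), ("existential", "mixed")]
    p_rest = sum(cells[c] for c in allowed_rest)
    total = Fraction(0)
    for h in range(threshold, n_random + 1):
        for e in range(0, min(max_exi_plus, n_random - h) + 1):
            r = n_random - h - e
            coeff = factorial(n_random) // (factorial(h) * factorial(e) * factorial(r))
            total += coeff * p_h**h * p_e**e * p_rest**r
    return total


def tail_table(
    scenario: str, n_values: range | list[int], threshold: int = 6
) -> pd.DataFrame:
    """Tabulate n versus exact tail probability for a scenario."""
    fn = tail_prob_scenario_a if scenario == "A" else tail_prob_scenario_b
    rows = [
        {"scenario": scenario, "n_random": n, "tail_probability": float(fn(n, threshold))}
        for n in n_values
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-check through the real pipeline
# ---------------------------------------------------------------------------

def _uniform_records(n_subjects: int, conditions: dict[str, int], seed: int) -> pd.DataFrame:
    """Binary responses uniform on every trial, produced by the actual
    simulator: at lapse rate 1/2 a binary response is the template value or
    its complement with equal probability, i.e. exactly uniform."""
    config = SimulationConfig(
        experiment="EXP1",
        n_subjects=n_subjects,
        group_weights={"hom/-si": 1.0},
        lapse_rate=0.5,
        seed=seed,
    )
    trials = pd.DataFrame(
        {
            "trial_index": np.arange(1, sum(conditions.values()) + 1),
            "condition": [c for c, m in conditions.items() for _ in range(m)],
        }
    )
    subjects = sample_population(config)
    return simulate_responses(subjects, trials, config)


def monte_carlo_tail(
    scenario: str,
    n_random: int,
    reps: int,
    seed: int = 0,
    threshold: int = 6,
) -> tuple[float, float]:
    """Estimate the tail probability by simulating ``reps`` cohorts of
    ``n_random`` uniformly random responders and categorizing them with the
    real majority-rule categorizer.  Returns (estimate, binomial SE)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    conditions = {"the-gap-pos": 3, "the-gap-neg": 3}
    if scenario == "B":
        conditions["some-all-pos"] = 4
    if scenario not in ("A", "B"):
        raise ValueError(f"unknown scenario: {scenario!r}")
    records = _uniform_records(reps * n_random, conditions, seed)
    hom = categorize_homogeneity(records, "binary")
    frame = pd.DataFrame(
        {
            "cohort": np.repeat(np.arange(reps), n_random),
            "is_hom": (hom == "homogeneous").to_numpy(),
            "is_exi": (hom == "existential").to_numpy(),
        },
        index=hom.index,
    )
    if scenario == "A":
        agg = frame.groupby("cohort")[["is_hom", "is_exi"]].sum()
        hits = (agg["is_hom"] >= threshold) & (agg["is_hom"] + agg["is_exi"] == n_random)
    else:
        si = categorize_implicature(records, "binary")
        frame["is_hom_minus"] = frame["is_hom"] & (si == "minus_si").to_numpy()
        frame["is_exi_plus"] = frame["is_exi"] & (si == "plus_si").to_numpy()
        frame["is_forbidden"] = ~(frame["is_hom"] | frame["is_exi"])
        agg = frame.groupby("cohort")[["is_hom_minus", "is_exi_plus", "is_forbidden"]].sum()
        hits = (
            (agg["is_hom_minus"] >= threshold)
            & (agg["is_forbidden"] == 0)
            & (agg["is_exi_plus"] <= 1)
        )
    estimate = float(hits.mean())
    se = float(np.sqrt(estimate * (1 - estimate) / reps))
    return estimate, se
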