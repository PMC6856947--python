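"""Latent-group mixture model: likelihoods, fitting, LOO, comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from plurhom import (
    Group,
    LatentGroupMixture,
    ModelParams,
    SimulationConfig,
    analysis_conditions,
    assign_groups,
    assignment_counts,
    compare_inventories,
    exact_loo,
    exp2_inventories,
    mixture_loglik,
    observation_loglik,
    simulate_cohort,
)


def true_groups(records: pd.DataFrame) -> pd.Series:
    return records.drop_duplicates("subject_id").set_index("subject_id")["true_group"]


class TestObservationLoglik:
    def test_null_slope_is_coin_flip(self):
        params = ModelParams(alpha=0.0, beta=1e-9)
        for resp in (0, 1):
            ll = observation_loglik(resp, "the-gap-pos", Group.from_label("exi/-si"), params, "binary")
            assert ll == pytest.approx(np.log(0.5), abs=1e-6)

    def test_saturation_at_large_slope(self):
        params = ModelParams(alpha=0.0, beta=30.0)
        ll = observation_loglik(1, "the-gap-pos", Group.from_label("exi/-si"), params, "binary")
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_ternary_intermediate_is_modal_for_gap_template(self):
        params = ModelParams(beta=8.0, c1=-1.0, c2=1.0)
        probs = [
            np.exp(
                observation_loglik(r, "the-gap-pos", Group.from_label("hom/-si"), params, "ternary")
            )
            for r in (-1, 0, 1)
        ]
        assert np.argmax(probs) == 1
        assert sum(probs) == pytest.approx(1.0)

    def test_ternary_cumulative_logit_closed_form(self):
        from scipy.special import expit

        params = ModelParams(beta=2.0, c1=-0.5, c2=1.5)
        t = 1  # the-gap-pos under the existential reading
        expected = [
            expit(params.c1 - params.beta * t),
            expit(params.c2 - params.beta * t) - expit(params.c1 - params.beta * t),
            1 - expit(params.c2 - params.beta * t),
        ]
        for r, e in zip((-1, 0, 1), expected):
            ll = observation_loglik(r, "the-gap-pos", Group.from_label("exi/-si"), params, "ternary")
            assert ll == pytest.approx(np.log(e))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            ModelParams(beta=-1.0)
        with pytest.raises(ValueError, match="c1 < c2"):
            ModelParams(c1=1.0, c2=-1.0)

    def test_invalid_response_rejected(self):
        with pytest.raises(ValueError, match="response"):
            observation_loglik(2, "the-gap-pos", Group.from_label("exi/-si"), ModelParams(), "binary")


class TestMarginalization:
    @pytest.mark.parametrize("paradigm,experiment", [("binary", "EXP1"), ("ternary", "EXP2")])
    def test_matches_brute_force_over_group_assignments(self, paradigm, experiment):
        """For a 3-subject cohort, the per-subject marginalization equals
        the explicit sum over all |G|^3 joint group assignments."""
        weights = {"hom/-si": 0.5, "exi/-si": 0.5}
        config = SimulationConfig(
            experiment=experiment, n_subjects=3, group_weights=weights, lapse_rate=0.2, seed=21
        )
        records = simulate_cohort(config)
        groups = ["exi/-si", "hom/-si", "hom/+si"]
        params = ModelParams(alpha=0.3, beta=1.7, c1=-0.8, c2=1.1)
        factorized = mixture_loglik(records, groups, params, paradigm)

        subjects = sorted(records["subject_id"].unique())
        per_subject = {
            (sid, g): sum(
                observation_loglik(int(r), c, Group.from_label(g), params, paradigm)
                for r, c in zip(*(records[records["subject_id"] == sid][k] for k in ("response", "condition")))
            )
            for sid in subjects
            for g in groups
        }
        total = -np.inf
        log_pi = np.log(1 / len(groups))
        for assignment in itertools.product(groups, repeat=len(subjects)):
            joint = sum(per_subject[(sid, g)] + log_pi for sid, g in zip(subjects, assignment))
            total = np.logaddexp(total, joint)
        assert factorized == pytest.approx(total)

    def test_null_slope_collapses_to_coin_flip_model(self):
        """As beta -> 0 the binary mixture's likelihood approaches the
        Bernoulli(1/2) null regardless of groups."""
        config = SimulationConfig(
            experiment="EXP1", n_subjects=4, group_weights={"hom/-si": 1.0}, lapse_rate=0.3, seed=5
        )
        records = simulate_cohort(config)
        ll = mixture_loglik(records, ["exi/-si", "hom/-si"], ModelParams(alpha=0.0, beta=1e-9), "binary")
        assert ll == pytest.approx(len(records) * np.log(0.5), rel=1e-6)


class TestFit:
    def test_noiseless_recovery_binary(self, exp1_noiseless):
        model = LatentGroupMixture(
            paradigm="binary", groups=["exi/+si", "exi/-si", "hom/+si", "hom/-si"]
        ).fit(exp1_noiseless)
        truth = true_groups(exp1_noiseless)
        pred = model.predict()
        assert (pred == truth.loc[pred.index]).all()
        assert model.group_probs_.max(axis=1).min() > 0.99

    def test_noiseless_recovery_ternary(self, exp2_noiseless):
        model = LatentGroupMixture(
            paradigm="ternary",
            groups=["exi/-si", "hom/+si", "hom/-si", "ws/-si", "sa/-si", "pt/-si"],
        ).fit(exp2_noiseless)
        truth = true_groups(exp2_noiseless)
        pred = model.predict()
        assert (pred == truth.loc[pred.index]).all()
        assert model.group_probs_.max(axis=1).min() > 0.99

    def test_single_group_spec_gives_probability_one(self, exp1_noiseless):
        model = LatentGroupMixture(paradigm="binary", groups=["hom/+si"]).fit(exp1_noiseless)
        assert np.allclose(model.group_probs_.to_numpy(), 1.0)

    def test_group_probabilities_sum_to_one(self, exp1_noisy):
        model = LatentGroupMixture(paradigm="binary").fit(exp1_noisy)
        assert np.allclose(model.group_probs_.sum(axis=1), 1.0)

    def test_relabeling_invariance(self, exp1_noisy):
        groups = ["exi/-si", "hom/+si", "hom/-si"]
        a = LatentGroupMixture(paradigm="binary", groups=groups).fit(exp1_noisy)
        b = LatentGroupMixture(paradigm="binary", groups=groups[::-1]).fit(exp1_noisy)
        assert np.allclose(
            a.group_probs_[groups].to_numpy(), b.group_probs_[groups].to_numpy()
        )
        assert a.elpd_ == pytest.approx(b.elpd_)

    def test_elpd_nonpositive(self, exp1_noisy):
        model = LatentGroupMixture(paradigm="binary").fit(exp1_noisy)
        assert model.elpd_ < 0
        assert model.elpd_se_ > 0

    def test_missing_condition_is_an_error(self, exp1_noisy):
        with pytest.raises(ValueError, match="never observed"):
            LatentGroupMixture(paradigm="binary").fit(
                exp1_noisy[exp1_noisy["condition"] != "some-all-pos"]
            )

    def test_empty_inventory_rejected(self, exp1_noisy):
        with pytest.raises(ValueError, match="non-empty"):
            LatentGroupMixture(paradigm="binary", groups=[]).fit(exp1_noisy)

    def test_exact_tie_breaks_to_lowest_index(self, exp1_noiseless):
        # exi/+si and exi/-si are indistinguishable without some-all-pos
        conditions = ["the-gap-pos", "the-gap-neg", "the-all-pos", "the-none-pos"]
        model = LatentGroupMixture(
            paradigm="binary", groups=["exi/+si", "exi/-si"], conditions=conditions
        ).fit(exp1_noiseless)
        assignment = assign_groups(model)
        assert (assignment["group"] == "exi/+si").all()
        assert assignment["tie"].all()

    def test_sklearn_protocol(self, exp1_noisy):
        from sklearn.base import clone

        model = LatentGroupMixture(paradigm="binary", grid_size=9)
        cloned = clone(model)
        assert cloned.get_params()["grid_size"] == 9
        cloned.set_params(grid_size=7).fit(exp1_noisy)
        assert hasattr(cloned, "elpd_")


class TestLoo:
    def test_quadrature_loo_matches_exact_refits(self):
        config = SimulationConfig(
            experiment="EXP1",
            n_subjects=6,
            group_weights={"hom/-si": 0.5, "exi/-si": 0.5},
            lapse_rate=0.15,
            seed=31,
        )
        records = simulate_cohort(config)
        model = LatentGroupMixture(
            paradigm="binary", groups=["exi/-si", "hom/-si"], grid_size=9
        ).fit(records)
        oracle = exact_loo(model, records)
        assert np.allclose(model.pointwise_loglik_, oracle, atol=1e-10)

    def test_mcmc_agrees_with_quadrature(self):
        config = SimulationConfig(
            experiment="EXP1",
            n_subjects=8,
            group_weights={"hom/-si": 0.5, "exi/-si": 0.5},
            lapse_rate=0.1,
            seed=17,
        )
        records = simulate_cohort(config)
        grid = LatentGroupMixture(paradigm="binary", groups=["exi/-si", "hom/-si"]).fit(records)
        mcmc = LatentGroupMixture(
            paradigm="binary",
            groups=["exi/-si", "hom/-si"],
            backend="mcmc",
            n_steps=400,
            n_burn=150,
            random_state=2,
        ).fit(records)
        assert mcmc.diagnostics_["pareto_k_max"] < 0.7
        assert abs(mcmc.elpd_ - grid.elpd_) < 2 * grid.elpd_se_
        pred_g, pred_m = grid.predict(), mcmc.predict()
        assert (pred_g == pred_m).all()


class TestComparison:
    def test_identical_inventories_have_zero_delta(self, exp1_noisy):
        inventories = {"a": ["exi/-si", "hom/-si"], "b": ["exi/-si", "hom/-si"]}
        table = compare_inventories(exp1_noisy, inventories, paradigm="binary")
        assert table["delta_elpd"].abs().max() == pytest.approx(0.0)

    def test_including_a_populated_group_improves_elpd(self, exp1_noisy):
        inventories = {
            "with_hom_minus": ["exi/+si", "exi/-si", "hom/+si", "hom/-si"],
            "without_hom_minus": ["exi/+si", "exi/-si", "hom/+si"],
        }
        table = compare_inventories(exp1_noisy, inventories, paradigm="binary")
        assert table.loc["with_hom_minus", "elpd"] > table.loc["without_hom_minus", "elpd"]

    def test_empty_group_margin_is_small_next_to_a_populated_one(self):
        """Dropping a populated group costs far more elpd than carrying an
        unpopulated one, the qualitative asymmetry behind the inventory
        comparisons."""
        config = SimulationConfig(
            experiment="EXP1",
            n_subjects=24,
            group_weights={"hom/-si": 0.5, "hom/+si": 0.5},
            lapse_rate=0.1,
            seed=23,
        )
        records = simulate_cohort(config)
        inventories = {
            "base": ["hom/+si", "hom/-si"],
            "plus_empty": ["hom/+si", "hom/-si", "exi/+si"],
            "minus_populated": ["hom/+si"],
        }
        table = compare_inventories(records, inventories, paradigm="binary")
        empty_penalty = table.loc["base", "elpd"] - table.loc["plus_empty", "elpd"]
        populated_gain = table.loc["base", "elpd"] - table.loc["minus_populated", "elpd"]
        assert 0 <= empty_penalty < populated_gain / 3

    def test_assignment_counts_match_simulated_tally(self, exp1_noiseless):
        model = LatentGroupMixture(
            paradigm="binary", groups=["exi/+si", "exi/-si", "hom/+si", "hom/-si"]
        ).fit(exp1_noiseless)
        counts = assignment_counts(model)
        tally = true_groups(exp1_noiseless).value_counts()
        assert counts.loc["hom", "-si"] == tally.get("hom/-si", 0)
        assert counts.loc["exi", "+si"] == tally.get("exi/+si", 0)
        assert counts.to_numpy().sum() == 24


class TestPresets:
    def test_analysis_conditions(self):
        assert "some-all-pos" in analysis_conditions("analysis1")
        assert "all-gap-pos" not in analysis_conditions("analysis1")
        assert "all-gap-pos" in analysis_conditions("analysis3")

    def test_inventories_never_include_exi_plus_si(self):
        for preset in ("analysis1", "analysis2", "analysis3"):
            for groups in exp2_inventories(preset).values():
                assert "exi/+si" not in groups
                assert "exi/-si" in groups

    def test_analysis1_explores_seven_combinations(self):
        inventories = exp2_inventories("analysis1")
        assert len(inventories) == 7
        for groups in inventories.values():
            assert set(g for g in groups if g.endswith("+si")) == {"hom/+si"}

    def test_analysis3_adds_partial_truth(self):
        for groups in exp2_inventories("analysis3").values():
            assert "pt/-si" in groups
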