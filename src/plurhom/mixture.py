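"""Bayesian latent-group mixture model for judgment data.

Each subject carries a discrete latent *group* (a reading of the definite
plural plus a scalar-implicature flag).  Given the group, responses are
independent across trials with template-driven probabilities:

* binary paradigm: ``P(accept) = logistic(alpha + beta * t)`` with template
  value ``t`` in {0, 1};
* ternary paradigm: a cumulative-logit (proportional-odds) model with linear
  predictor ``beta * t``, ``t`` in {−1, 0, 1}, and ordered cutpoints
  ``c1 < c2`` separating the minimal / intermediate / maximal rewards.

The slope ``beta`` is constrained positive so that a higher template value
raises the response, which pins the group labels.  The latent group is
marginalized per subject; continuous parameters get weakly-informative
zero-centred priors and are integrated either over a deterministic quadrature
grid (exact, fast, reproducible) or by MCMC (emcee ensemble sampler).

Model comparison uses leave-one-out expected log predictive density.  Because
observations within a subject are exchangeable only given the group, the
pointwise quantity is the within-subject conditional predictive
``p(y_i | y_{s,-i}, theta)``; its reciprocal is the exact importance weight
for dropping observation ``i``, so quadrature LOO is exact on the grid and
PSIS-smoothed on MCMC draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy import stats
from sklearn.base import BaseEstimator

from .conditions import PARADIGM_CONDITIONS, PARADIGM_RESPONSES
from .semantics import Group, PARADIGM_GROUPS, Reading, derive_template

__all__ = [
    "ModelParams",
    "observation_loglik",
    "mixture_loglik",
    "LatentGroupMixture",
    "assign_groups",
    "assignment_counts",
    "loo_elpd",
    "exact_loo",
    "compare_inventories",
    "analysis_conditions",
    "exp2_inventories",
]


@dataclass(frozen=True)
class ModelParams:
    """Continuous parameters at one posterior point."""

    alpha: float = 0.0          # binary intercept
    beta: float = 1.0           # template slope, > 0
    c1: float = -1.0            # ternary cutpoints, c1 < c2
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.c1 >= self.c2:
            raise ValueError("cutpoints must satisfy c1 < c2")


def _binary_logp(alpha: float, beta: float, t: np.ndarray) -> np.ndarray:
    """log P(response | template) for responses (0, 1); shape (..., 2)."""
    eta = alpha + beta * np.asarray(t, dtype=float)
    p1 = expit(eta)
    return np.log(np.stack([1 - p1, p1], axis=-1))


def _ternary_logp(beta: float, c1: float, c2: float, t: np.ndarray) -> np.ndarray:
    """log P(response | template) for responses (−1, 0, 1); shape (..., 3)."""
    eta = beta * np.asarray(t, dtype=float)
    q1 = expit(c1 - eta)          # P(y = minimal)
    q2 = expit(c2 - eta)          # P(y <= intermediate)
    probs = np.stack([q1, q2 - q1, 1 - q2], axis=-1)
    return np.log(np.clip(probs, 1e-300, None))


def observation_loglik(
    response: int,
    condition: str,
    group: Group,
    params: ModelParams,
    paradigm: str,
) -> float:
    """Log-probability of one response under one group's template."""
    template = derive_template(group, paradigm)
    t = template[condition]
    options = PARADIGM_RESPONSES[paradigm]
    if response not in options:
        raise ValueError(f"response {response} not valid for the {paradigm} paradigm")
    idx = options.index(response)
    if paradigm == "binary":
        return float(_binary_logp(params.alpha, params.beta, np.array(t))[idx])
    return float(_ternary_logp(params.beta, params.c1, params.c2, np.array(t))[idx])


def mixture_loglik(
    records: pd.DataFrame,
    groups: Sequence[str],
    params: ModelParams,
    paradigm: str,
    weights: Sequence[float] | None = None,
) -> float:
    """Marginal log-likelihood of the records at fixed continuous parameters:
    the per-subject latent group is summed out (mixing weights uniform unless
    given), and subjects are independent."""
    if weights is None:
        weights = np.full(len(groups), 1.0 / len(groups))
    log_pi = np.log(np.asarray(weights, dtype=float))
    total = 0.0
    for _, sub in records.groupby("subject_id"):
        per_group = np.array(
            [
                sum(
                    observation_loglik(int(r), c, Group.from_label(g), params, paradigm)
                    for r, c in zip(sub["response"], sub["condition"])
                )
                for g in groups
            ]
        )
        total += float(logsumexp(per_group + log_pi))
    return total


# ---------------------------------------------------------------------------
# Named analysis presets
# ---------------------------------------------------------------------------

THE_CONDITIONS = (
    "the-gap-pos",
    "the-gap-neg",
    "the-all-pos",
    "the-all-neg",
    "the-none-pos",
    "the-none-neg",
)


def analysis_conditions(preset: str) -> tuple[str, ...]:
    """Condition subsets for the shipped ternary analyses: ``analysis1`` and
    ``analysis2`` use the definite conditions plus the implicature-relevant
    some-all-pos; ``analysis3`` adds all-gap-pos to separate the partial-truth
    group from the homogeneous one."""
    if preset in ("analysis1", "analysis2"):
        return THE_CONDITIONS + ("some-all-pos",)
    if preset == "analysis3":
        return THE_CONDITIONS + ("some-all-pos", "all-gap-pos")
    raise ValueError(f"unknown preset: {preset!r}")


def exp2_inventories(preset: str = "analysis1") -> dict[str, list[str]]:
    """Group inventories explored by the ternary analyses.

    All inventories contain exi/−si; the exi/+si group is never included
    (following the near-absence of that pattern in the binary experiment).
    ``analysis1``/``analysis3`` admit hom/+si as the only +si group and
    explore the non-empty combinations of hom/−si, ws/−si and sa/−si
    (``analysis3`` adds pt/−si to each); ``analysis2`` also includes sa/+si
    and ws/+si throughout.
    """
    base = ["exi/-si", "hom/+si"]
    extras = {"hom": "hom/-si", "ws": "ws/-si", "sa": "sa/-si"}
    combos = [
        ("hom", "ws"),
        ("hom", "sa"),
        ("hom", "ws", "sa"),
        ("hom",),
        ("ws",),
        ("ws", "sa"),
        ("sa",),
    ]
    out: dict[str, list[str]] = {}
    for combo in combos:
        name = "+".join(combo)
        groups = base + [extras[c] for c in combo]
        if preset == "analysis2":
            groups = groups + ["sa/+si", "ws/+si"]
        if preset == "analysis3":
            groups = groups + ["pt/-si"]
        out[name] = groups
    return out


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class LatentGroupMixture(BaseEstimator):
    """Finite-mixture response model with a per-subject latent group.

    Parameters
    ----------
    paradigm : "binary" or "ternary".
    groups : group labels admitted by the model (default: the canonical
        inventory of the paradigm).
    conditions : condition labels entering the likelihood (default: the full
        design of the paradigm).
    backend : "grid" for deterministic quadrature over the continuous
        parameters (mixing weights fixed uniform), "mcmc" for the emcee
        ensemble sampler with a flat Dirichlet prior on the weights.
    alpha_scale, beta_scale, cut_scale : scales of the zero-centred normal /
        half-normal priors on intercept, slope and cutpoints.
    grid_size : number of quadrature nodes per parameter axis.
    n_walkers, n_steps, n_burn : emcee settings.
    random_state : seed for the sampler.

    Attributes
    ----------
    groups_, conditions_ : resolved inventories.
    subjects_ : subject identifiers in fit order.
    group_probs_ : DataFrame (subjects x groups) of posterior group
        probabilities.
    pointwise_loglik_ : per-observation LOO log predictive densities.
    elpd_, elpd_se_ : leave-one-out expected log predictive density.
    params_mean_ : posterior means of the continuous parameters.
    diagnostics_ : dict with sampler / importance-weight diagnostics.
    """

    def __init__(
        self,
        paradigm: str = "binary",
        groups: Sequence[str] | None = None,
        conditions: Sequence[str] | None = None,
        backend: str = "grid",
        alpha_scale: float = 2.5,
        beta_scale: float = 4.0,
        cut_scale: float = 3.0,
        grid_size: int = 13,
        n_walkers: int = 24,
        n_steps: int = 700,
        n_burn: int = 300,
        random_state: int = 0,
    ):
        self.paradigm = paradigm
        self.groups = groups
        self.conditions = conditions
        self.backend = backend
        self.alpha_scale = alpha_scale
        self.beta_scale = beta_scale
        self.cut_scale = cut_scale
        self.grid_size = grid_size
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.random_state = random_state

    # -- data plumbing ------------------------------------------------------

    def _resolve(self) -> None:
        if self.paradigm not in ("binary", "ternary"):
            raise ValueError(f"unknown paradigm: {self.paradigm!r}")
        default_groups = [g.label for g in PARADIGM_GROUPS[self.paradigm]]
        self.groups_ = list(self.groups) if self.groups is not None else default_groups
        if not self.groups_:
            raise ValueError("the group inventory must be non-empty")
        design = [c.label for c in PARADIGM_CONDITIONS[self.paradigm]]
        self.conditions_ = (
            list(self.conditions) if self.conditions is not None else design
        )
        unknown = set(self.conditions_) - set(design)
        if unknown:
            raise ValueError(f"conditions outside the {self.paradigm} design: {sorted(unknown)}")
        self.template_ = np.array(
            [
                [derive_template(Group.from_label(g), self.paradigm)[c] for c in self.conditions_]
                for g in self.groups_
            ]
        )

    def _encode(self, records: pd.DataFrame):
        sub = records[records["condition"].isin(self.conditions_)]
        missing = set(self.conditions_) - set(sub["condition"])
        if missing:
            raise ValueError(f"conditions never observed in the data: {sorted(missing)}")
        subjects = list(dict.fromkeys(sub["subject_id"]))
        s_idx = sub["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        c_idx = sub["condition"].map({c: i for i, c in enumerate(self.conditions_)}).to_numpy()
        options = PARADIGM_RESPONSES[self.paradigm]
        if not sub["response"].isin(options).all():
            bad = sorted(set(sub["response"]) - set(options))
            raise ValueError(f"responses outside the {self.paradigm} range: {bad}")
        r_idx = sub["response"].map({r: i for i, r in enumerate(options)}).to_numpy()
        return subjects, s_idx, c_idx, r_idx

    # -- posterior points ---------------------------------------------------

    def _grid_points(self):
        """Quadrature nodes (list of ModelParams-like tuples) and prior log
        weights."""
        m = self.grid_size
        if self.paradigm == "binary":
            alphas = np.linspace(-4.0, 4.0, m)
            betas = np.linspace(0.25, 2.5 * self.beta_scale, m)
            aa, bb = np.meshgrid(alphas, betas, indexing="ij")
            theta = np.column_stack([aa.ravel(), bb.ravel()])
            logw = stats.norm.logpdf(theta[:, 0], 0, self.alpha_scale) + stats.halfnorm.logpdf(
                theta[:, 1], 0, self.beta_scale
            )
            return theta, logw
        k = max(5, m // 2 + 1)
        c1s = np.linspace(-2.5 * self.cut_scale, -0.25, k)
        c2s = np.linspace(0.25, 2.5 * self.cut_scale, k)
        betas = np.linspace(0.25, 2.5 * self.beta_scale, k)
        g1, g2, gb = np.meshgrid(c1s, c2s, betas, indexing="ij")
        theta = np.column_stack([g1.ravel(), g2.ravel(), gb.ravel()])
        logw = (
            stats.norm.logpdf(theta[:, 0], 0, self.cut_scale)
            + stats.norm.logpdf(theta[:, 1], 0, self.cut_scale)
            + stats.halfnorm.logpdf(theta[:, 2], 0, self.beta_scale)
        )
        return theta, logw

    def _logp_tables(self, theta: np.ndarray) -> np.ndarray:
        """log P(response | group, condition) per posterior point:
        shape (n_points, n_groups, n_conditions, n_responses)."""
        t = self.template_.astype(float)  # (G, C)
        if self.paradigm == "binary":
            return np.stack([_binary_logp(a, b, t) for a, b in theta[:, :2]])
        return np.stack([_ternary_logp(b, c1, c2, t) for c1, c2, b in theta[:, :3]])

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "LatentGroupMixture":
        self._resolve()
        subjects, s_idx, c_idx, r_idx = self._encode(X)
        self.subjects_ = subjects
        S, G = len(subjects), len(self.groups_)
        n_obs = len(s_idx)

        if self.backend == "grid":
            theta, logw0 = self._grid_points()
            log_pi = np.full(G, -np.log(G))  # uniform mixing weights
            pi_draws = None
        elif self.backend == "mcmc":
            theta, log_pi_draws = self._run_mcmc(subjects, s_idx, c_idx, r_idx)
            logw0 = np.zeros(len(theta))  # equally weighted posterior draws
            pi_draws = log_pi_draws
        else:
            raise ValueError(f"unknown backend: {self.backend!r}")

        logp = self._logp_tables(theta)  # (P, G, C, R)
        P = len(theta)
        # per-observation log-prob under each (point, group): (P, G, n_obs)
        obs_lp = logp[:, :, c_idx, r_idx]
        # subject-group log-likelihoods: (P, G, S)
        ll = np.zeros((P, G, S))
        np.add.at(ll.transpose(2, 0, 1), s_idx, obs_lp.transpose(2, 0, 1))

        if pi_draws is None:
            prior_mix = log_pi[None, :, None]  # (1, G, 1)
        else:
            prior_mix = pi_draws[:, :, None]   # (P, G, 1)
        joint = ll + prior_mix                      # (P, G, S)
        subj_marg = logsumexp(joint, axis=1)        # (P, S)

        if self.backend == "grid":
            log_post = logw0 + subj_marg.sum(axis=1)
            log_post -= logsumexp(log_post)
        else:
            log_post = np.full(P, -np.log(P))
        self._theta_, self._log_post_, self._log_pi_ = theta, log_post, (
            pi_draws if pi_draws is not None else np.tile(log_pi, (P, 1))
        )

        # posterior group probabilities, averaged over the theta posterior
        cond_group = joint - subj_marg[:, None, :]          # log p(g | y_s, theta)
        probs = np.einsum("p,pgs->sg", np.exp(log_post), np.exp(cond_group))
        probs /= probs.sum(axis=1, keepdims=True)
        self.group_probs_ = pd.DataFrame(probs, index=subjects, columns=self.groups_)

        # conditional pointwise predictive: log p(y_i | y_{s,-i}, theta)
        drop = logsumexp(joint[:, :, s_idx] - obs_lp, axis=1)   # (P, n_obs)
        log_f = subj_marg[:, s_idx] - drop
        self._log_f_ = log_f

        if self.backend == "grid":
            # exact importance-sampling LOO on the quadrature posterior
            loo_i = -(logsumexp(log_post[:, None] - log_f, axis=0))
            self.diagnostics_ = {"backend": "grid", "n_points": P}
        else:
            loo_i, khat = _psis_loo(log_f)
            self.diagnostics_ = {
                "backend": "mcmc",
                "n_draws": P,
                "pareto_k_max": float(np.max(khat)),
                "pareto_k_above_0.7": int(np.sum(khat > 0.7)),
                "acceptance_fraction": getattr(self, "_accept_frac_", np.nan),
            }
            if np.max(khat) > 0.7:
                import warnings

                warnings.warn(
                    f"PSIS-LOO importance weights unreliable for "
                    f"{int(np.sum(khat > 0.7))} observations (max k-hat "
                    f"{np.max(khat):.2f})",
                    stacklevel=2,
                )
        self.pointwise_loglik_ = loo_i
        self.elpd_ = float(loo_i.sum())
        self.elpd_se_ = float(np.sqrt(len(loo_i) * np.var(loo_i, ddof=1)))
        self._obs_index_ = (s_idx, c_idx, r_idx)
        self.params_mean_ = self._posterior_means()
        return self

    def _posterior_means(self) -> dict[str, float]:
        w = np.exp(self._log_post_)
        theta = self._theta_
        if self.paradigm == "binary":
            return {
                "alpha": float(w @ theta[:, 0]),
                "beta": float(w @ theta[:, 1]),
            }
        return {
            "c1": float(w @ theta[:, 0]),
            "c2": float(w @ theta[:, 1]),
            "beta": float(w @ theta[:, 2]),
        }

    # -- MCMC backend -------------------------------------------------------

    def _log_prior(self, x: np.ndarray) -> float:
        G = len(self.groups_)
        if self.paradigm == "binary":
            alpha, log_beta = x[0], x[1]
            z = x[2 : 2 + G - 1]
            lp = stats.norm.logpdf(alpha, 0, self.alpha_scale)
            beta = np.exp(log_beta)
            lp += stats.halfnorm.logpdf(beta, 0, self.beta_scale) + log_beta
        else:
            c1, log_gap, log_beta = x[0], x[1], x[2]
            z = x[3 : 3 + G - 1]
            gap, beta = np.exp(log_gap), np.exp(log_beta)
            lp = stats.norm.logpdf(c1, 0, self.cut_scale)
            lp += stats.norm.logpdf(c1 + gap, 0, self.cut_scale) + log_gap
            lp += stats.halfnorm.logpdf(beta, 0, self.beta_scale) + log_beta
        # flat Dirichlet on pi via softmax transform; Jacobian = prod(pi)
        log_pi = _softmax_log(z)
        lp += log_pi.sum()
        return float(lp)

    def _unpack(self, x: np.ndarray):
        G = len(self.groups_)
        if self.paradigm == "binary":
            theta = np.array([x[0], np.exp(x[1])])
            z = x[2 : 2 + G - 1]
        else:
            theta = np.array([x[0], x[0] + np.exp(x[1]), np.exp(x[2])])
            z = x[3 : 3 + G - 1]
        return theta, _softmax_log(z)

    def _run_mcmc(self, subjects, s_idx, c_idx, r_idx):
        import emcee

        G = len(self.groups_)
        S = len(subjects)
        n_cont = 2 if self.paradigm == "binary" else 3
        ndim = n_cont + G - 1

        def log_prob(x: np.ndarray) -> float:
            theta, log_pi = self._unpack(x)
            lp = self._log_prior(x)
            if not np.isfinite(lp):
                return -np.inf
            logp = self._logp_tables(theta[None, :])[0]       # (G, C, R)
            obs_lp = logp[:, c_idx, r_idx]                    # (G, n_obs)
            ll = np.zeros((G, S))
            np.add.at(ll.T, s_idx, obs_lp.T)
            return lp + float(logsumexp(ll + log_pi[:, None], axis=0).sum())

        rng = np.random.default_rng(self.random_state)
        x0 = rng.normal(0, 0.5, size=(self.n_walkers, ndim))
        if self.paradigm == "ternary":
            x0[:, 0] -= 1.0  # start c1 below zero
        sampler = emcee.EnsembleSampler(self.n_walkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState(self.random_state).get_state()
        sampler.run_mcmc(x0, self.n_steps, progress=False)
        self._accept_frac_ = float(np.mean(sampler.acceptance_fraction))
        chain = sampler.get_chain(discard=self.n_burn, thin=2, flat=True)
        if len(chain) > 600:
            keep = np.linspace(0, len(chain) - 1, 600).astype(int)
            chain = chain[keep]
        thetas, log_pis = zip(*(self._unpack(x) for x in chain))
        return np.array(thetas), np.array(log_pis)

    # -- downstream API -----------------------------------------------------

    def predict_proba(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Posterior group probabilities; for new records, computed under the
        fitted posterior over the continuous parameters."""
        if X is None:
            return self.group_probs_
        subjects, s_idx, c_idx, r_idx = self._encode(X)
        logp = self._logp_tables(self._theta_)
        obs_lp = logp[:, :, c_idx, r_idx]
        ll = np.zeros((len(self._theta_), len(self.groups_), len(subjects)))
        np.add.at(ll.transpose(2, 0, 1), s_idx, obs_lp.transpose(2, 0, 1))
        joint = ll + self._log_pi_[:, :, None]
        cond = joint - logsumexp(joint, axis=1)[:, None, :]
        probs = np.einsum("p,pgs->sg", np.exp(self._log_post_), np.exp(cond))
        probs /= probs.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, index=subjects, columns=self.groups_)

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        """Maximum-posterior group per subject (ties break to the lowest
        inventory index)."""
        probs = self.predict_proba(X)
        order = {g: i for i, g in enumerate(self.groups_)}
        cols = sorted(probs.columns, key=order.get)
        return probs[cols].idxmax(axis=1).rename("group")

    def score(self, X: pd.DataFrame | None = None, y=None) -> float:
        return self.elpd_


def _softmax_log(z: np.ndarray) -> np.ndarray:
    """log of softmax([z, 0]) — the mixing weights on the simplex."""
    full = np.concatenate([z, [0.0]])
    return full - logsumexp(full)


def _psis_loo(log_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PSIS-smoothed importance-sampling LOO over MCMC draws.

    ``log_f`` has shape (n_draws, n_obs); raw log weights are ``-log_f``.
    """
    import arviz as az

    # psislw smooths along the last axis (draws): pass (n_obs, n_draws)
    lw, khat = az.psislw(-log_f.T.copy())
    loo_i = logsumexp(np.asarray(lw) + log_f.T, axis=1)
    return loo_i, np.asarray(khat)


# ---------------------------------------------------------------------------
# Assignment tables, LOO oracles, inventory comparison
# ---------------------------------------------------------------------------

def assign_groups(model: LatentGroupMixture) -> pd.DataFrame:
    """Per-subject argmax assignment with its posterior probability and a
    flag for exact ties."""
    probs = model.group_probs_
    best = model.predict()
    max_p = probs.max(axis=1)
    ties = (probs.values == max_p.values[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {"group": best, "posterior_probability": max_p, "tie": ties}
    )


def assignment_counts(model: LatentGroupMixture) -> pd.DataFrame:
    """Count table of argmax assignments, rows = reading, columns = ±si."""
    assignment = assign_groups(model)
    parsed = assignment["group"].map(Group.from_label)
    frame = pd.DataFrame(
        {
            "reading": [g.reading.value for g in parsed],
            "si": ["+si" if g.si else "-si" for g in parsed],
        }
    )
    readings = list(dict.fromkeys(Group.from_label(g).reading.value for g in model.groups_))
    table = pd.crosstab(frame["reading"], frame["si"])
    for col in ("-si", "+si"):
        if col not in table.columns:
            table[col] = 0
    return table.reindex([r for r in readings if r in table.index])[["-si", "+si"]]


def loo_elpd(model: LatentGroupMixture) -> tuple[float, float]:
    return model.elpd_, model.elpd_se_


def exact_loo(model: LatentGroupMixture, X: pd.DataFrame) -> np.ndarray:
    """Oracle LOO: refit the (grid) posterior once per left-out observation
    and evaluate its exact posterior predictive density.  Feasible only at
    desk scale; used to validate the importance-sampling shortcut."""
    if model.backend != "grid":
        raise ValueError("the exact-LOO oracle is defined for the grid backend")
    fitted = LatentGroupMixture(**model.get_params()).fit(X)
    s_idx, c_idx, r_idx = fitted._obs_index_
    theta, logw0 = fitted._grid_points()
    logp = fitted._logp_tables(theta)
    G = len(fitted.groups_)
    log_pi = np.full(G, -np.log(G))
    obs_lp = logp[:, :, c_idx, r_idx]
    S = len(fitted.subjects_)
    ll = np.zeros((len(theta), G, S))
    np.add.at(ll.transpose(2, 0, 1), s_idx, obs_lp.transpose(2, 0, 1))
    out = np.empty(len(s_idx))
    for i in range(len(s_idx)):
        ll_i = ll.copy()
        ll_i[:, :, s_idx[i]] -= obs_lp[:, :, i]
        subj_marg = logsumexp(ll_i + log_pi[None, :, None], axis=1)
        log_post = logw0 + subj_marg.sum(axis=1)
        log_post -= logsumexp(log_post)
        # predictive of the left-out obs given the subject's remaining data
        joint = ll_i[:, :, s_idx[i]] + log_pi[None, :]
        cond = joint - logsumexp(joint, axis=1)[:, None]
        pred = logsumexp(cond + obs_lp[:, :, i], axis=1)
        out[i] = logsumexp(log_post + pred)
    return out


def compare_inventories(
    records: pd.DataFrame,
    inventories: Mapping[str, Sequence[str]],
    **model_kwargs,
) -> pd.DataFrame:
    """Fit one mixture per group inventory on the same records and compare by
    LOO elpd.  Returns a table with elpd, its SE, the difference to the best
    inventory and the *paired* SE of that difference (pointwise)."""
    fits: dict[str, LatentGroupMixture] = {}
    for name, groups in inventories.items():
        fits[name] = LatentGroupMixture(groups=list(groups), **model_kwargs).fit(records)
    n_points = {len(f.pointwise_loglik_) for f in fits.values()}
    if len(n_points) != 1:
        raise ValueError("inventories were fitted on mismatched observations")
    best = max(fits, key=lambda k: fits[k].elpd_)
    rows = []
    for name, fit in sorted(fits.items(), key=lambda kv: -kv[1].elpd_):
        diff = fit.pointwise_loglik_ - fits[best].pointwise_loglik_
        rows.append(
            {
                "inventory": name,
                "groups": ",".join(fit.groups_),
                "elpd": fit.elpd_,
                "se": fit.elpd_se_,
                "delta_elpd": float(diff.sum()),
                "delta_se": float(np.sqrt(len(diff) * np.var(diff, ddof=1))),
            }
        )
    out = pd.DataFrame(rows).set_index("inventory")
    out.attrs["fits"] = fits
    return out
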