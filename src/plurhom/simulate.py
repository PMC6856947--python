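"""Synthetic truth-value-judgment cohorts with known latent groups.

Generates trial lists replicating the two experimental designs (24 binary
trials; 26 ternary trials), samples subjects from a mixture of interpretive
groups, and produces template-driven responses corrupted by a symmetric lapse
rate: with probability ``1 − ε`` a subject answers according to its group's
template, with probability ``ε`` the response is replaced by a uniform draw
over the *other* response option(s).

The experimenter-driven "dynamic" selection of definite-control targets is
replaced by a balanced randomized assignment (half clearly true, half clearly
false), which preserves the anti-bias purpose of the original policy while
keeping the generator independent of the simulated answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import (
    DEFINITE_CONTROLS,
    EXPERIMENT_PARADIGM,
    EXPERIMENT_TRIAL_COUNTS,
    PARADIGM_CONDITIONS,
    PARADIGM_RESPONSES,
    Condition,
)
from .semantics import Group, PARADIGM_GROUPS, derive_template

RECORD_COLUMNS = [
    "subject_id",
    "age_group",
    "paradigm",
    "trial_index",
    "condition",
    "response",
    "true_group",
]

# Independent sub-streams of the master seed, so that e.g. changing the number
# of subjects never perturbs the trial list.
_STREAM_TRIALS, _STREAM_GROUPS, _STREAM_LAPSES = 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    experiment: str = "EXP1"            # EXP1 (binary) or EXP2 (ternary)
    n_subjects: int = 24
    group_weights: Mapping[str, float] = field(
        default_factory=lambda: {"hom/-si": 0.25, "hom/+si": 0.42, "exi/-si": 0.29, "exi/+si": 0.04}
    )
    lapse_rate: float = 0.05
    domain_size: int = 4
    seed: int = 0
    age_group: str = "child"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_PARADIGM:
            raise ValueError(f"unknown experiment: {self.experiment!r}")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        total = sum(self.group_weights.values())
        if self.group_weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_weights must sum to 1, got {total}")
        admissible = {g.label for g in PARADIGM_GROUPS[self.paradigm]}
        bad = set(self.group_weights) - admissible
        if bad:
            raise ValueError(
                f"groups {sorted(bad)} are not admissible in the {self.paradigm} paradigm"
            )

    @property
    def paradigm(self) -> str:
        return EXPERIMENT_PARADIGM[self.experiment]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


def build_trial_list(
    experiment: str,
    seed: int = 0,
    trial_counts: Mapping[Condition, int] | None = None,
) -> pd.DataFrame:
    """Pseudorandom trial order with every third trial a definite control.

    Returns a frame with columns ``trial_index`` (1-based) and ``condition``.
    Control trials are balanced between clearly-true and clearly-false targets.
    """
    counts = dict(trial_counts or EXPERIMENT_TRIAL_COUNTS[experiment])
    rng = _rng(seed, _STREAM_TRIALS)
    controls = [c.label for c in DEFINITE_CONTROLS for _ in range(counts.get(c, 0))]
    targets = [
        c.label for c, m in counts.items() if c not in DEFINITE_CONTROLS for _ in range(m)
    ]
    rng.shuffle(controls)
    rng.shuffle(targets)
    n_total = len(controls) + len(targets)
    control_positions = list(range(2, n_total, 3))[: len(controls)]  # trials 3, 6, ...
    ordered: list[str | None] = [None] * n_total
    for pos, ctrl in zip(control_positions, controls):
        ordered[pos] = ctrl
    tgt_iter = iter(targets)
    ctrl_iter = iter(controls[len(control_positions):])
    for pos in range(n_total):
        if ordered[pos] is None:
            ordered[pos] = next(tgt_iter, None) or next(ctrl_iter)
    return pd.DataFrame(
        {"trial_index": np.arange(1, n_total + 1), "condition": ordered}
    )


def sample_population(config: SimulationConfig) -> pd.DataFrame:
    """Draw subjects with latent groups from the configured mixture."""
    labels = sorted(config.group_weights)
    probs = np.array([config.group_weights[g] for g in labels], dtype=float)
    rng = _rng(config.seed, _STREAM_GROUPS)
    if config.n_subjects == 0:
        return pd.DataFrame(columns=["subject_id", "age_group", "true_group"])
    draws = rng.choice(len(labels), size=config.n_subjects, p=probs)
    width = max(3, len(str(config.n_subjects)))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)],
            "age_group": config.age_group,
            "true_group": [labels[i] for i in draws],
        }
    )


def simulate_responses(
    subjects: pd.DataFrame,
    trials: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Template responses with lapse noise, one row per subject x trial."""
    paradigm = config.paradigm
    options = np.array(PARADIGM_RESPONSES[paradigm])
    group_labels = sorted(set(subjects["true_group"]))
    cond_labels = [c.label for c in PARADIGM_CONDITIONS[paradigm]]
    cond_index = {c: i for i, c in enumerate(cond_labels)}

    template = np.empty((len(group_labels), len(cond_labels)), dtype=int)
    for gi, glabel in enumerate(group_labels):
        tpl = derive_template(Group.from_label(glabel), paradigm, config.domain_size)
        for ci, clabel in enumerate(cond_labels):
            template[gi, ci] = tpl[clabel]

    n_subj, n_trials = len(subjects), len(trials)
    gidx = subjects["true_group"].map({g: i for i, g in enumerate(group_labels)}).to_numpy()
    cidx = trials["condition"].map(cond_index).to_numpy()
    if np.any(pd.isna(cidx)):
        bad = trials.loc[pd.isna(trials["condition"].map(cond_index)), "condition"].unique()
        raise ValueError(f"conditions not in the {paradigm} design: {sorted(bad)}")

    resp = template[np.repeat(gidx, n_trials), np.tile(cidx, n_subj)].astype(int)
    rng = _rng(config.seed, _STREAM_LAPSES)
    lapse = rng.random(resp.shape) < config.lapse_rate
    if lapse.any():
        # replace each lapsed response by a uniform draw over the other options
        other = np.array([[o for o in options if o != t] for t in options])
        rows = np.searchsorted(options, resp[lapse])
        picks = rng.integers(0, len(options) - 1, size=rows.size)
        resp[lapse] = other[rows, picks]

    return pd.DataFrame(
        {
            "subject_id": np.repeat(subjects["subject_id"].to_numpy(), n_trials),
            "age_group": np.repeat(subjects["age_group"].to_numpy(), n_trials),
            "paradigm": paradigm,
            "trial_index": np.tile(trials["trial_index"].to_numpy(), n_subj),
            "condition": np.tile(trials["condition"].to_numpy(), n_subj),
            "response": resp,
            "true_group": np.repeat(subjects["true_group"].to_numpy(), n_trials),
        }
    )


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Trial list + population + responses in one call."""
    trials = build_trial_list(config.experiment, config.seed)
    subjects = sample_population(config)
    if subjects.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return simulate_responses(subjects, trials, config)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, dtype={"subject_id": str, "condition": str})
    missing = [c for c in RECORD_COLUMNS if c not in records.columns and c != "true_group"]
    if missing:
        raise ValueError(f"response CSV is missing columns: {missing}")
    records["response"] = records["response"].astype(int)
    records["trial_index"] = records["trial_index"].astype(int)
    return records
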