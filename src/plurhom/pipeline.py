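"""End-to-end orchestration: simulate or load a cohort, run inclusion,
categorization, enumeration, mixture fitting and inventory comparison, and
write every report table with a manifest and log."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import (
    chi_square_2xk,
    group_counts,
    summarize_subjects,
)
from .conditions import (
    EXPERIMENT_PARADIGM,
    EXPERIMENT_TRIAL_COUNTS,
    PARADIGM_CONDITIONS,
    PARADIGM_RESPONSES,
)
from .enumeration import tail_table
from .mixture import (
    LatentGroupMixture,
    analysis_conditions,
    assignment_counts,
    compare_inventories,
    exp2_inventories,
)
from .simulate import RECORD_COLUMNS, SimulationConfig, read_records, simulate_cohort

logger = logging.getLogger("plurhom")


class InputValidationError(ValueError):
    """Raised with a structured list of violations in ``.violations``."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid response data:\n" + "\n".join(violations))


def validate_input(path: str | Path, experiment: str) -> pd.DataFrame:
    """Load a long-format response CSV and verify the column set, condition
    vocabulary, response range and per-subject trial counts."""
    records = read_records(path)
    paradigm = EXPERIMENT_PARADIGM[experiment]
    violations: list[str] = []
    labels = {c.label for c in PARADIGM_CONDITIONS[paradigm]}
    bad_conditions = sorted(set(records["condition"]) - labels)
    for lbl in bad_conditions:
        violations.append(f"unknown condition label: {lbl!r}")
    options = set(PARADIGM_RESPONSES[paradigm])
    bad_resp = sorted(set(records["response"]) - options)
    for r in bad_resp:
        violations.append(f"response {r} outside the {paradigm} range {sorted(options)}")
    counts = records.groupby("subject_id").size()
    expected = sum(EXPERIMENT_TRIAL_COUNTS[experiment].values())
    for sid, n in counts.items():
        if n != expected:
            violations.append(f"subject {sid}: {n} trials, expected {expected}")
    if violations:
        raise InputValidationError(violations)
    return records


@dataclass
class PipelineConfig:
    experiment: str = "EXP1"
    simulation: SimulationConfig | None = None
    input_path: str | None = None
    output_dir: str = "plurhom_report"
    seed: int = 0
    backend: str = "grid"
    analyses: list[str] = field(default_factory=list)  # EXP2 presets to run

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ValueError("exactly one of simulation / input_path must be given")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if data.get("simulation") is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        return cls(**data)


def demo_config(output_dir: str = "plurhom_report", seed: int = 1) -> PipelineConfig:
    """Bundled demonstration: a noiseless binary cohort whose composition
    mirrors the canonical child groupings (6 hom/−si, 10 hom/+si, 7 exi/−si,
    1 exi/+si)."""
    sim = SimulationConfig(
        experiment="EXP1",
        n_subjects=24,
        group_weights={"hom/-si": 0.25, "hom/+si": 10 / 24, "exi/-si": 7 / 24, "exi/+si": 1 / 24},
        lapse_rate=0.0,
        seed=seed,
    )
    return PipelineConfig(experiment="EXP1", simulation=sim, output_dir=output_dir, seed=seed)


def _chi_square_report(summary: pd.DataFrame) -> pd.DataFrame | None:
    """Adults-versus-children chi-square over homogeneity categories, when
    both age groups are present; empty categories are dropped first (a zero
    column would make the statistic undefined)."""
    kept = summary[summary["inclusion"]]
    if kept["age_group"].nunique() < 2:
        return None
    table = pd.crosstab(kept["age_group"], kept["homogeneity_category"])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return None
    stat, df = chi_square_2xk(table.to_numpy())
    return pd.DataFrame(
        {"statistic": [stat], "df": [df], "n": [int(table.to_numpy().sum())]}
    )


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle; returns the tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    tables: dict[str, pd.DataFrame] = {}
    try:
        paradigm = EXPERIMENT_PARADIGM[config.experiment]
        if config.simulation is not None:
            logger.info("simulating cohort: %s", asdict(config.simulation))
            records = simulate_cohort(config.simulation)
        else:
            logger.info("loading records from %s", config.input_path)
            records = validate_input(config.input_path, config.experiment)
        tables["records"] = records

        summary = summarize_subjects(records)
        tables["subject_summaries"] = summary.reset_index()
        tables["group_counts"] = group_counts(summary).reset_index()
        chi = _chi_square_report(summary)
        if chi is not None:
            tables["chi_square"] = chi

        tables["enumeration_scenario_a"] = tail_table("A", range(6, 14))
        tables["enumeration_scenario_b"] = tail_table("B", range(6, 25))

        included = summary.index[summary["inclusion"]]
        fit_records = records[records["subject_id"].isin(included)]
        if paradigm == "binary":
            inventories = {
                "all": ["exi/+si", "exi/-si", "hom/+si", "hom/-si", "uni/+si", "uni/-si"],
                "no_exi+si": ["exi/-si", "hom/+si", "hom/-si", "uni/+si", "uni/-si"],
                "no_hom-si": ["exi/+si", "exi/-si", "hom/+si", "uni/+si", "uni/-si"],
                "no_exi+si_no_hom-si": ["exi/-si", "hom/+si", "uni/+si", "uni/-si"],
            }
            model = LatentGroupMixture(
                paradigm=paradigm,
                groups=inventories["all"],
                backend=config.backend,
                random_state=config.seed,
            ).fit(fit_records)
            tables["assignment_counts"] = assignment_counts(model).reset_index()
            tables["group_probabilities"] = model.group_probs_.reset_index(names="subject_id")
            comparison = compare_inventories(
                fit_records,
                inventories,
                paradigm=paradigm,
                backend=config.backend,
                random_state=config.seed,
            )
            tables["inventory_comparison"] = comparison.reset_index()
        else:
            presets = config.analyses or ["analysis1"]
            for preset in presets:
                conditions = list(analysis_conditions(preset))
                inventories = exp2_inventories(preset)
                comparison = compare_inventories(
                    fit_records,
                    inventories,
                    paradigm=paradigm,
                    conditions=conditions,
                    backend=config.backend,
                    random_state=config.seed,
                )
                tables[f"inventory_comparison_{preset}"] = comparison.reset_index()
                best = comparison.index[0]
                model = comparison.attrs["fits"][best]
                tables[f"assignment_counts_{preset}"] = assignment_counts(model).reset_index()
                tables[f"group_probabilities_{preset}"] = model.group_probs_.reset_index(
                    names="subject_id"
                )

        # per-subject mean responses on the affirmative homogeneity and
        # implicature targets (scatter coordinates)
        scatter = (
            records[records["condition"].isin(["the-gap-pos", "some-all-pos"])]
            .groupby(["subject_id", "condition"])["response"]
            .mean()
            .unstack()
            .rename(
                columns={
                    "the-gap-pos": "mean_response_homogeneity_pos",
                    "some-all-pos": "mean_response_implicature",
                }
            )
            .reset_index()
        )
        tables["subject_means"] = scatter

        manifest = {
            "experiment": config.experiment,
            "seed": config.seed,
            "backend": config.backend,
            "simulation": asdict(config.simulation) if config.simulation else None,
            "input_path": config.input_path,
            "tables": {},
        }
        for name, frame in tables.items():
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            manifest["tables"][name] = path.name
            logger.info("wrote %s (%d rows)", path.name, len(frame))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return tables
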