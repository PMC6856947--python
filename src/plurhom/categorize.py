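"""Rule-based subject categorization, inclusion criteria and chi-square tests.

Implements the majority-response scheme used in both experiments: a subject is
kept if at least 6 of the 8 clearly-true/clearly-false definite controls are
answered correctly; homogeneity categories come from the majority response to
the three positive and three negative definite-in-gap targets; the
scalar-implicature category from the implicature targets (4 binary trials with
a 3/4 rule, 3 ternary trials with a 2/3 rule where "reject" is any
non-maximal reward); and the ternary paradigm additionally flags response
biases on the incomplete-description, partial-truth and scope-ambiguity
controls.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .conditions import (
    DEFINITE_CONTROLS,
    FALSE_CONTROLS,
    PARADIGM_RESPONSES,
    TRUE_CONTROLS,
)

HOMOGENEITY_CATEGORIES = (
    "homogeneous",
    "existential",
    "universal",
    "wide_scope_existential",
    "inconsistent",
)
SI_CATEGORIES = ("plus_si", "minus_si", "mixed")
BIAS_FLAGS = ("incomplete_description", "partial_truth", "scope_ambiguity")


def _counts(records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-subject response counts for one condition (columns = responses)."""
    sub = records[records["condition"] == condition]
    paradigm = records["paradigm"].iat[0]
    table = (
        sub.groupby(["subject_id", "response"]).size().unstack(fill_value=0)
    )
    for r in PARADIGM_RESPONSES[paradigm]:
        if r not in table.columns:
            table[r] = 0
    return table.reindex(sorted(records["subject_id"].unique()), fill_value=0)


def _require_trials(records: pd.DataFrame, condition: str, n: int) -> pd.DataFrame:
    table = _counts(records, condition)
    totals = table.sum(axis=1)
    bad = totals[totals != n]
    if len(bad):
        raise ValueError(
            f"expected {n} {condition} trials per subject; "
            f"subjects with other counts: {list(bad.index[:5])}"
        )
    return table


def apply_inclusion(records: pd.DataFrame, threshold: int = 6) -> pd.Index:
    """Subjects answering at least ``threshold`` of the 8 definite controls
    correctly (maximal response on clearly-true, minimal on clearly-false)."""
    paradigm = records["paradigm"].iat[0]
    lo, hi = min(PARADIGM_RESPONSES[paradigm]), max(PARADIGM_RESPONSES[paradigm])
    correct = None
    total = None
    for cond in DEFINITE_CONTROLS:
        table = _counts(records, cond.label)
        target = hi if cond in TRUE_CONTROLS else lo
        c = table[target]
        t = table.sum(axis=1)
        correct = c if correct is None else correct + c
        total = t if total is None else total + t
    bad = total[total != 8]
    if len(bad):
        raise ValueError(
            f"expected 8 definite-control trials per subject; "
            f"subjects with other counts: {list(bad.index[:5])}"
        )
    return correct[correct >= threshold].index


def categorize_homogeneity(records: pd.DataFrame, paradigm: str | None = None) -> pd.Series:
    """Majority-rule homogeneity category per subject.

    Binary (reject = 0, accept = 1); with three trials per polarity the four
    patterns partition every possible response profile:

    * homogeneous: reject >= 2/3 positive and >= 2/3 negative targets
    * existential: accept >= 2/3 positive, reject >= 2/3 negative
    * universal: reject >= 2/3 positive, accept >= 2/3 negative
    * wide_scope_existential: accept >= 2/3 of both

    Ternary (minimal/intermediate/maximal = −1/0/+1), more specific categories
    take precedence:

    * existential: maximal >= 2/3 positive and minimal >= 2/3 negative
    * universal: minimal >= 2/3 positive and maximal >= 2/3 negative
    * homogeneous: non-maximal >= 2/3 positive and non-maximal >= 2/3 negative
    * otherwise inconsistent
    """
    paradigm = paradigm or records["paradigm"].iat[0]
    pos = _require_trials(records, "the-gap-pos", 3)
    neg = _require_trials(records, "the-gap-neg", 3)

    if paradigm == "binary":
        rej_pos, rej_neg = pos[0] >= 2, neg[0] >= 2
        out = pd.Series("inconsistent", index=pos.index, name="homogeneity_category")
        out[rej_pos & rej_neg] = "homogeneous"
        out[~rej_pos & rej_neg] = "existential"
        out[rej_pos & ~rej_neg] = "universal"
        out[~rej_pos & ~rej_neg] = "wide_scope_existential"
        return out

    max_pos, max_neg = pos[1] >= 2, neg[1] >= 2
    min_pos, min_neg = pos[-1] >= 2, neg[-1] >= 2
    nonmax_pos = (pos[-1] + pos[0]) >= 2
    nonmax_neg = (neg[-1] + neg[0]) >= 2
    out = pd.Series("inconsistent", index=pos.index, name="homogeneity_category")
    out[nonmax_pos & nonmax_neg] = "homogeneous"
    out[min_pos & max_neg] = "universal"
    out[max_pos & min_neg] = "existential"
    return out


def categorize_implicature(records: pd.DataFrame, paradigm: str | None = None) -> pd.Series:
    """Scalar-implicature category from the some-all-pos trials.

    Binary: 4 trials, plus_si iff >= 3 rejections, minus_si iff >= 3
    acceptances, mixed otherwise.  Ternary: 3 trials with the majority rule,
    where any non-maximal reward counts as a rejection (implicature-driven).
    """
    paradigm = paradigm or records["paradigm"].iat[0]
    if paradigm == "binary":
        table = _require_trials(records, "some-all-pos", 4)
        rejections, acceptances, need = table[0], table[1], 3
    else:
        table = _require_trials(records, "some-all-pos", 3)
        rejections, acceptances, need = table[-1] + table[0], table[1], 2
    out = pd.Series("mixed", index=table.index, name="si_category")
    out[rejections >= need] = "plus_si"
    out[acceptances >= need] = "minus_si"
    return out


def flag_biases(records: pd.DataFrame) -> pd.DataFrame:
    """Ternary-only response-bias flags from the three control conditions:
    a bias against incomplete descriptions (maximal reward on fewer than 2/3
    some-gap-pos trials), in favor of partial truth (minimal reward on fewer
    than 2/3 all-gap-pos trials), or a scope-ambiguity effect (intermediate
    response on more than 1/3 all-gap-neg trials)."""
    if records["paradigm"].iat[0] != "ternary":
        raise ValueError("bias flags are defined only for the ternary paradigm")
    incomplete = _require_trials(records, "some-gap-pos", 3)
    partial = _require_trials(records, "all-gap-pos", 3)
    scope = _require_trials(records, "all-gap-neg", 3)
    return pd.DataFrame(
        {
            "incomplete_description": incomplete[1] < 2,
            "partial_truth": partial[-1] < 2,
            "scope_ambiguity": scope[0] > 1,
        }
    )


def summarize_subjects(records: pd.DataFrame, inclusion_threshold: int = 6) -> pd.DataFrame:
    """Per-subject summary: inclusion, homogeneity and implicature category,
    bias flags (ternary), and the true group when the data are simulated."""
    paradigm = records["paradigm"].iat[0]
    kept = apply_inclusion(records, inclusion_threshold)
    summary = pd.DataFrame(
        {
            "inclusion": pd.Series(True, index=kept).reindex(
                sorted(records["subject_id"].unique()), fill_value=False
            )
        }
    )
    summary.index.name = "subject_id"
    summary["homogeneity_category"] = categorize_homogeneity(records, paradigm)
    summary["si_category"] = categorize_implicature(records, paradigm)
    if paradigm == "ternary":
        summary = summary.join(flag_biases(records))
    meta = records.drop_duplicates("subject_id").set_index("subject_id")
    summary["age_group"] = meta["age_group"]
    if "true_group" in meta.columns:
        summary["true_group"] = meta["true_group"]
    return summary


def group_counts(summary: pd.DataFrame, included_only: bool = True) -> pd.DataFrame:
    """Count table shaped like the descriptive report tables: rows are
    homogeneity categories, columns implicature categories."""
    data = summary[summary["inclusion"]] if included_only else summary
    table = pd.crosstab(data["homogeneity_category"], data["si_category"])
    rows = [c for c in HOMOGENEITY_CATEGORIES if c in table.index]
    cols = [c for c in ("minus_si", "plus_si", "mixed") if c in table.columns]
    return table.loc[rows, cols]


def chi_square_2xk(table: Iterable[Iterable[float]]) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom for a counts
    matrix, without continuity correction.  Errors on a zero expected cell."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must contain nonnegative integer counts")
    expected = stats.contingency.expected_freq(arr)
    zero = np.argwhere(expected == 0)
    if len(zero):
        r, c = zero[0]
        raise ValueError(f"zero expected count in cell (row {r}, column {c})")
    stat, _, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df)


class DescriptiveCategorizer(BaseEstimator):
    """Rule-based categorizer with the scikit-learn estimator surface.

    ``fit`` computes per-subject summaries from a long-format response frame;
    ``predict`` returns the homogeneity category for (new) records.

    Parameters
    ----------
    inclusion_threshold : minimum number of correct definite controls (of 8).
    """

    def __init__(self, inclusion_threshold: int = 6):
        self.inclusion_threshold = inclusion_threshold

    def fit(self, X: pd.DataFrame, y=None) -> "DescriptiveCategorizer":
        self.summary_ = summarize_subjects(X, self.inclusion_threshold)
        self.included_ = self.summary_.index[self.summary_["inclusion"]]
        self.group_counts_ = group_counts(self.summary_)
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return categorize_homogeneity(X)

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).summary_["homogeneity_category"]
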