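"""Design vocabulary shared by every stage of the pipeline.

A *condition* is one cell of the truth-value-judgment design: a determiner
(``the``/``some``/``all``), a visual context (``all``/``none``/``gap``) and a
sentence polarity (``pos``/``neg``).  Its canonical string label is
``"<determiner>-<context>-<polarity>"``, e.g. ``the-gap-pos``.  All CSV files,
templates and model specifications use these labels and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Determiner(str, Enum):
    THE = "the"
    SOME = "some"
    ALL = "all"


class Context(str, Enum):
    """How many of the displayed objects satisfy the predicate."""

    ALL = "all"    # k = n
    NONE = "none"  # k = 0
    GAP = "gap"    # 0 < k < n


class Polarity(str, Enum):
    POS = "pos"
    NEG = "neg"


@dataclass(frozen=True, order=True)
class Condition:
    determiner: Determiner
    context: Context
    polarity: Polarity

    @property
    def label(self) -> str:
        return f"{self.determiner.value}-{self.context.value}-{self.polarity.value}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        try:
            d, c, p = label.split("-")
            return cls(Determiner(d), Context(c), Polarity(p))
        except ValueError as exc:
            raise ValueError(f"not a valid condition label: {label!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _c(label: str) -> Condition:
    return Condition.from_label(label)


# The nine conditions of the binary (accept/reject) paradigm.
BINARY_CONDITIONS: tuple[Condition, ...] = tuple(
    _c(lbl)
    for lbl in (
        "the-gap-pos",
        "the-gap-neg",
        "the-all-pos",
        "the-all-neg",
        "the-none-pos",
        "the-none-neg",
        "all-gap-pos",
        "all-gap-neg",
        "some-all-pos",
    )
)

# The ternary (reward-scale) paradigm adds the incomplete-description control.
TERNARY_CONDITIONS: tuple[Condition, ...] = BINARY_CONDITIONS + (_c("some-gap-pos"),)

# Uncontroversially true/false plural-definite controls used for inclusion.
DEFINITE_CONTROLS: tuple[Condition, ...] = tuple(
    _c(lbl) for lbl in ("the-all-pos", "the-all-neg", "the-none-pos", "the-none-neg")
)
# Controls whose target answer is the maximal response.
TRUE_CONTROLS: frozenset[Condition] = frozenset({_c("the-all-pos"), _c("the-none-neg")})
FALSE_CONTROLS: frozenset[Condition] = frozenset({_c("the-none-pos"), _c("the-all-neg")})

# Per-condition trial counts for the two experiments.
EXP1_TRIAL_COUNTS: dict[Condition, int] = {
    _c("the-gap-pos"): 3,
    _c("the-gap-neg"): 3,
    _c("the-all-pos"): 2,
    _c("the-all-neg"): 2,
    _c("the-none-pos"): 2,
    _c("the-none-neg"): 2,
    _c("all-gap-pos"): 3,
    _c("all-gap-neg"): 3,
    _c("some-all-pos"): 4,
}

EXP2_TRIAL_COUNTS: dict[Condition, int] = {
    _c("the-gap-pos"): 3,
    _c("the-gap-neg"): 3,
    _c("the-all-pos"): 2,
    _c("the-all-neg"): 2,
    _c("the-none-pos"): 2,
    _c("the-none-neg"): 2,
    _c("some-all-pos"): 3,
    _c("some-gap-pos"): 3,
    _c("all-gap-pos"): 3,
    _c("all-gap-neg"): 3,
}

EXPERIMENT_TRIAL_COUNTS = {"EXP1": EXP1_TRIAL_COUNTS, "EXP2": EXP2_TRIAL_COUNTS}
EXPERIMENT_PARADIGM = {"EXP1": "binary", "EXP2": "ternary"}
PARADIGM_CONDITIONS = {"binary": BINARY_CONDITIONS, "ternary": TERNARY_CONDITIONS}
PARADIGM_RESPONSES = {"binary": (0, 1), "ternary": (-1, 0, 1)}


@dataclass(frozen=True)
class WorldState:
    """A finite model: ``n_objects`` objects of which ``k_matching`` match."""

    n_objects: int
    k_matching: int

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be positive")
        if not 0 <= self.k_matching <= self.n_objects:
            raise ValueError("k_matching must lie in [0, n_objects]")

    @property
    def context(self) -> Context:
        if self.k_matching == self.n_objects:
            return Context.ALL
        if self.k_matching == 0:
            return Context.NONE
        return Context.GAP


def world_for_context(context: Context, n_objects: int = 4) -> WorldState:
    """Canonical world for a context label (``gap`` shows half the objects
    matching, as in the experimental displays of four objects with two of the
    named colour)."""
    if context is Context.ALL:
        k = n_objects
    elif context is Context.NONE:
        k = 0
    else:
        k = n_objects // 2
        if k in (0, n_objects):
            raise ValueError(f"no gap world exists for n_objects={n_objects}")
    return WorldState(n_objects, k)
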