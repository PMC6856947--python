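"""Trivalent finite-model semantics for the SOME/ALL/THE fragment.

Meanings are truth sets over the number ``k`` of matching objects in a domain
of size ``n``.  A plural definite ("the trucks are blue") is given a literal
existential meaning which recursive exhaustification strengthens to the
universal meaning; the homogeneous reading is trivalent, true when all objects
match, false when none do, and neither true nor false (a *gap*) in between.

From the evaluation rules the module derives, for every interpretive group
(a reading of the definite plus a scalar-implicature flag), the full predicted
response template over the design conditions of either judgment paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .conditions import (
    BINARY_CONDITIONS,
    TERNARY_CONDITIONS,
    Condition,
    Context,
    Determiner,
    Polarity,
    WorldState,
    world_for_context,
)


# ---------------------------------------------------------------------------
# Meanings and exhaustification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Meaning:
    """A classical sentence meaning: the set of ``k`` values (0..n) at which
    the sentence is true."""

    n_objects: int
    truth_set: frozenset[int]

    def __post_init__(self) -> None:
        if not all(0 <= k <= self.n_objects for k in self.truth_set):
            raise ValueError("truth_set must be a subset of {0..n_objects}")

    def entails(self, other: "Meaning") -> bool:
        self._check_domain(other)
        return self.truth_set <= other.truth_set

    def complement(self) -> "Meaning":
        full = frozenset(range(self.n_objects + 1))
        return Meaning(self.n_objects, full - self.truth_set)

    def intersect(self, other: "Meaning") -> "Meaning":
        self._check_domain(other)
        return Meaning(self.n_objects, self.truth_set & other.truth_set)

    def _check_domain(self, other: "Meaning") -> None:
        if self.n_objects != other.n_objects:
            raise ValueError("meanings live on different domain sizes")

    def __bool__(self) -> bool:
        return bool(self.truth_set)


def some_meaning(n_objects: int) -> Meaning:
    """Existential: at least one object matches."""
    return Meaning(n_objects, frozenset(range(1, n_objects + 1)))


def all_meaning(n_objects: int) -> Meaning:
    """Universal: every object matches."""
    return Meaning(n_objects, frozenset({n_objects}))


class Reading(str, Enum):
    """Construal of the plural definite description.

    EXI  low-scope existential
    HOM  homogeneous (trivalent)
    UNI  low-scope universal
    WSE  wide-scope existential (the fourth logically possible binary pattern)
    SA   universal with a scope-ambiguity response strategy under negation
    WS   strict wide-scope universal
    PT   wide-scope universal with a partial-truth response strategy
    """

    EXI = "exi"
    HOM = "hom"
    UNI = "uni"
    WSE = "wse"
    SA = "sa"
    WS = "ws"
    PT = "pt"


_UNIVERSAL_THE_READINGS = {Reading.UNI, Reading.SA, Reading.WS, Reading.PT}


def literal_meaning(
    determiner: Determiner, n_objects: int, reading: Reading | None = None
) -> Meaning:
    """Literal (pre-exhaustification) meaning of a positive sentence.

    The definite THE requires a reading: existential readings (and the
    homogeneous reading, whose *literal* layer is existential on the
    implicature account) yield the existential truth set, universal
    construals the universal one.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    if determiner is Determiner.SOME:
        return some_meaning(n_objects)
    if determiner is Determiner.ALL:
        return all_meaning(n_objects)
    # THE
    if reading in (Reading.EXI, Reading.HOM, Reading.WSE):
        return some_meaning(n_objects)
    if reading in _UNIVERSAL_THE_READINGS:
        return all_meaning(n_objects)
    raise ValueError(
        f"no literal meaning for determiner {determiner!r} under reading {reading!r}"
    )


def exhaustify(prejacent: Meaning, alternatives: Sequence[Meaning]) -> Meaning:
    """Conjoin the prejacent with the negation of its innocently excludable
    alternatives.

    An alternative is a candidate for exclusion if the prejacent does not
    entail it.  Exclusion is *innocent*: an alternative is excluded only if it
    belongs to every maximal set of candidates whose joint negation is
    consistent with the prejacent.  On scales ordered by entailment this
    coincides with negating the strictly stronger alternatives.
    """
    if not prejacent:
        raise ValueError("vacuous assertion: prejacent has an empty truth set")
    candidates = [a for a in alternatives if not prejacent.entails(a)]
    for a in candidates:
        prejacent._check_domain(a)
    if not candidates:
        return prejacent

    def negate_jointly(subset: Iterable[Meaning]) -> Meaning:
        result = prejacent
        for a in subset:
            result = result.intersect(a.complement())
        return result

    consistent: list[frozenset[int]] = [
        frozenset(idx)
        for r in range(len(candidates) + 1)
        for idx in combinations(range(len(candidates)), r)
        if negate_jointly([candidates[i] for i in idx])
    ]
    maximal = [s for s in consistent if not any(s < t for t in consistent)]
    innocently_excludable = frozenset.intersection(*maximal) if maximal else frozenset()
    return negate_jointly([candidates[i] for i in sorted(innocently_excludable)])


Alternative = Union[Meaning, tuple[Meaning, Sequence[Meaning]]]


def recursive_exhaustify(prejacent: Meaning, alternatives: Sequence[Alternative]) -> Meaning:
    """Two-level exhaustification: exh(exh(prejacent)).

    The inner level exhaustifies the prejacent against the raw alternatives;
    the outer level then negates the *exhaustified* alternatives.  Each
    alternative may be given as a bare :class:`Meaning` (exhaustified against
    the remaining alternatives in the list) or as a ``(meaning, its_own_
    alternatives)`` pair for scales that bring their own stronger members —
    the definite's sole alternative "some" carries "all" on its scale, which
    is what strengthens the existential literal to the universal meaning.
    """
    raw = [a[0] if isinstance(a, tuple) else a for a in alternatives]
    strengthened: list[Meaning] = []
    for i, a in enumerate(alternatives):
        if isinstance(a, tuple):
            meaning, own_alts = a
            inner = list(own_alts)
        else:
            meaning = a
            inner = [m for j, m in enumerate(raw) if j != i]
        strengthened.append(exhaustify(meaning, inner))
    result = exhaustify(exhaustify(prejacent, raw), strengthened)
    if not result:
        raise ValueError("contradictory strengthening: recursive exhaustification is empty")
    return result


def strengthened_definite_meaning(n_objects: int) -> Meaning:
    """Meaning of a positive plural definite after recursive exhaustification:
    the existential literal with alternative "some" (whose own scale-mate is
    "all") comes out universal."""
    the_literal = literal_meaning(Determiner.THE, n_objects, Reading.EXI)
    return recursive_exhaustify(
        the_literal, [(some_meaning(n_objects), [all_meaning(n_objects)])]
    )


# ---------------------------------------------------------------------------
# Trivalent evaluation
# ---------------------------------------------------------------------------

class TrivalentValue(str, Enum):
    TRUE = "true"
    FALSE = "false"
    GAP = "gap"

    def negate(self) -> "TrivalentValue":
        if self is TrivalentValue.TRUE:
            return TrivalentValue.FALSE
        if self is TrivalentValue.FALSE:
            return TrivalentValue.TRUE
        return TrivalentValue.GAP


def _tv(condition: bool) -> TrivalentValue:
    return TrivalentValue.TRUE if condition else TrivalentValue.FALSE


@dataclass(frozen=True)
class SentenceForm:
    determiner: Determiner
    polarity: Polarity


def evaluate(form: SentenceForm, reading: Reading, world: WorldState) -> TrivalentValue:
    """Trivalent truth value of a design sentence in a world.

    Negation takes scope over the low-scope meanings (trivalent negation for
    the homogeneous reading); the WS/PT construals instead give the negated
    definite the wide-scope universal parse (true only when nothing matches).
    """
    k, n = world.k_matching, world.n_objects
    d, pol = form.determiner, form.polarity

    if d is Determiner.SOME:
        positive = _tv(k >= 1)
        return positive if pol is Polarity.POS else positive.negate()
    if d is Determiner.ALL:
        positive = _tv(k == n)
        # "pas tous": negation of the universal, true iff not all match.
        return positive if pol is Polarity.POS else positive.negate()

    # THE
    if reading is Reading.HOM:
        if k == n:
            positive = TrivalentValue.TRUE
        elif k == 0:
            positive = TrivalentValue.FALSE
        else:
            positive = TrivalentValue.GAP
        return positive if pol is Polarity.POS else positive.negate()
    if reading in (Reading.EXI, Reading.WSE):
        if pol is Polarity.POS:
            return _tv(k >= 1)
        if reading is Reading.EXI:
            return _tv(k == 0)       # ¬∃: low-scope existential under negation
        return _tv(k < n)            # ∃¬: wide-scope existential
    if reading in (Reading.UNI, Reading.SA):
        if pol is Polarity.POS:
            return _tv(k == n)
        return _tv(k < n)            # ¬∀: low-scope universal under negation
    if reading in (Reading.WS, Reading.PT):
        if pol is Polarity.POS:
            return _tv(k == n)
        return _tv(k == 0)           # ∀¬: wide-scope universal
    raise ValueError(f"cannot evaluate reading {reading!r} for determiner {d!r}")


# ---------------------------------------------------------------------------
# Interpretive groups and response templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Group:
    """An interpretive group: a reading plus whether scalar implicatures are
    computed (the flag only ever affects sentences with lexical "some")."""

    reading: Reading
    si: bool

    @property
    def label(self) -> str:
        return f"{self.reading.value}/{'+si' if self.si else '-si'}"

    @classmethod
    def from_label(cls, label: str) -> "Group":
        reading, si = label.split("/")
        return cls(Reading(reading), {"+si": True, "-si": False}[si])

    def __str__(self) -> str:  # pragma: no cover
        return self.label


BINARY_READINGS = (Reading.EXI, Reading.HOM, Reading.UNI, Reading.WSE)
TERNARY_READINGS = (Reading.EXI, Reading.HOM, Reading.SA, Reading.WS, Reading.PT)

# Canonical six binary groups (the wide-scope existential pattern is admissible
# but not part of the canonical inventory) and ten ternary groups.
BINARY_GROUPS: tuple[Group, ...] = tuple(
    Group(r, si) for r in (Reading.EXI, Reading.HOM, Reading.UNI) for si in (True, False)
)
TERNARY_GROUPS: tuple[Group, ...] = tuple(
    Group(r, si) for r in TERNARY_READINGS for si in (True, False)
)

PARADIGM_GROUPS = {"binary": BINARY_GROUPS, "ternary": TERNARY_GROUPS}

_TV_TO_TERNARY = {TrivalentValue.TRUE: 1, TrivalentValue.GAP: 0, TrivalentValue.FALSE: -1}

# Cells of the ternary template that the evaluation rules do not fix: how the
# scope-ambiguity / wide-scope / partial-truth strategies respond to the
# negated universal control "all-gap-neg".  Overridable by the caller.
DEFAULT_TERNARY_OVERRIDES: dict[tuple[Reading, str], int] = {
    (Reading.SA, "all-gap-neg"): 1,
    (Reading.WS, "all-gap-neg"): 0,
    (Reading.PT, "all-gap-neg"): 0,
}


@dataclass(frozen=True)
class ResponseTemplate:
    paradigm: str
    group: Group
    entries: Mapping[str, int]  # condition label -> expected response

    def __getitem__(self, condition: str | Condition) -> int:
        label = condition.label if isinstance(condition, Condition) else condition
        return self.entries[label]


def _implicature_false(condition: Condition, world: WorldState) -> bool:
    """True when the sentence is literally true but its scalar implicature is
    false: a positive "some" sentence whose exhaustified meaning fails."""
    if condition.determiner is not Determiner.SOME or condition.polarity is not Polarity.POS:
        return False
    n = world.n_objects
    literal = some_meaning(n)
    strengthened = exhaustify(literal, [all_meaning(n)])
    k = world.k_matching
    return k in literal.truth_set and k not in strengthened.truth_set


def derive_template(
    group: Group,
    paradigm: str,
    n_objects: int = 4,
    ternary_overrides: Mapping[tuple[Reading, str], int] | None = None,
) -> ResponseTemplate:
    """Predicted response of ``group`` to every condition of ``paradigm``.

    Binary: accept (1) iff the sentence evaluates true and, for implicature
    computers, carries no false implicature; the truth-value gap maps to
    rejection.  Ternary: true/gap/false map to +1/0/−1; a literally true
    sentence with a false implicature earns the intermediate reward; the SA
    strategy gives the intermediate response to the negated definite in gap
    contexts (scopally ambiguous), and the PT strategy upgrades "partially
    true" falsity (a failed universal claim with some matching objects, or a
    failed wide-scope negative universal with some non-matching ones) to the
    intermediate response.
    """
    if paradigm == "binary":
        conditions, admissible = BINARY_CONDITIONS, BINARY_READINGS
    elif paradigm == "ternary":
        conditions, admissible = TERNARY_CONDITIONS, TERNARY_READINGS
    else:
        raise ValueError(f"unknown paradigm: {paradigm!r}")
    if group.reading not in admissible:
        raise ValueError(f"group {group.label} is not admissible in the {paradigm} paradigm")

    overrides = dict(DEFAULT_TERNARY_OVERRIDES)
    if ternary_overrides:
        overrides.update(ternary_overrides)

    entries: dict[str, int] = {}
    for cond in conditions:
        world = world_for_context(cond.context, n_objects)
        form = SentenceForm(cond.determiner, cond.polarity)
        value = evaluate(form, group.reading, world)
        false_si = group.si and _implicature_false(cond, world)

        if paradigm == "binary":
            entries[cond.label] = int(value is TrivalentValue.TRUE and not false_si)
            continue

        resp = _TV_TO_TERNARY[value]
        if false_si:
            resp = 0  # literally true but underinformative
        if group.reading is Reading.SA and cond.determiner is Determiner.THE:
            if cond.polarity is Polarity.NEG and cond.context is Context.GAP:
                resp = 0  # true or false depending on scope: intermediate
        if group.reading is Reading.PT and value is TrivalentValue.FALSE:
            k, n = world.k_matching, world.n_objects
            universal_claim = cond.determiner is Determiner.ALL or cond.determiner is Determiner.THE
            if universal_claim:
                if cond.polarity is Polarity.POS and k > 0:
                    resp = 0  # partially true positive universal
                if cond.polarity is Polarity.NEG and k < n:
                    resp = 0  # partially true wide-scope negative universal
        key = (group.reading, cond.label)
        if key in overrides:
            resp = overrides[key]
        entries[cond.label] = resp
    return ResponseTemplate(paradigm, group, entries)


def templates_frame(
    paradigm: str,
    groups: Sequence[Group] | None = None,
    n_objects: int = 4,
    ternary_overrides: Mapping[tuple[Reading, str], int] | None = None,
) -> pd.DataFrame:
    """Long-format table of predicted responses with columns
    ``condition, group, paradigm, expected_response``."""
    groups = tuple(groups) if groups is not None else PARADIGM_GROUPS[paradigm]
    rows = []
    for group in groups:
        template = derive_template(group, paradigm, n_objects, ternary_overrides)
        for cond, resp in template.entries.items():
            rows.append(
                {
                    "condition": cond,
                    "group": group.label,
                    "paradigm": paradigm,
                    "expected_response": resp,
                }
            )
    return pd.DataFrame(rows)


def template_matrix(
    paradigm: str,
    groups: Sequence[Group] | None = None,
    n_objects: int = 4,
    ternary_overrides: Mapping[tuple[Reading, str], int] | None = None,
) -> pd.DataFrame:
    """Wide table: rows are condition labels, columns group labels."""
    long = templates_frame(paradigm, groups, n_objects, ternary_overrides)
    order = [c.label for c in (BINARY_CONDITIONS if paradigm == "binary" else TERNARY_CONDITIONS)]
    groups = tuple(groups) if groups is not None else PARADIGM_GROUPS[paradigm]
    wide = long.pivot(index="condition", columns="group", values="expected_response")
    return wide.loc[order, [g.label for g in groups]]
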