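"""Grammar and data model for IPC and composite item codes.

The Item Perspective Classification (IPC) framework codes the content of a
questionnaire item as

* an **appraisal type** — rational ``R`` or emotional ``E``;
* one or more **concepts**, each belonging to a fundamental domain:
  inorganic ``I``, biological ``B``, social ``S``, psychological ``P``, or
  open-ended ``X`` for vague / higher-order concepts; and
* **relations** between consecutive concepts: interactive ``*`` (directed:
  the first concept impacts the second), forced choice ``/``, or plain
  conjunction ``,``.

``R_B*S`` thus reads "a rational appraisal of a biological concept impacting
a social concept".  An item whose content cannot be classified at all gets
the sentinel code ``nc``.

A **composite item code** further specifies concepts with ICF category codes
(or ``nd-`` rater-generated placeholders), written in square brackets:
``R_B[b28013]*S[d760]``.  A bare concatenated dialect without brackets
(``R_Bb28013*Sd760``) is accepted on input; the bracketed form is the
canonical serialization.  Open-ended (``X``) concepts may carry an ``nd-``
spec but never a real ICF code: by definition they are not singly linkable.

Canonicalization sorts concepts within runs of the order-insensitive
relations ``,`` and ``/`` (by domain letter, then spec) and leaves the
directed ``*`` segments untouched, so that semantically identical codes
compare equal.  ICF-framework code lists are canonicalized by alphanumeric
sorting.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .icf_codes import CodeLike, ICFCode, ICFSyntaxError, RaterGeneratedCode, parse_icf

__all__ = [
    "AppraisalType",
    "ConceptDomain",
    "RelationOp",
    "ConceptUnit",
    "ItemCode",
    "IPCItemCode",
    "CompositeItemCode",
    "Framework",
    "ItemCoding",
    "CodingDataset",
    "CodeSyntaxError",
    "NC",
    "parse_ipc",
    "parse_composite",
    "render",
    "canonicalize",
    "canonicalize_icf_list",
    "strip_specs",
    "is_fully_classified",
    "enumerate_composites",
    "read_coding_table",
    "write_coding_table",
]


class AppraisalType(enum.Enum):
    """Rational vs. emotional appraisal."""

    R = "R"
    E = "E"


class ConceptDomain(enum.Enum):
    """Fundamental concept domains; X marks open-ended concepts."""

    I = "I"  # noqa: E741 - the framework's own letter
    B = "B"
    S = "S"
    P = "P"
    X = "X"


class RelationOp(enum.Enum):
    """Relation between two consecutive concepts in an item."""

    INTERACTIVE = "*"  # directed: left impacts right
    FORCED_CHOICE = "/"
    CONJUNCTION = ","

    @property
    def order_sensitive(self) -> bool:
        return self is RelationOp.INTERACTIVE


class CodeSyntaxError(ValueError):
    """Malformed item-code string; carries the offending position."""

    def __init__(self, message: str, text: str, position: int):
        super().__init__(f"{message} at position {position} in {text!r}")
        self.text = text
        self.position = position


@dataclass(frozen=True)
class ConceptUnit:
    """One concept: a domain letter plus an optional ICF / nd- spec."""

    domain: ConceptDomain
    spec: Optional[CodeLike] = None

    def __post_init__(self) -> None:
        if self.domain is ConceptDomain.X and isinstance(self.spec, ICFCode):
            raise ValueError(
                "open-ended (X) concepts cannot carry an ICF code; use an nd- spec"
            )

    def __str__(self) -> str:
        if self.spec is None:
            return self.domain.value
        return f"{self.domain.value}[{self.spec}]"

    @property
    def sort_key(self) -> tuple[str, str]:
        return (self.domain.value, "" if self.spec is None else str(self.spec))


@dataclass(frozen=True)
class ItemCode:
    """An IPC or composite item code, or the ``nc`` sentinel.

    A code with no concept specs is a pure IPC code; populating specs makes
    it composite.  ``IPCItemCode`` and ``CompositeItemCode`` are aliases of
    this class — the grammar and all operations are closed under one type.
    """

    appraisal: Optional[AppraisalType]
    concepts: tuple[ConceptUnit, ...]
    relations: tuple[RelationOp, ...]
    not_classified: bool = False

    def __post_init__(self) -> None:
        if self.not_classified:
            if self.appraisal is not None or self.concepts or self.relations:
                raise ValueError("nc sentinel carries no appraisal, concepts or relations")
            return
        if self.appraisal is None:
            raise ValueError("classified item code requires an appraisal type")
        if not self.concepts:
            raise ValueError("classified item code requires at least one concept")
        if len(self.relations) != len(self.concepts) - 1:
            raise ValueError(
                f"{len(self.concepts)} concepts require {len(self.concepts) - 1} "
                f"relations, got {len(self.relations)}"
            )

    @property
    def is_composite(self) -> bool:
        return any(c.spec is not None for c in self.concepts)

    def __str__(self) -> str:
        return render(self)


IPCItemCode = ItemCode
CompositeItemCode = ItemCode

#: the "not classified" sentinel
NC = ItemCode(appraisal=None, concepts=(), relations=(), not_classified=True)

_APPRAISALS = {a.value for a in AppraisalType}
_DOMAINS = {d.value for d in ConceptDomain}
_RELATIONS = {r.value: r for r in RelationOp}


def _parse(text: str, allow_specs: bool) -> ItemCode:
    if not text:
        raise CodeSyntaxError("empty code", text, 0)
    if text == "nc":
        return NC
    if text.startswith("nc"):
        raise CodeSyntaxError("trailing characters after nc sentinel", text, 2)
    pos = 0
    if text[pos] not in _APPRAISALS:
        raise CodeSyntaxError(
            f"expected appraisal letter R or E, found {text[pos]!r}", text, pos
        )
    appraisal = AppraisalType(text[pos])
    pos += 1
    if pos >= len(text) or text[pos] != "_":
        raise CodeSyntaxError("expected '_' after appraisal letter", text, pos)
    pos += 1

    concepts: list[ConceptUnit] = []
    relations: list[RelationOp] = []
    while True:
        if pos >= len(text):
            raise CodeSyntaxError("dangling relation operator", text, pos) if relations \
                else CodeSyntaxError("empty concept list", text, pos)
        ch = text[pos]
        if ch not in _DOMAINS:
            raise CodeSyntaxError(f"unknown domain letter {ch!r}", text, pos)
        domain = ConceptDomain(ch)
        pos += 1
        spec: Optional[CodeLike] = None
        spec_start = pos
        if pos < len(text) and text[pos] == "[":
            end = text.find("]", pos)
            if end < 0:
                raise CodeSyntaxError("unterminated '[' spec", text, pos)
            raw = text[pos + 1 : end]
            pos = end + 1
            spec = _parse_spec(raw, text, spec_start + 1)
        elif pos < len(text) and text[pos] not in _RELATIONS:
            # bare concatenated dialect: spec runs until the next relation op
            end = pos
            while end < len(text) and text[end] not in _RELATIONS:
                end += 1
            raw = text[pos:end]
            pos = end
            spec = _parse_spec(raw, text, spec_start)
        if spec is not None and not allow_specs:
            raise CodeSyntaxError("ICF spec not allowed in a pure IPC code", text, spec_start)
        try:
            concepts.append(ConceptUnit(domain, spec))
        except ValueError as exc:
            raise CodeSyntaxError(str(exc), text, spec_start) from exc
        if pos == len(text):
            break
        op = text[pos]
        if op not in _RELATIONS:
            raise CodeSyntaxError(f"expected relation operator, found {op!r}", text, pos)
        relations.append(_RELATIONS[op])
        pos += 1
    return ItemCode(appraisal, tuple(concepts), tuple(relations))


def _parse_spec(raw: str, text: str, position: int) -> CodeLike:
    try:
        return parse_icf(raw)
    except ICFSyntaxError as exc:
        raise CodeSyntaxError(str(exc), text, position) from exc


def parse_ipc(text: str) -> ItemCode:
    """Parse a pure IPC code such as ``R_B*S`` or the sentinel ``nc``."""
    return _parse(text, allow_specs=False)


def parse_composite(text: str) -> ItemCode:
    """Parse a composite code; accepts bracketed and bare-spec dialects.

    Concepts without specs are allowed (a composite code need not specify
    every concept), so every valid IPC string is also a valid composite
    string.
    """
    return _parse(text, allow_specs=True)


def render(code: ItemCode, canonical: bool = False) -> str:
    """Serialize ``code``; with ``canonical=True`` canonicalize first."""
    if canonical:
        code = canonicalize(code)
    if code.not_classified:
        return "nc"
    out = [code.appraisal.value, "_", str(code.concepts[0])]
    for op, unit in zip(code.relations, code.concepts[1:]):
        out.append(op.value)
        out.append(str(unit))
    return "".join(out)


def canonicalize(code: ItemCode) -> ItemCode:
    """Sort the leading run of order-insensitive-related concepts.

    Relations chain left-to-right with no precedence, so ``A,B*C`` reads
    ``(A,B)*C``: only the *leading* maximal run of one repeated ``,`` or
    ``/`` operator is a genuinely unordered concept set.  Those concepts are
    sorted by (domain letter, spec string); every concept after the first
    operator change — and everything around the directed ``*`` — is bound to
    its position and left untouched.  A code whose relations are all one
    insensitive operator (the common case) therefore gets fully sorted.
    Idempotent, and invariant under permutation of the sortable run.
    """
    if code.not_classified or len(code.concepts) <= 1:
        return code
    first = code.relations[0]
    if first.order_sensitive:
        return code
    end = 1
    while end < len(code.relations) and code.relations[end] is first:
        end += 1
    concepts = list(code.concepts)
    concepts[: end + 1] = sorted(concepts[: end + 1], key=lambda u: u.sort_key)
    return replace(code, concepts=tuple(concepts))


def canonicalize_icf_list(codes: Iterable[CodeLike]) -> tuple[CodeLike, ...]:
    """Re-list ICF / rater-generated codes in alphanumeric order."""
    return tuple(sorted(codes, key=str))


def strip_specs(code: ItemCode) -> ItemCode:
    """Project a composite code onto its pure IPC skeleton."""
    if code.not_classified:
        return code
    return replace(code, concepts=tuple(replace(u, spec=None) for u in code.concepts))


def is_fully_classified(code: Union[ItemCode, Sequence[CodeLike]]) -> bool:
    """True unless the code is ``nc`` or contains a rater-generated spec.

    Accepts an item code or an ICF-framework code list.  A pure IPC code
    with no specs is fully classified by the IPC framework.
    """
    if isinstance(code, ItemCode):
        if code.not_classified:
            return False
        return not any(isinstance(u.spec, RaterGeneratedCode) for u in code.concepts)
    return bool(code) and not any(isinstance(c, RaterGeneratedCode) for c in code)


def enumerate_composites(
    concepts: Sequence[ConceptUnit],
    appraisals: Iterable[AppraisalType],
    relation_forms: Iterable[RelationOp],
) -> set[ItemCode]:
    """All distinct canonical two-concept composite codes.

    The cross product of appraisal types and relation forms is expanded; the
    directed interaction ``*`` contributes both concept orders, while ``/``
    and ``,`` collapse to a single canonical code per appraisal.  Duplicates
    (e.g. two identical concept units under ``*``) collapse by set semantics.
    """
    if len(concepts) != 2:
        raise ValueError("enumeration is defined over exactly two concept units")
    a, b = concepts
    out: set[ItemCode] = set()
    for app in appraisals:
        for op in relation_forms:
            orders = [(a, b), (b, a)] if op.order_sensitive else [(a, b)]
            for pair in orders:
                out.add(canonicalize(ItemCode(app, tuple(pair), (op,))))
    return out


class Framework(enum.Enum):
    """Which classification framework a coding row belongs to."""

    IPC = "ipc"
    ICF = "icf"
    COMPOSITE = "composite"


#: parsed in-memory code: an item code, or a list of ICF/nd codes
CodingValue = Union[ItemCode, tuple[CodeLike, ...]]


@dataclass(frozen=True)
class ItemCoding:
    """One rater's code for one item under one framework."""

    item_id: str
    rater_id: str
    framework: Framework
    code: CodingValue

    def canonical(self) -> "ItemCoding":
        if isinstance(self.code, ItemCode):
            return replace(self, code=canonicalize(self.code))
        return replace(self, code=canonicalize_icf_list(self.code))

    def code_string(self) -> str:
        if isinstance(self.code, ItemCode):
            return render(self.code, canonical=True)
        return ";".join(str(c) for c in canonicalize_icf_list(self.code))


def _parse_cell(framework: Framework, cell: str) -> CodingValue:
    if framework is Framework.ICF:
        parts = [p.strip() for p in cell.split(";") if p.strip()]
        if not parts:
            raise ValueError("ICF coding requires at least one code")
        return tuple(parse_icf(p) for p in parts)
    if framework is Framework.IPC:
        return parse_ipc(cell.strip())
    return parse_composite(cell.strip())


@dataclass
class CodingDataset:
    """Items × raters × frameworks table of codes, with optional consensus.

    Every (item, rater, framework) triple appears at most once, and within a
    framework all raters must cover the same items.  ``consensus`` maps
    (item, framework) to a collaboratively agreed code, when available.
    """

    codings: list[ItemCoding]
    consensus: dict[tuple[str, Framework], CodingValue] = field(default_factory=dict)

    _index: dict[tuple[str, str, Framework], ItemCoding] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for c in self.codings:
            key = (c.item_id, c.rater_id, c.framework)
            if key in self._index:
                raise ValueError(f"duplicate coding for {key}")
            self._index[key] = c
        for fw in self.frameworks():
            per_rater = {
                r: {c.item_id for c in self.codings if c.rater_id == r and c.framework is fw}
                for r in self.raters(fw)
            }
            item_sets = list(per_rater.values())
            if any(s != item_sets[0] for s in item_sets[1:]):
                raise ValueError(
                    f"raters cover different item sets for framework {fw.value}"
                )

    def frameworks(self) -> list[Framework]:
        return sorted({c.framework for c in self.codings}, key=lambda f: f.value)

    def raters(self, framework: Optional[Framework] = None) -> list[str]:
        return sorted(
            {
                c.rater_id
                for c in self.codings
                if framework is None or c.framework is framework
            }
        )

    def items(self, framework: Optional[Framework] = None) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.codings:
            if framework is None or c.framework is framework:
                seen.setdefault(c.item_id, None)
        return list(seen)

    def get(self, item_id: str, rater_id: str, framework: Framework) -> ItemCoding:
        return self._index[(item_id, rater_id, framework)]

    def codes_by_item(self, framework: Framework) -> dict[str, dict[str, ItemCoding]]:
        """item_id -> rater_id -> coding, for one framework."""
        out: dict[str, dict[str, ItemCoding]] = {}
        for c in self.codings:
            if c.framework is framework:
                out.setdefault(c.item_id, {})[c.rater_id] = c
        return out


_CONSENSUS_RATER = "consensus"


def read_coding_table(path: str | Path) -> CodingDataset:
    """Load a coding table (TSV or CSV by extension).

    Columns: ``item_id``, ``rater_id``, ``framework`` (ipc|icf|composite),
    ``code``; ICF cells may hold ';'-separated code lists.  Rows whose
    ``rater_id`` is the reserved word ``consensus`` populate the consensus
    mapping instead of the rater grid.  Malformed rows are reported with
    their line number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["item_id", "rater_id", "framework", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    codings: list[ItemCoding] = []
    consensus: dict[tuple[str, Framework], CodingValue] = {}
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            fw = Framework(row["framework"].strip().lower())
            value = _parse_cell(fw, row["code"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if row["rater_id"].strip().lower() == _CONSENSUS_RATER:
            consensus[(row["item_id"], fw)] = value
        else:
            codings.append(ItemCoding(row["item_id"], row["rater_id"], fw, value))
    return CodingDataset(codings, consensus)


def write_coding_table(dataset: CodingDataset, path: str | Path) -> None:
    """Write a dataset back to TSV/CSV in the canonical cell syntax."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = [
        {
            "item_id": c.item_id,
            "rater_id": c.rater_id,
            "framework": c.framework.value,
            "code": c.code_string(),
        }
        for c in dataset.codings
    ]
    for (item, fw), value in dataset.consensus.items():
        rows.append(
            {
                "item_id": item,
                "rater_id": _CONSENSUS_RATER,
                "framework": fw.value,
                "code": ItemCoding(item, _CONSENSUS_RATER, fw, value).code_string(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
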