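"""Syntax, hierarchy and validation for ICF category codes.

The International Classification of Functioning, Disability and Health (ICF)
assigns each category an alphanumeric code: a component letter — ``b`` (body
functions), ``s`` (body structures), ``d`` (activities and participation) or
``e`` (environmental factors) — followed by digits.  The digit string is
hierarchical: one digit addresses a chapter, three digits a second-level
category, four a third-level and five a fourth-level category (two-digit
codes do not exist).  Personal factors have no codes in the classification.

Concepts that cannot be placed under any ICF category are represented by
*rater-generated* placeholder codes with the prefix ``nd-`` ("not defined"),
e.g. ``nd-gh`` for the undefined higher-order concept "general health".

Only code *syntax* and hierarchy are modelled here; category definitions are
not bundled.  A user-supplied two-column TSV catalog (``code<TAB>label``) can
optionally be loaded for membership validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "ICFCode",
    "RaterGeneratedCode",
    "ICFCatalog",
    "ICFSyntaxError",
    "parse_icf",
    "level",
    "ancestors",
]

#: valid ICF component letters
COMPONENTS = ("b", "s", "d", "e")

#: permitted digit-string lengths, in hierarchy order (chapter .. 4th level)
_LEVEL_LENGTHS = (1, 3, 4, 5)

_ND_RE = re.compile(r"^nd-([a-z0-9][a-z0-9_]*)$")
_ICF_RE = re.compile(r"^([bsde])([0-9]+)$")


class ICFSyntaxError(ValueError):
    """Raised when a string is not a valid ICF or rater-generated code."""


@dataclass(frozen=True, order=True)
class ICFCode:
    """A structural ICF category code, e.g. ``b28013`` or ``d760``."""

    component: str
    digits: str

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ICFSyntaxError(
                f"unknown ICF component {self.component!r} (expected one of {COMPONENTS})"
            )
        if not self.digits.isdigit():
            raise ICFSyntaxError(f"non-numeric ICF digits {self.digits!r}")
        if len(self.digits) not in _LEVEL_LENGTHS:
            raise ICFSyntaxError(
                f"ICF code {self.component}{self.digits}: digit length "
                f"{len(self.digits)} invalid (must be one of {_LEVEL_LENGTHS})"
            )

    @property
    def chapter(self) -> "ICFCode":
        return ICFCode(self.component, self.digits[0])

    def __str__(self) -> str:
        return f"{self.component}{self.digits}"


@dataclass(frozen=True, order=True)
class RaterGeneratedCode:
    """An ``nd-`` placeholder for a concept not defined by the ICF."""

    tag: str

    def __post_init__(self) -> None:
        if not _ND_RE.match(f"nd-{self.tag}"):
            raise ICFSyntaxError(f"invalid rater-generated tag {self.tag!r}")

    def __str__(self) -> str:
        return f"nd-{self.tag}"


CodeLike = Union[ICFCode, RaterGeneratedCode]


def parse_icf(text: str) -> CodeLike:
    """Parse ``text`` into an :class:`ICFCode` or :class:`RaterGeneratedCode`.

    ``nd-``-prefixed strings yield rater-generated codes; anything else must
    be a component letter followed by 1, 3, 4 or 5 digits.  Qualifier
    suffixes (e.g. ``b280.2``) are rejected.
    """
    if not text:
        raise ICFSyntaxError("empty ICF code")
    m = _ND_RE.match(text)
    if m:
        return RaterGeneratedCode(m.group(1))
    if text.startswith("nd-"):
        raise ICFSyntaxError(f"invalid rater-generated code {text!r}")
    m = _ICF_RE.match(text)
    if not m:
        raise ICFSyntaxError(f"invalid ICF code {text!r}")
    return ICFCode(m.group(1), m.group(2))


def level(code: ICFCode) -> int:
    """Hierarchy level of ``code``: 1 (chapter) through 4 (fourth level)."""
    return _LEVEL_LENGTHS.index(len(code.digits)) + 1


def ancestors(code: ICFCode) -> list[ICFCode]:
    """All strict ancestors of ``code``, from chapter downward.

    ``len(ancestors(c)) == level(c) - 1`` for every valid code.
    """
    return [
        ICFCode(code.component, code.digits[:n])
        for n in _LEVEL_LENGTHS
        if n < len(code.digits)
    ]


@dataclass
class ICFCatalog:
    """Optional user-supplied catalog mapping codes to labels.

    Parents implied by a member code's digit prefix are synthesized with an
    empty label when the file omits them, so hierarchy walks never dangle.
    """

    labels: dict[ICFCode, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in list(self.labels):
            for anc in ancestors(code):
                self.labels.setdefault(anc, "")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ICFCatalog":
        labels: dict[ICFCode, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() == "code":
                    continue
                code = parse_icf(parts[0])
                if not isinstance(code, ICFCode):
                    raise ICFSyntaxError(
                        f"{path}:{lineno}: rater-generated codes do not belong in a catalog"
                    )
                labels[code] = parts[1] if len(parts) > 1 else ""
        return cls(labels)

    def __contains__(self, code: CodeLike) -> bool:
        return isinstance(code, ICFCode) and code in self.labels

    def unknown_codes(self, codes: Iterable[CodeLike]) -> list[ICFCode]:
        """Structurally valid ICF codes absent from the catalog.

        This is a warning contract: callers report these without aborting
        metric computation.  Rater-generated codes are never flagged.
        """
        return sorted(
            {c for c in codes if isinstance(c, ICFCode) and c not in self.labels}
        )
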