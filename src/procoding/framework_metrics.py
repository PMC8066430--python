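"""Framework-performance indicators over a two-rater coding dataset.

Three indicators compare how classification frameworks perform when used to
code questionnaire-item content:

* **classification capacity** — percent of items both amenable to
  classification (no ``nc`` sentinel, no ``nd-`` rater-generated codes) and
  coded identically by the two raters after canonicalization;
* **coding efficiency** — the number of unique codes the framework needed to
  classify the item sample (fewer codes = more efficient), split into valid
  framework codes and rater-generated ones;
* **content overlap detection** — percent of items sharing an identical code
  with at least one other item.  For whole-item frameworks (IPC, composite)
  the match key is the full canonical code; for the ICF framework any single
  ICF / nd- code shared between two items' code lists counts.  The top-k
  variant restricts match keys to the k most frequently used codes.

Efficiency and overlap are computed on a *final* coding per item: the
consensus column when the dataset has one, otherwise the agreed code where
the two raters coincide (disagreeing items are excluded and reported).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional, Union

from .coding_model import (
    CodingDataset,
    CodingValue,
    Framework,
    ItemCode,
    ItemCoding,
    canonicalize_icf_list,
    is_fully_classified,
)

__all__ = [
    "ConsensusPolicy",
    "MetricsReport",
    "percent_agreement",
    "classification_capacity",
    "coding_efficiency",
    "content_overlap",
    "top_codes",
    "compute_metrics",
    "resolve_final_codings",
]


class ConsensusPolicy(enum.Enum):
    """Where the final per-item coding comes from."""

    CONSENSUS_COLUMN = "consensus_column"
    RATER_INTERSECTION = "rater_intersection"
    #: consensus column when present, else rater intersection
    AUTO = "auto"


@dataclass
class MetricsReport:
    framework: Framework
    n_items: int
    classification_capacity: float
    percent_agreement: float
    unique_total: int
    unique_valid: int
    unique_rater_generated: int
    content_overlap: float
    content_overlap_topk: float
    top_k: int
    top_codes: list[tuple[str, int]]
    unresolved_items: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "framework": self.framework.value,
            "n_items": self.n_items,
            "classification_capacity": self.classification_capacity,
            "percent_agreement": self.percent_agreement,
            "coding_efficiency": {
                "unique_total": self.unique_total,
                "unique_valid": self.unique_valid,
                "unique_rater_generated": self.unique_rater_generated,
            },
            "content_overlap": self.content_overlap,
            "content_overlap_topk": self.content_overlap_topk,
            "top_k": self.top_k,
            "top_codes": [{"code": c, "frequency": f} for c, f in self.top_codes],
        }
        if self.unresolved_items:
            d["unresolved_items"] = self.unresolved_items
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _two_rater_grid(
    dataset: CodingDataset, framework: Framework
) -> tuple[list[str], list[tuple[ItemCoding, ItemCoding]]]:
    raters = dataset.raters(framework)
    if len(raters) != 2:
        raise ValueError(
            f"two-rater design required; framework {framework.value} has "
            f"{len(raters)} raters"
        )
    by_item = dataset.codes_by_item(framework)
    missing = [i for i, d in by_item.items() if len(d) != 2]
    if missing:
        raise ValueError(f"items missing a rater's coding: {missing}")
    items = list(by_item)
    pairs = [(by_item[i][raters[0]], by_item[i][raters[1]]) for i in items]
    return items, pairs


def _canonical_key(coding: ItemCoding) -> str:
    return coding.code_string()


def percent_agreement(dataset: CodingDataset, framework: Framework) -> float:
    """Percent of items whose two canonicalized codes are identical."""
    items, pairs = _two_rater_grid(dataset, framework)
    agree = sum(_canonical_key(a) == _canonical_key(b) for a, b in pairs)
    return 100.0 * agree / len(items)


def classification_capacity(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
) -> float:
    """Percent of items fully classified *and* agreed by both raters.

    Always ≤ percent_agreement and ≤ the fully-classified fraction.  The
    ``policy`` argument is accepted for interface symmetry; capacity is
    defined on the independent rater codings themselves.
    """
    items, pairs = _two_rater_grid(dataset, framework)
    ok = sum(
        _canonical_key(a) == _canonical_key(b) and is_fully_classified(a.code)
        for a, b in pairs
    )
    return 100.0 * ok / len(items)


def resolve_final_codings(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
) -> tuple[dict[str, CodingValue], list[str]]:
    """Final per-item coding plus the list of unresolved items.

    Under the consensus-column policy every item must be present in the
    consensus mapping; under rater intersection an item resolves only when
    the two raters' canonical codes coincide.
    """
    items, pairs = _two_rater_grid(dataset, framework)
    has_consensus = any(fw is framework for (_, fw) in dataset.consensus)
    if policy is ConsensusPolicy.AUTO:
        policy = (
            ConsensusPolicy.CONSENSUS_COLUMN
            if has_consensus
            else ConsensusPolicy.RATER_INTERSECTION
        )
    final: dict[str, CodingValue] = {}
    unresolved: list[str] = []
    if policy is ConsensusPolicy.CONSENSUS_COLUMN:
        for item in items:
            try:
                final[item] = dataset.consensus[(item, framework)]
            except KeyError:
                unresolved.append(item)
        return final, unresolved
    for item, (a, b) in zip(items, pairs):
        if _canonical_key(a) == _canonical_key(b):
            final[item] = a.canonical().code
        else:
            unresolved.append(item)
    return final, unresolved


def _code_units(framework: Framework, value: CodingValue) -> list[str]:
    """Countable code strings for one item's final coding.

    IPC / composite: the whole canonical item code.  ICF: each individual
    ICF or rater-generated code in the list.
    """
    coding = ItemCoding("_", "_", framework, value)
    if framework is Framework.ICF:
        return [str(c) for c in canonicalize_icf_list(value)]
    return [coding.code_string()]


def _is_rater_generated(framework: Framework, value: CodingValue, unit: str) -> bool:
    if framework is Framework.ICF:
        return unit.startswith("nd-")
    if isinstance(value, ItemCode):
        return not is_fully_classified(value)
    raise TypeError(f"{framework.value} coding must be an item code")


def coding_efficiency(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
) -> dict[str, int]:
    """Unique-code counts over the final codings.

    Returns ``unique_total``, ``unique_valid`` and ``unique_rater_generated``
    (codes that are ``nc``, contain an ``nd-`` spec, or are ``nd-`` codes).
    """
    final, _ = resolve_final_codings(dataset, framework, policy)
    valid: set[str] = set()
    rater_gen: set[str] = set()
    for value in final.values():
        for unit in _code_units(framework, value):
            if _is_rater_generated(framework, value, unit):
                rater_gen.add(unit)
            else:
                valid.add(unit)
    # a code string is one or the other, never both
    rater_gen -= valid
    return {
        "unique_total": len(valid) + len(rater_gen),
        "unique_valid": len(valid),
        "unique_rater_generated": len(rater_gen),
    }


def _unit_frequencies(final: dict[str, CodingValue], framework: Framework) -> dict[str, int]:
    """code string -> number of items carrying it (once per item)."""
    freq: dict[str, int] = {}
    for value in final.values():
        for unit in set(_code_units(framework, value)):
            freq[unit] = freq.get(unit, 0) + 1
    return freq


def content_overlap(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
    top_k: Optional[int] = None,
) -> float:
    """Percent of items sharing a code with at least one other item.

    With ``top_k`` set, only the k most frequent codes are eligible match
    keys, and a key must still appear in at least two items.
    """
    if top_k is not None and top_k <= 0:
        raise ValueError("top_k must be positive")
    final, _ = resolve_final_codings(dataset, framework, policy)
    if not final:
        return 0.0
    freq = _unit_frequencies(final, framework)
    eligible = set(freq)
    if top_k is not None:
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        eligible = {code for code, _ in ranked[:top_k]}
    overlapping = sum(
        any(unit in eligible and freq[unit] >= 2 for unit in set(_code_units(framework, v)))
        for v in final.values()
    )
    return 100.0 * overlapping / len(final)


def top_codes(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
    k: int = 5,
) -> list[tuple[str, int]]:
    """The k most frequently used codes (item frequency, ties alphanumeric)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    final, _ = resolve_final_codings(dataset, framework, policy)
    freq = _unit_frequencies(final, framework)
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def compute_metrics(
    dataset: CodingDataset,
    framework: Framework,
    policy: ConsensusPolicy = ConsensusPolicy.AUTO,
    top_k: int = 5,
) -> MetricsReport:
    """All indicators for one framework, bundled into a report."""
    items, _ = _two_rater_grid(dataset, framework)
    eff = coding_efficiency(dataset, framework, policy)
    _, unresolved = resolve_final_codings(dataset, framework, policy)
    return MetricsReport(
        framework=framework,
        n_items=len(items),
        classification_capacity=classification_capacity(dataset, framework, policy),
        percent_agreement=percent_agreement(dataset, framework),
        unique_total=eff["unique_total"],
        unique_valid=eff["unique_valid"],
        unique_rater_generated=eff["unique_rater_generated"],
        content_overlap=content_overlap(dataset, framework, policy),
        content_overlap_topk=content_overlap(dataset, framework, policy, top_k=top_k),
        top_k=top_k,
        top_codes=top_codes(dataset, framework, policy, k=top_k),
        unresolved_items=unresolved,
    )
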