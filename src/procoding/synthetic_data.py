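"""Synthetic item banks and two-rater codings with known ground truth.

No coded questionnaire dataset is publicly available for this kind of
content analysis, so every pipeline stage is exercised against simulated
data whose generating parameters are known.  The generator emulates the
structure of a pooled health-related-quality-of-life item sample:

* ``n_items`` items (default 159, six questionnaires' worth);
* a truncated-geometric number of concepts per item on ``1..max_concepts``
  calibrated so the mean is ``mean_concepts`` (default 1.7);
* concept domains drawn from ``domain_probs``; open-ended (X) concepts are
  by construction not ICF-classifiable;
* a fraction ``p_icf_unclassifiable`` of items (default 0.31) forced to
  contain at least one concept that no ICF category fits (the concept gets
  an ``nd-`` placeholder, and half the time becomes open-ended X);
* every other concept linked to an ICF category drawn from a bundled pool
  of 60 *synthetic* structural codes (syntax-valid codes spanning the b, s,
  d and e components, with sibling groups so that substitution errors are
  possible; no category text is included).

Two raters are derived from the truth by independent element-wise errors:
appraisal flip, relation resample, domain resample (among the four concrete
domains), ICF-spec substitution by a sibling category, and a whole-item
``nc`` lapse.  Each rater's IPC, ICF and composite rows are emitted
consistently from the same perturbed composite code.  Everything is
reproducible from a single seed.

Closed-form expectations for classification capacity under this error model
(`expected_capacity`) serve as analytic oracles for simulation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .coding_model import (
    NC,
    AppraisalType,
    CodingDataset,
    ConceptDomain,
    ConceptUnit,
    Framework,
    ItemCode,
    ItemCoding,
    RelationOp,
    strip_specs,
)
from .icf_codes import ICFCode, RaterGeneratedCode, parse_icf

__all__ = [
    "SimulationConfig",
    "RaterErrorRates",
    "TrueItem",
    "DEFAULT_ICF_POOL",
    "generate_item_bank",
    "simulate_raters",
    "simulate",
    "expected_capacity",
    "concept_count_distribution",
]


def _build_default_pool() -> tuple[str, ...]:
    families = {
        "b1": ["b126", "b130", "b134", "b152", "b1520", "b1521", "b1522"],
        "b2": ["b280", "b2800", "b2801", "b28010", "b28013", "b28014"],
        "b4": ["b420", "b4200", "b4201", "b4202"],
        "b7": ["b730", "b7300", "b7301", "b735"],
        "d4": ["d410", "d415", "d430", "d450", "d4500", "d4501", "d455"],
        "d6": ["d620", "d630", "d640"],
        "d7": ["d710", "d7100", "d7101", "d720", "d750", "d760", "d7600", "d7601", "d770"],
        "d8": ["d845", "d850"],
        "d9": ["d910", "d920", "d9201", "d9204"],
        "s7": ["s710", "s720", "s730", "s7300", "s7301"],
        "e1": ["e110", "e1100"],
        "e3": ["e310", "e315", "e320", "e325"],
        "e4": ["e410", "e420", "e450"],
    }
    pool = tuple(code for fam in families.values() for code in fam)
    assert len(pool) == len(set(pool)) == 60
    return pool


#: 60 synthetic, structurally valid ICF-style codes (no category text)
DEFAULT_ICF_POOL: tuple[str, ...] = _build_default_pool()

#: nd- tags for unclassifiable concepts (general health, quality of life,
#: well-being, health state, personal factor)
_ND_TAGS = ("gh", "qol", "wb", "hs", "pf")

#: domain an ICF component letter most plausibly specifies
_COMPONENT_DOMAIN = {"b": ConceptDomain.B, "s": ConceptDomain.B,
                     "d": ConceptDomain.S, "e": ConceptDomain.I}


@dataclass(frozen=True)
class RaterErrorRates:
    """Independent per-rater perturbation probabilities."""

    e_appraisal: float = 0.005
    e_relation: float = 0.005
    e_domain: float = 0.005
    e_icf_substitute: float = 0.005
    e_nc: float = 0.005

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion, got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    n_items: int = 159
    mean_concepts: float = 1.7
    max_concepts: int = 3
    domain_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.06, "B": 0.37, "S": 0.22, "P": 0.35, "X": 0.0}
    )
    appraisal_prob_R: float = 0.8
    relation_probs: dict[str, float] = field(
        default_factory=lambda: {"*": 0.5, "/": 0.2, ",": 0.3}
    )
    p_icf_unclassifiable: float = 0.31
    icf_code_pool: tuple[str, ...] = DEFAULT_ICF_POOL
    rater_error: RaterErrorRates = field(default_factory=RaterErrorRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if not math.isclose(sum(self.domain_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("domain_probs must sum to 1")
        if not math.isclose(sum(self.relation_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("relation_probs must sum to 1")
        if not 0.0 <= self.appraisal_prob_R <= 1.0:
            raise ValueError("appraisal_prob_R must be a proportion")
        if not 0.0 <= self.p_icf_unclassifiable <= 1.0:
            raise ValueError("p_icf_unclassifiable must be a proportion")
        if not self.icf_code_pool:
            raise ValueError("icf_code_pool must be non-empty")
        if not 1.0 <= self.mean_concepts <= self.max_concepts:
            raise ValueError(
                "mean_concepts must lie within [1, max_concepts] "
                "(truncated distribution cannot reach it otherwise)"
            )
        concept_count_distribution(self.mean_concepts, self.max_concepts)  # solvable?

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "mean_concepts": self.mean_concepts,
            "max_concepts": self.max_concepts,
            "domain_probs": dict(self.domain_probs),
            "appraisal_prob_R": self.appraisal_prob_R,
            "relation_probs": dict(self.relation_probs),
            "p_icf_unclassifiable": self.p_icf_unclassifiable,
            "icf_code_pool": list(self.icf_code_pool),
            "rater_error": dict(self.rater_error.__dict__),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "rater_error" in d:
            d["rater_error"] = RaterErrorRates(**d["rater_error"])
        if "icf_code_pool" in d:
            d["icf_code_pool"] = tuple(d["icf_code_pool"])
        return cls(**d)


@dataclass(frozen=True)
class TrueItem:
    """Ground-truth composite code for one simulated item."""

    item_id: str
    true_composite: ItemCode
    icf_classifiable: tuple[bool, ...]


def concept_count_distribution(mean: float, max_concepts: int) -> np.ndarray:
    """Truncated-geometric pmf on 1..max_concepts with the requested mean.

    Weights are q**(k-1); q is solved so the truncated mean matches.  q < 1
    favours short items, q > 1 long ones; the mean is attainable on
    (1, max_concepts) exclusive, with the endpoints handled as point masses.
    """
    k = np.arange(1, max_concepts + 1, dtype=float)
    if math.isclose(mean, 1.0):
        p = np.zeros(max_concepts)
        p[0] = 1.0
        return p
    if math.isclose(mean, float(max_concepts)):
        p = np.zeros(max_concepts)
        p[-1] = 1.0
        return p

    def truncated_mean(q: float) -> float:
        w = q ** (k - 1)
        return float((k * w).sum() / w.sum())

    q = brentq(lambda x: truncated_mean(x) - mean, 1e-12, 1e6)
    w = q ** (k - 1)
    return w / w.sum()


def _domain_dist(config: SimulationConfig) -> tuple[list[ConceptDomain], np.ndarray]:
    doms = [ConceptDomain(d) for d in config.domain_probs]
    p = np.array([config.domain_probs[d.value] for d in doms])
    return doms, p


def _concrete_domain_dist(config: SimulationConfig) -> tuple[list[ConceptDomain], np.ndarray]:
    """domain_probs restricted to the four concrete domains, renormalized."""
    doms, p = _domain_dist(config)
    keep = [i for i, d in enumerate(doms) if d is not ConceptDomain.X]
    p = p[keep]
    if p.sum() <= 0:
        raise ValueError("domain_probs must put mass on a concrete domain")
    return [doms[i] for i in keep], p / p.sum()


def generate_item_bank(config: SimulationConfig) -> list[TrueItem]:
    """Draw the ground-truth item bank for a simulation run."""
    rng = np.random.default_rng([config.seed, 0])
    count_pmf = concept_count_distribution(config.mean_concepts, config.max_concepts)
    doms, dom_p = _domain_dist(config)
    rels = [RelationOp(r) for r in config.relation_probs]
    rel_p = np.array([config.relation_probs[r.value] for r in rels])
    pool = [parse_icf(c) for c in config.icf_code_pool]
    if any(not isinstance(c, ICFCode) for c in pool):
        raise ValueError("icf_code_pool must contain plain ICF codes")

    bank: list[TrueItem] = []
    for i in range(config.n_items):
        n_concepts = int(rng.choice(np.arange(1, config.max_concepts + 1), p=count_pmf))
        appraisal = (
            AppraisalType.R if rng.random() < config.appraisal_prob_R else AppraisalType.E
        )
        domains = [doms[j] for j in rng.choice(len(doms), size=n_concepts, p=dom_p)]
        relations = tuple(
            rels[j] for j in rng.choice(len(rels), size=n_concepts - 1, p=rel_p)
        )
        units = []
        classifiable = []
        for d in domains:
            if d is ConceptDomain.X:
                units.append(ConceptUnit(d, RaterGeneratedCode(str(rng.choice(_ND_TAGS)))))
                classifiable.append(False)
            else:
                units.append(ConceptUnit(d, pool[int(rng.integers(len(pool)))]))
                classifiable.append(True)
        if rng.random() < config.p_icf_unclassifiable:
            j = int(rng.integers(n_concepts))
            domain = ConceptDomain.X if rng.random() < 0.5 else units[j].domain
            units[j] = ConceptUnit(domain, RaterGeneratedCode(str(rng.choice(_ND_TAGS))))
            classifiable[j] = False
        bank.append(
            TrueItem(
                item_id=f"item{i + 1:04d}",
                true_composite=ItemCode(appraisal, tuple(units), relations),
                icf_classifiable=tuple(classifiable),
            )
        )
    return bank


def _siblings(code: ICFCode, pool: list[ICFCode]) -> list[ICFCode]:
    """Substitution targets: same parent, else same chapter, else any other."""
    same_parent = [
        c
        for c in pool
        if c != code
        and c.component == code.component
        and len(c.digits) == len(code.digits)
        and c.digits[:-1] == code.digits[:-1]
    ]
    if same_parent:
        return same_parent
    same_chapter = [
        c
        for c in pool
        if c != code and c.component == code.component and c.digits[0] == code.digits[0]
    ]
    if same_chapter:
        return same_chapter
    return [c for c in pool if c != code]


def _perturb(item: TrueItem, config: SimulationConfig, rng: np.random.Generator,
             pool: list[ICFCode]) -> ItemCode:
    err = config.rater_error
    if rng.random() < err.e_nc:
        return NC
    code = item.true_composite
    appraisal = code.appraisal
    if rng.random() < err.e_appraisal:
        appraisal = AppraisalType.E if appraisal is AppraisalType.R else AppraisalType.R
    rels = [RelationOp(r) for r in config.relation_probs]
    rel_p = np.array([config.relation_probs[r.value] for r in rels])
    relations = tuple(
        rels[int(rng.choice(len(rels), p=rel_p))] if rng.random() < err.e_relation else r
        for r in code.relations
    )
    cdoms, cdom_p = _concrete_domain_dist(config)
    units = []
    for u in code.concepts:
        domain, spec = u.domain, u.spec
        if rng.random() < err.e_domain:
            domain = cdoms[int(rng.choice(len(cdoms), p=cdom_p))]
        if isinstance(spec, ICFCode) and rng.random() < err.e_icf_substitute:
            sibs = _siblings(spec, pool)
            if sibs:
                spec = sibs[int(rng.integers(len(sibs)))]
        if domain is ConceptDomain.X and isinstance(spec, ICFCode):
            # a rater cannot call a concept open-ended and still ICF-link it
            domain = u.domain
        units.append(ConceptUnit(domain, spec))
    return ItemCode(appraisal, tuple(units), relations)


def _rows_for(item_id: str, rater: str, composite: ItemCode) -> list[ItemCoding]:
    if composite.not_classified:
        icf: tuple = (RaterGeneratedCode("nc"),)
        ipc = NC
    else:
        icf = tuple(u.spec for u in composite.concepts)
        ipc = strip_specs(composite)
    return [
        ItemCoding(item_id, rater, Framework.IPC, ipc),
        ItemCoding(item_id, rater, Framework.ICF, icf),
        ItemCoding(item_id, rater, Framework.COMPOSITE, composite),
    ]


def simulate_raters(bank: list[TrueItem], config: SimulationConfig) -> CodingDataset:
    """Derive two raters' IPC/ICF/composite codings from the truth."""
    rng = np.random.default_rng([config.seed, 1])
    pool = [parse_icf(c) for c in config.icf_code_pool]
    codings: list[ItemCoding] = []
    for item in bank:
        for rater in ("rater1", "rater2"):
            codings.extend(_rows_for(item.item_id, rater, _perturb(item, config, rng, pool)))
    return CodingDataset(codings)


def simulate(config: SimulationConfig) -> tuple[list[TrueItem], CodingDataset]:
    """Generate the truth and the two-rater dataset in one call."""
    bank = generate_item_bank(config)
    return bank, simulate_raters(bank, config)


# ---------------------------------------------------------------------------
# analytic oracles for the error model


def _agree_categorical(probs: np.ndarray, e: float) -> float:
    """P(two raters' final values coincide) for a resample-type error.

    The truth is drawn from ``probs``; each rater independently keeps it
    with probability 1-e or redraws from ``probs``.
    """
    agree = 0.0
    for t, pt in enumerate(probs):
        stay = (1 - e) + e * pt
        others = sum((e * pv) ** 2 for v, pv in enumerate(probs) if v != t)
        agree += pt * (stay**2 + others)
    return agree


def _agree_spec(config: SimulationConfig) -> float:
    """P(two raters keep the same ICF spec), exact over the pool.

    Substitution picks uniformly among a code's sibling set, so coincident
    substitutions agree with probability 1/|siblings|.
    """
    s = config.rater_error.e_icf_substitute
    pool = [parse_icf(c) for c in config.icf_code_pool]
    total = 0.0
    for code in pool:
        k = len(_siblings(code, pool))
        if k == 0:  # nothing to substitute with: the code never changes
            total += 1.0
        else:
            total += (1 - s) ** 2 + (s**2) / k
    return total / len(pool)


def expected_capacity(config: SimulationConfig, framework: Framework) -> float:
    """Closed-form expected classification capacity (percent).

    Capacity requires the item's final codes to be identical between raters
    and free of nc / nd- codes.  For the composite framework that confines
    the calculation to truth-classifiable items (no forced-nd concept); for
    IPC any item except an ``nc`` lapse can qualify.  Requires the base
    domain draw to put no mass on X (the default), where the unclassifiable
    fraction is exactly ``p_icf_unclassifiable``.
    """
    if config.domain_probs.get("X", 0.0) > 0.0:
        raise ValueError("closed form requires domain_probs['X'] == 0")
    err = config.rater_error
    count_pmf = concept_count_distribution(config.mean_concepts, config.max_concepts)
    _, cdom_p = _concrete_domain_dist(config)
    rel_p = np.array(list(config.relation_probs.values()))
    a_app = (1 - err.e_appraisal) ** 2 + err.e_appraisal**2
    a_rel = _agree_categorical(rel_p, err.e_relation)
    a_dom = _agree_categorical(cdom_p, err.e_domain)
    # an X-domain truth concept: raters resample only to concrete domains,
    # so agreement needs both to keep X or both to land on the same domain
    d = err.e_domain
    a_dom_x = (1 - d) ** 2 + d**2 * float((cdom_p**2).sum())
    a_spec = _agree_spec(config)
    p_nd = config.p_icf_unclassifiable
    both_coded = (1 - err.e_nc) ** 2

    total = 0.0
    for c, pc in enumerate(count_pmf, start=1):
        core = a_app * a_rel ** (c - 1)
        if framework is Framework.COMPOSITE:
            # classifiable items only: every concept concrete + ICF-specified
            total += pc * (1 - p_nd) * core * (a_dom * a_spec) ** c
        elif framework is Framework.ICF:
            # agreement on the sorted spec list; domains are irrelevant.
            # order-insensitivity makes this an upper-bound-free approximation
            # only when specs are distinct; treated as a product oracle.
            total += pc * (1 - p_nd) * a_spec**c
        elif framework is Framework.IPC:
            # nd- specs are stripped; the flagged concept is X half the time
            flagged = 0.5 * a_dom_x + 0.5 * a_dom
            total += pc * core * a_dom ** (c - 1) * ((1 - p_nd) * a_dom + p_nd * flagged)
        else:
            raise ValueError(f"unsupported framework {framework}")
    return 100.0 * both_coded * total
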