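"""Krippendorff's alpha for nominal full-item codes, with bootstrap CIs.

Krippendorff's α is a chance-corrected agreement coefficient,

    α = 1 − D_o / D_e,

where D_o is the observed disagreement and D_e the disagreement expected by
chance given the label margins.  It ranges from below 0 (systematic
disagreement) through 0 (agreement at chance level) to 1 (perfect
reliability); 0.667 is conventionally the lowest acceptable level and 0.8 a
good one.  Unlike Cohen's κ it handles any number of coders and missing
values, which suits content-analysis designs.

For nominal data both quantities derive from the **coincidence matrix**: for
every unit (item) with m_u ≥ 2 codable values, each ordered pair of values
from distinct coders contributes 1/(m_u − 1) to cell (j, k).  Then with
margins n_j and total n,

    D_o = Σ_{j≠k} o_jk / n,        D_e = Σ_{j≠k} n_j n_k / (n (n − 1)).

Units are the items, values the canonical *full* item-code strings (one
whole IPC/composite code, or the alphanumerically sorted ICF code list),
rater-generated codes included as ordinary labels.

Confidence intervals are percentile bootstrap over units: items are
resampled with replacement, α recomputed per replicate, and the interval
taken from the replicate distribution.  Replicates on which α is undefined
(no expected disagreement) are redrawn, up to a capped budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coding_model import CodingDataset, Framework

__all__ = [
    "ReliabilityData",
    "AlphaResult",
    "CoincidenceMatrix",
    "AlphaUndefinedError",
    "coincidence_matrix",
    "krippendorff_alpha",
    "bootstrap_ci",
    "alpha_with_ci",
]


class AlphaUndefinedError(ValueError):
    """α is undefined: expected disagreement is zero (a single label)."""


@dataclass
class ReliabilityData:
    """Units × coders nominal labels; ``None`` marks a missing value."""

    units: list[str]
    coders: list[str]
    values: list[list[Optional[str]]]  # shape (n_units, n_coders)

    def __post_init__(self) -> None:
        if len(self.coders) < 2:
            raise ValueError("reliability requires at least two coders")
        for row in self.values:
            if len(row) != len(self.coders):
                raise ValueError("each unit needs one slot per coder")

    @classmethod
    def from_dataset(cls, dataset: CodingDataset, framework: Framework) -> "ReliabilityData":
        raters = dataset.raters(framework)
        by_item = dataset.codes_by_item(framework)
        units = list(by_item)
        values = [
            [
                by_item[i][r].code_string() if r in by_item[i] else None
                for r in raters
            ]
            for i in units
        ]
        return cls(units=units, coders=list(raters), values=values)

    def pairable_units(self) -> list[list[str]]:
        """Per-unit label lists, keeping only units with ≥ 2 values."""
        out = []
        for row in self.values:
            present = [v for v in row if v is not None]
            if len(present) >= 2:
                out.append(present)
        return out


@dataclass
class CoincidenceMatrix:
    """Symmetric label-pair coincidence counts."""

    labels: list[str]
    counts: np.ndarray  # (L, L), float

    @property
    def margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class AlphaResult:
    alpha: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_bootstrap: int = 0
    confidence: float = 0.95
    seed: Optional[int] = None
    unstable: bool = False
    n_units: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap,
            "confidence": self.confidence,
            "seed": self.seed,
            "unstable": self.unstable,
            "n_units": self.n_units,
        }


def _units_coincidence(unit_values: Sequence[Sequence[str]]) -> CoincidenceMatrix:
    labels = sorted({v for row in unit_values for v in row})
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for row in unit_values:
        m = len(row)
        w = 1.0 / (m - 1)
        for a in range(m):
            for b in range(m):
                if a != b:
                    counts[index[row[a]], index[row[b]]] += w
    return CoincidenceMatrix(labels, counts)


def coincidence_matrix(data: ReliabilityData) -> CoincidenceMatrix:
    """Build the coincidence matrix over all pairable units."""
    rows = data.pairable_units()
    if not rows:
        raise ValueError("no unit has two or more coded values")
    return _units_coincidence(rows)


def _alpha_from_matrix(cm: CoincidenceMatrix) -> float:
    n = cm.total
    margins = cm.margins
    d_o = float(cm.counts.sum() - np.trace(cm.counts)) / n
    # sum_{j != k} n_j n_k = (sum n_j)^2 - sum n_j^2
    d_e = float(n * n - (margins**2).sum()) / (n * (n - 1))
    if d_e == 0.0:
        raise AlphaUndefinedError(
            "expected disagreement is zero: all values share one label"
        )
    return 1.0 - d_o / d_e


def krippendorff_alpha(data: ReliabilityData) -> float:
    """Nominal-metric Krippendorff's α for the dataset.

    Raises :class:`AlphaUndefinedError` when every value across all units is
    the same single label (D_e = 0).
    """
    return _alpha_from_matrix(coincidence_matrix(data))


def bootstrap_ci(
    data: ReliabilityData,
    n_bootstrap: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Percentile bootstrap interval for α, resampling units.

    Returns ``(ci_low, ci_high, unstable)``.  Replicates with undefined α
    are redrawn within a 10× draw budget; ``unstable`` is set when more than
    half of all draws had fewer than two distinct labels.
    """
    if not 0.0 <= confidence < 1.0:
        raise ValueError("confidence must be in [0, 1)")
    rows = data.pairable_units()
    if not rows:
        raise ValueError("no unit has two or more coded values")
    rng = np.random.default_rng(seed)
    alphas = np.empty(n_bootstrap)
    got = 0
    draws = 0
    degenerate = 0
    budget = 10 * n_bootstrap
    while got < n_bootstrap and draws < budget:
        idx = rng.integers(0, len(rows), size=len(rows))
        sample = [rows[i] for i in idx]
        draws += 1
        try:
            alphas[got] = _alpha_from_matrix(_units_coincidence(sample))
        except AlphaUndefinedError:
            degenerate += 1
            continue
        got += 1
    if got == 0:
        raise AlphaUndefinedError("every bootstrap replicate had a single label")
    alphas = alphas[:got]
    unstable = degenerate > draws / 2
    tail = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(alphas, [tail, 1.0 - tail])
    return float(lo), float(hi), unstable


def alpha_with_ci(
    data: ReliabilityData,
    n_bootstrap: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
) -> AlphaResult:
    """Point estimate plus bootstrap CI, bundled with its provenance."""
    a = krippendorff_alpha(data)
    lo, hi, unstable = bootstrap_ci(data, n_bootstrap, confidence, seed)
    return AlphaResult(
        alpha=a,
        ci_low=lo,
        ci_high=hi,
        n_bootstrap=n_bootstrap,
        confidence=confidence,
        seed=seed,
        unstable=unstable,
        n_units=len(data.pairable_units()),
    )
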