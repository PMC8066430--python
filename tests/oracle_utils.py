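"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computation paths: metrics are
recomputed by direct enumeration over code strings, and Krippendorff's
alpha by an O(n^2) pairwise sweep that never builds a coincidence matrix.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence


def alpha_pairwise(rows: Sequence[Sequence[Optional[str]]]) -> float:
    """Nominal Krippendorff's alpha by explicit pair enumeration.

    ``rows`` holds one label list per unit (missing values as None).
    Observed disagreement averages the within-unit pair disagreement, each
    unit's pairs weighted by 1/(m_u - 1); expected disagreement enumerates
    every cross-slot pair of values in the pooled sample.
    """
    units = []
    for row in rows:
        present = [v for v in row if v is not None]
        if len(present) >= 2:
            units.append(present)
    if not units:
        raise ValueError("no pairable unit")
    pooled = [v for u in units for v in u]
    n = len(pooled)
    num = 0.0
    for u in units:
        w = 1.0 / (len(u) - 1)
        for a, b in combinations(u, 2):
            num += 2 * w * (a != b)  # both ordered pairs
    d_o = num / n
    dis = sum(a != b for a, b in combinations(pooled, 2)) * 2
    d_e = dis / (n * (n - 1))
    if d_e == 0:
        raise ZeroDivisionError("expected disagreement is zero")
    return 1.0 - d_o / d_e


def metrics_item_codes(pairs: Sequence[tuple[str, str]]) -> dict:
    """Brute-force indicators for a whole-item-code framework.

    ``pairs`` holds each item's two canonical code strings.  A code is
    rater-generated when it is ``nc`` or mentions ``nd-``.
    """
    n = len(pairs)
    agree = [a for a, b in pairs if a == b]
    full = [a == b and "nd-" not in a and a != "nc" for a, b in pairs]
    final = list(agree)
    valid = {c for c in final if "nd-" not in c and c != "nc"}
    rg = {c for c in final if "nd-" in c or c == "nc"}
    overlap = sum(final.count(c) >= 2 for c in final)
    freq: dict[str, int] = {}
    for c in final:
        freq[c] = freq.get(c, 0) + 1
    return {
        "percent_agreement": 100.0 * len(agree) / n,
        "classification_capacity": 100.0 * sum(full) / n,
        "unique_total": len(valid | rg),
        "unique_valid": len(valid),
        "unique_rater_generated": len(rg),
        "content_overlap": 100.0 * overlap / len(final) if final else 0.0,
        "freq": freq,
    }


def metrics_icf_lists(pairs: Sequence[tuple[tuple[str, ...], tuple[str, ...]]]) -> dict:
    """Brute-force indicators for the ICF (code-list) framework."""
    n = len(pairs)
    norm = [(tuple(sorted(a)), tuple(sorted(b))) for a, b in pairs]
    agree = [a for a, b in norm if a == b]
    full = [
        a == b and all(not c.startswith("nd-") for c in a) for a, b in norm
    ]
    codes = {c for lst in agree for c in lst}
    valid = {c for c in codes if not c.startswith("nd-")}
    rg = codes - valid
    overlap = 0
    for i, lst in enumerate(agree):
        others = {c for j, other in enumerate(agree) if j != i for c in other}
        if set(lst) & others:
            overlap += 1
    return {
        "percent_agreement": 100.0 * len(agree) / n,
        "classification_capacity": 100.0 * sum(full) / n,
        "unique_total": len(codes),
        "unique_valid": len(valid),
        "unique_rater_generated": len(rg),
        "content_overlap": 100.0 * overlap / len(agree) if agree else 0.0,
    }


def overlap_topk(final_units: Sequence[Sequence[str]], k: Optional[int]) -> float:
    """Brute-force top-k content overlap over per-item code-unit lists."""
    if not final_units:
        return 0.0
    freq: dict[str, int] = {}
    for units in final_units:
        for c in set(units):
            freq[c] = freq.get(c, 0) + 1
    eligible = set(freq)
    if k is not None:
        eligible = {c for c, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:k]}
    hits = sum(
        any(c in eligible and freq[c] >= 2 for c in set(units)) for units in final_units
    )
    return 100.0 * hits / len(final_units)
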