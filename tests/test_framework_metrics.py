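import itertools

import pytest

from conftest import dataset_from_strings
from oracle_utils import metrics_icf_lists, metrics_item_codes, overlap_topk

from procoding.coding_model import CodingDataset, Framework, ItemCoding, parse_ipc
from procoding.framework_metrics import (
    ConsensusPolicy,
    classification_capacity,
    coding_efficiency,
    compute_metrics,
    content_overlap,
    percent_agreement,
    resolve_final_codings,
    top_codes,
)
from procoding.synthetic_data import RaterErrorRates, SimulationConfig, simulate

IPC = Framework.IPC
ICF = Framework.ICF
COMP = Framework.COMPOSITE


def test_percent_agreement_enumeration():
    """4 items, one disagreement: 75%."""
    ds = dataset_from_strings(
        IPC, {"1": ("R_B", "R_B"), "2": ("R_S", "R_S"), "3": ("R_P", "E_P"), "4": ("R_I", "R_I")}
    )
    assert percent_agreement(ds, IPC) == 75.0


def test_agreement_respects_canonicalization():
    ds = dataset_from_strings(COMP, {"1": ("E_B[b4200]/S[d7100]", "E_S[d7100]/B[b4200]")})
    assert percent_agreement(ds, COMP) == 100.0


def test_capacity_counts_only_fully_classified_agreements():
    """One nd item and one disagreement out of four: capacity 50%."""
    ds = dataset_from_strings(
        COMP,
        {
            "1": ("R_B", "R_B"),
            "2": ("R_S", "R_S"),
            "3": ("R_X[nd-gh]", "R_X[nd-gh]"),
            "4": ("R_P", "E_P"),
        },
    )
    assert classification_capacity(ds, COMP) == 50.0
    assert percent_agreement(ds, COMP) == 75.0


def test_capacity_zero_when_all_nc():
    ds = dataset_from_strings(IPC, {"1": ("nc", "nc"), "2": ("nc", "nc")})
    assert classification_capacity(ds, IPC) == 0.0
    assert percent_agreement(ds, IPC) == 100.0


def test_more_than_two_raters_unsupported():
    codings = [
        ItemCoding("1", r, IPC, parse_ipc("R_B")) for r in ("A", "B", "C")
    ]
    with pytest.raises(ValueError, match="two-rater"):
        percent_agreement(CodingDataset(codings), IPC)


def test_coding_efficiency_ipc_counts():
    """Final codes {R_B, R_B, R_S, R_X with nd}: 3 unique, 1 rater-generated."""
    ds = dataset_from_strings(
        COMP,
        {
            "1": ("R_B", "R_B"),
            "2": ("R_B", "R_B"),
            "3": ("R_S", "R_S"),
            "4": ("R_X[nd-gh]", "R_X[nd-gh]"),
        },
    )
    assert coding_efficiency(ds, COMP) == {
        "unique_total": 3,
        "unique_valid": 2,
        "unique_rater_generated": 1,
    }


def test_coding_efficiency_icf_flattens_lists():
    ds = dataset_from_strings(ICF, {"1": ("b28013;d760", "b28013;d760"), "2": ("d760", "d760")})
    assert coding_efficiency(ds, ICF) == {
        "unique_total": 2,
        "unique_valid": 2,
        "unique_rater_generated": 0,
    }


def test_disagreements_excluded_and_reported():
    ds = dataset_from_strings(IPC, {"1": ("R_B", "E_B"), "2": ("R_S", "R_S")})
    final, unresolved = resolve_final_codings(ds, IPC)
    assert set(final) == {"2"} and unresolved == ["1"]
    assert coding_efficiency(ds, IPC)["unique_total"] == 1


def test_consensus_column_policy():
    codings = [
        ItemCoding("1", "A", IPC, parse_ipc("R_B")),
        ItemCoding("1", "B", IPC, parse_ipc("E_B")),
    ]
    ds = CodingDataset(codings, consensus={("1", IPC): parse_ipc("R_B")})
    final, unresolved = resolve_final_codings(ds, IPC)
    assert not unresolved and str(final["1"]) == "R_B"
    # explicit intersection policy still reports the disagreement
    _, unresolved = resolve_final_codings(ds, IPC, ConsensusPolicy.RATER_INTERSECTION)
    assert unresolved == ["1"]


def test_content_overlap_whole_code():
    ds = dataset_from_strings(
        IPC, {"1": ("R_B", "R_B"), "2": ("R_B", "R_B"), "3": ("R_S", "R_S")}
    )
    assert content_overlap(ds, IPC) == pytest.approx(200 / 3)


def test_content_overlap_all_unique_is_zero():
    ds = dataset_from_strings(IPC, {"1": ("R_B", "R_B"), "2": ("R_S", "R_S")})
    assert content_overlap(ds, IPC) == 0.0


def test_content_overlap_icf_single_code_matching():
    """Items 1 and 2 share d760; item 3 overlaps nobody."""
    ds = dataset_from_strings(
        ICF,
        {"1": ("b28013;d760", "b28013;d760"), "2": ("d760;nd-gh", "d760;nd-gh"), "3": ("e310", "e310")},
    )
    assert content_overlap(ds, ICF) == pytest.approx(200 / 3)


def test_top_codes_frequency_then_alphanumeric():
    ds = dataset_from_strings(
        IPC,
        {
            "1": ("R_B", "R_B"), "2": ("R_B", "R_B"), "3": ("R_B", "R_B"),
            "4": ("E_B", "E_B"), "5": ("E_B", "E_B"), "6": ("E_B", "E_B"),
            "7": ("R_S", "R_S"),
        },
    )
    assert top_codes(ds, IPC, k=2) == [("E_B", 3), ("R_B", 3)]
    assert top_codes(ds, IPC, k=10) == [("E_B", 3), ("R_B", 3), ("R_S", 1)]


def test_top_k_overlap_requires_two_carriers():
    """A top-k code carried by a single item never creates overlap."""
    ds = dataset_from_strings(IPC, {"1": ("R_B", "R_B"), "2": ("R_S", "R_S")})
    assert content_overlap(ds, IPC, top_k=2) == 0.0
    with pytest.raises(ValueError):
        content_overlap(ds, IPC, top_k=0)


def test_metrics_invariant_under_relabeling_and_reordering():
    items = {"1": ("R_B", "R_B"), "2": ("R_S", "E_S"), "3": ("R_X[nd-a]", "R_X[nd-a]")}
    ds1 = dataset_from_strings(COMP, items)
    swapped = {k: (b, a) for k, (a, b) in reversed(list(items.items()))}
    ds2 = dataset_from_strings(COMP, swapped)
    m1, m2 = compute_metrics(ds1, COMP), compute_metrics(ds2, COMP)
    assert (m1.classification_capacity, m1.percent_agreement, m1.unique_total,
            m1.content_overlap) == (
        m2.classification_capacity, m2.percent_agreement, m2.unique_total,
        m2.content_overlap)


# ---------------------------------------------------------------------------
# oracle equivalence and quantified invariants


_CODE_ALPHABET = ("R_B", "R_S", "E_B/S", "R_X[nd-a]")


def _check_against_oracle(assignment):
    pairs = list(assignment)
    ds = dataset_from_strings(
        COMP, {f"i{k}": pair for k, pair in enumerate(pairs)}
    )
    expected = metrics_item_codes(pairs)
    assert percent_agreement(ds, COMP) == pytest.approx(expected["percent_agreement"])
    assert classification_capacity(ds, COMP) == pytest.approx(
        expected["classification_capacity"]
    )
    eff = coding_efficiency(ds, COMP)
    assert eff["unique_total"] == expected["unique_total"]
    assert eff["unique_valid"] == expected["unique_valid"]
    assert eff["unique_rater_generated"] == expected["unique_rater_generated"]
    if expected["freq"]:
        assert content_overlap(ds, COMP) == pytest.approx(expected["content_overlap"])


def test_exhaustive_two_item_datasets_match_oracle():
    """Every 2-rater, 2-item dataset over a 4-code alphabet, exhaustively."""
    cells = list(itertools.product(_CODE_ALPHABET, repeat=2))
    for assignment in itertools.product(cells, repeat=2):
        _check_against_oracle(assignment)


def test_capacity_never_exceeds_agreement_on_simulations():
    for seed in range(5):
        cfg = SimulationConfig(
            n_items=60, seed=seed, rater_error=RaterErrorRates(0.1, 0.1, 0.1, 0.1, 0.05)
        )
        _, ds = simulate(cfg)
        for fw in Framework:
            assert classification_capacity(ds, fw) <= percent_agreement(ds, fw) + 1e-9


def test_topk_overlap_monotone_in_k():
    cfg = SimulationConfig(n_items=80, seed=3)
    _, ds = simulate(cfg)
    for fw in Framework:
        full = content_overlap(ds, fw)
        prev = 0.0
        for k in (1, 2, 5, 10, 50, 10_000):
            cur = content_overlap(ds, fw, top_k=k)
            assert cur >= prev - 1e-9
            prev = cur
        assert prev == pytest.approx(full)


def test_fully_classified_dataset_capacity_equals_agreement():
    cfg = SimulationConfig(
        n_items=50, seed=9, p_icf_unclassifiable=0.0,
        rater_error=RaterErrorRates(0.2, 0.2, 0.2, 0.2, 0.0),
    )
    _, ds = simulate(cfg)
    for fw in Framework:
        assert classification_capacity(ds, fw) == pytest.approx(percent_agreement(ds, fw))


def test_icf_overlap_topk_against_oracle():
    cfg = SimulationConfig(n_items=40, seed=11)
    _, ds = simulate(cfg)
    final, _ = resolve_final_codings(ds, ICF)
    units = [[str(c) for c in lst] for lst in final.values()]
    for k in (1, 3, 5, None):
        assert content_overlap(ds, ICF, top_k=k) == pytest.approx(overlap_topk(units, k))
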