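import json
from pathlib import Path

import pytest

from procoding.coding_model import (
    CodingDataset,
    Framework,
    ItemCoding,
    parse_composite,
    parse_icf,
    parse_ipc,
    read_coding_table,
)

DATA_DIR = Path(__file__).parent / "data"


def dataset_from_strings(framework: Framework, item_pairs: dict) -> CodingDataset:
    """Two-rater dataset from {item: (code_str_A, code_str_B)}.

    ICF-framework code strings are ';'-separated lists.
    """
    codings = []
    for item, (a, b) in item_pairs.items():
        for rater, cell in (("A", a), ("B", b)):
            if framework is Framework.ICF:
                value = tuple(parse_icf(p) for p in cell.split(";"))
            elif framework is Framework.IPC:
                value = parse_ipc(cell)
            else:
                value = parse_composite(cell)
            codings.append(ItemCoding(item, rater, framework, value))
    return CodingDataset(codings)


@pytest.fixture(scope="session")
def fixture_dataset() -> CodingDataset:
    return read_coding_table(DATA_DIR / "fixture_coding.tsv")


@pytest.fixture(scope="session")
def fixture_expected() -> dict:
    with open(DATA_DIR / "fixture_expected.json", encoding="utf-8") as fh:
        return json.load(fh)
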