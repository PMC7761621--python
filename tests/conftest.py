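import pytest

from ptmquant import datasets
from ptmquant.evidence import PSMRecord
from ptmquant.modifications import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def vdac1():
    return datasets.load_vdac1()


@pytest.fixture(scope="session")
def vdac_proteins():
    return tuple(datasets.load_vdac_proteins())


def make_psm(
    sequence="PEPTIDEK",
    deamidated_positions=(),
    raw_file="run_01",
    charge=2,
    intensity=1e6,
    protein="P1",
):
    """PSMRecord builder for tests; deamidated positions are 1-based."""
    mods = tuple(("deamidation", p) for p in sorted(deamidated_positions))
    parts, cursor = ["_"], 0
    for _name, pos in mods:
        parts.append(sequence[cursor:pos])
        parts.append("(de)")
        cursor = pos
    parts.append(sequence[cursor:])
    parts.append("_")
    return PSMRecord(
        raw_file=raw_file,
        sequence=sequence,
        modified_sequence="".join(parts),
        modifications=mods,
        charge=charge,
        intensity=intensity,
        proteins=(protein,),
        leading_razor_protein=protein,
    )
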