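import io
import random

import pytest

from snprflp import default_fixture_enzymes, parse_enzyme_table

ENZYME_TABLE = """\
# name\tsite\tsuppliers\tprice
EcoRI\tG^AATTC\tN\t62
BsaI\tGGTCTC(1/5)\tN\t75
HinfI\tG^ANTC\tN\t60
AluI\tAG^CT\tN\t58
AccI\tGT^MKAC\tN\t70
"""


@pytest.fixture(scope="session")
def small_enzymes():
    enzymes, _ = parse_enzyme_table(io.StringIO(ENZYME_TABLE))
    return {e.name: e for e in enzymes}


@pytest.fixture(scope="session")
def panel():
    """The built-in fixture enzyme panel (15 common enzymes)."""
    return default_fixture_enzymes()


@pytest.fixture()
def rng():
    return random.Random(20240901)


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
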