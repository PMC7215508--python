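import numpy as np
import pytest

from cassarray import queries, simulate


def random_seq(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# exact concrete expansions of the Cassandra motifs, used to build
# hand-checkable constructs: boxA + 18 nt + boxC + 30 nt + PBS = 85 nt
BOXA_CONCRETE = "AGTTAAGTATGT"
BOXC_CONCRETE = "AAAATAGGTAACT"


def cassandra_construct(gap_ab: int = 18, gap_cp: int = 30, fill: str = "C") -> str:
    return (
        BOXA_CONCRETE + fill * gap_ab + BOXC_CONCRETE + fill * gap_cp + queries.PBS
    )


@pytest.fixture(scope="session")
def cassandra_query():
    return queries.parse_query(queries.CASSANDRA_QUERY)


@pytest.fixture(scope="session")
def tandem_query():
    return queries.parse_query(queries.CASSANDRA_TANDEM_QUERY)


@pytest.fixture(scope="session")
def avena_unit():
    """Default unit: 229 nt LTR + 252 nt internal domain (481 nt period)."""
    return simulate.make_unit(simulate.UnitSpec(seed=11))


@pytest.fixture(scope="session")
def avena_array(avena_unit):
    """Six units head-to-tail plus the closing LTR."""
    return simulate.make_array(avena_unit.seq, 6, avena_unit.ltr)
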