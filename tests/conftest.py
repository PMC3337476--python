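import pytest

from macontrast import Genome, make_genome, uniform_usage_table


@pytest.fixture
def toy_genome() -> Genome:
    return Genome("toy", "ACGTAGATCGA")


@pytest.fixture(scope="session")
def genome_100k() -> Genome:
    return make_genome(100_000, 0.508, seed=20_240_001)


@pytest.fixture(scope="session")
def uniform_table():
    return uniform_usage_table()


# Printed per-offset G/C counts for the two published mutation sets, offsets
# -5..+5 with the mutated site in the middle; used across context tests.
COUNTS_23 = [16, 10, 16, 18, 15, 16, 15, 10, 13, 10, 11]
COUNTS_80 = [40, 50, 40, 42, 61, 61, 39, 51, 38, 33, 57]


@pytest.fixture(scope="session")
def published_counts():
    return {
        "genome_wide": {"counts": COUNTS_23, "n": 23, "p": 0.508},
        "lacI": {"counts": COUNTS_80, "n": 80, "p": 0.563},
    }
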