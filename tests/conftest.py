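import numpy as np
import pytest

from orgmut import synth
from orgmut.orgmodel import OrganelleGenome, RegionIndex, parse_repeat_row

# Printed rows of the published mtDNA repeat catalog (name, copy1, copy2,
# percent identity, length); copy2 printed descending marks an inverted pair.
TABLE1_ROWS = [
    ("A", "19,682-20,237", "346,208-346,763", 99.82, 556),
    ("B", "41,464-41,999", "321,967-321,431", 99.81, 537),
    ("G", "30,938-31,272", "271,395-271,061", 99.40, 335),
    ("MMJS", "134,427-135,193", "257,452-258,143", 88.66, 767),
    ("D", "6118-6569", "84,540-84,089", 97.79, 452),
    ("L", "270,775-271,023", "331,877-332,125", 100, 249),
    ("EE", "65,547-65,673", "73,611-73,737", 99.21, 127),
    ("F", "206,095-206,444", "246,766-247,115", 100, 350),
    ("X", "288,315-288,518", "306,969-307,174", 97.57, 206),
    ("I", "30,442-30,722", "255,122-254,842", 99.64, 281),
    ("C", "36,362-36,824", "144,409-143,947", 99.57, 463),
]


@pytest.fixture(scope="session")
def table1_repeats():
    return [parse_repeat_row(*row) for row in TABLE1_ROWS]


@pytest.fixture(scope="session")
def tiny_genome():
    return OrganelleGenome("tiny", "AACGT")


@pytest.fixture(scope="session")
def synth_reference():
    """A 30-kb genome with genes and one direct + one inverted repeat."""
    genome, features, repeats = synth.simulate_genome(
        30_000,
        n_genes={"CDS": 4, "intron": 1, "rRNA": 1, "tRNA": 2},
        repeat_specs=[(300, 100.0, "direct"), (300, 99.0, "inverted")],
        seed=7,
    )
    return genome, features, repeats


@pytest.fixture(scope="session")
def synth_region_index(synth_reference):
    genome, features, _ = synth_reference
    return RegionIndex(genome, features)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
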