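import numpy as np
import pytest

from petei.fixtures import FixtureSpec, make_loop_corpus, make_rigged_benchmark, make_scaffold

MINI_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.401   2.441   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.032   2.800   0.100  1.00  0.00           C
ATOM      7  C   ALA A   2       5.530   2.705   0.001  1.00  0.00           C
ATOM      8  O   ALA A   2       6.132   1.642   0.002  1.00  0.00           O
ATOM      9  CB AALA A   2       3.521   3.702   1.221  0.60  0.00           C
ATOM     10  CB BALA A   2       3.600   3.800   1.300  0.40  0.00           C
ATOM     11  N   GLY A   3       6.151   3.867   0.000  1.00  0.00           N
ATOM     12  CA  GLY A   3       7.601   3.912   0.050  1.00  0.00           C
ATOM     13  C   GLY A   3       8.155   5.330   0.020  1.00  0.00           C
ATOM     14  O   GLY A   3       7.420   6.322   0.010  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def mini_pdb_text() -> str:
    return MINI_PDB


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def scaffold_and_specs(fixture_spec):
    return make_scaffold(fixture_spec)


@pytest.fixture(scope="session")
def corpus_and_labels(fixture_spec, scaffold_and_specs):
    scaffold, specs = scaffold_and_specs
    return make_loop_corpus(fixture_spec, scaffold, specs)


@pytest.fixture(scope="session")
def rigged():
    return make_rigged_benchmark(FixtureSpec(seed=0, rigged=True))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
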