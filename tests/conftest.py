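import numpy as np
import pytest

from famseq_assoc.genotypes import finalize_matrix
from famseq_assoc.pedigree import Individual


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def write_ped(tmp_path):
    """Write whitespace-separated pedigree lines to a temp file."""

    def _write(lines, name="pedigree.fam"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def trio():
    return [
        Individual("dad", "F1", None, None, "male", "control"),
        Individual("mom", "F1", None, None, "female", "control"),
        Individual("kid", "F1", "dad", "mom", "male", "case"),
    ]


def make_matrix(dosage, positions=None, chrom="1"):
    """Finalized GenotypeMatrix from an integer ALT-dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = range(100, 100 + 10 * m, 10)
    ids = [f"i{k}" for k in range(n)]
    raw = [(chrom, int(p), "A", "T") for p in positions]
    return finalize_matrix(ids, raw, dosage)


@pytest.fixture
def matrix_factory():
    return make_matrix
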