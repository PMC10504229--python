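import os

import numpy as np
import pytest

from gwhap.io_formats import read_trait_table
from gwhap.types import ALT_HOM, HET, MISSING, REF_HOM, GenotypePanel

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")
TABLE1_CSV = os.path.join(DATA_DIR, "table1_aac.csv")


def make_panel(calls, chrom=None, pos=None, ref=None, alt=None):
    """Build a valid GenotypePanel around a call matrix (acc x snp)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_snp = calls.shape
    if chrom is None:
        chrom = ["chr01"] * n_snp
    if pos is None:
        pos = list(range(100, 100 + 10 * n_snp, 10))
    if ref is None:
        ref = ["A"] * n_snp
    if alt is None:
        alt = ["G"] * n_snp
    return GenotypePanel(
        accession_ids=[f"ACC{i:03d}" for i in range(n_acc)],
        snp_ids=[f"{c}_{p}" for c, p in zip(chrom, pos)],
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        calls=calls,
    )


def random_panel(rng, n_acc=10, n_snp=8, p_missing=0.1, p_het=0.05):
    """Random panel with hets and missing calls for fuzz tests."""
    u = rng.random((n_acc, n_snp))
    calls = np.where(rng.random((n_acc, n_snp)) < 0.5, REF_HOM, ALT_HOM)
    calls = np.where(u < p_het, HET, calls)
    calls = np.where(u > 1.0 - p_missing, MISSING, calls)
    return make_panel(calls.astype(np.int8))


@pytest.fixture(scope="session")
def table1():
    return read_trait_table(TABLE1_CSV)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
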