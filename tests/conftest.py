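import numpy as np
import pytest

from peagbs import io_formats as io
from peagbs import synthetic_gbs as sg


@pytest.fixture(scope="session")
def small_truth():
    """3-group structured collection with known truth (60 accessions)."""
    cfg = sg.SimConfig(
        n_groups=3, accessions_per_group=20, n_loci=100, divergence=0.25,
        seed=2,
    )
    return sg.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_cfg(small_truth):
    return small_truth.config


def make_catalog(loci, alleles=("A", "G"), length=64, offset=10):
    """Deterministic toy catalog: fixed tag with the A allele at the offset."""
    base = ("ACGT" * 20)[:length]
    records = []
    for i, locus in enumerate(loci):
        seq = list(base)
        seq[offset] = alleles[0]
        records.append(
            io.TagRecord(
                locus, "".join(seq), offset, alleles[0], alleles[1],
                io.UNEAK if length == 64 else io.STACKS,
            )
        )
    return io.TagCatalog(records)


def make_gm(calls, loci=None, accessions=None):
    calls = np.asarray(calls, dtype=np.int8)
    loci = loci or [f"L{i}" for i in range(calls.shape[0])]
    accessions = accessions or [f"S{j}" for j in range(calls.shape[1])]
    return io.GenotypeMatrix(loci, accessions, calls)
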