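import numpy as np
import pytest

import snphase as sp
from snphase.reads import AlignedRead


def make_read(start, bases, name="r", strand="+", mapq=60, quals=None,
              insertions=None, deletions=None, haplotype=0, truth_hap=0):
    """Hand-build a dense AlignedRead; 'D' in ``bases`` marks deletions."""
    syms = np.array([{"A": 0, "C": 1, "G": 2, "T": 3, "D": 4}[b]
                     for b in bases], dtype=np.int8)
    if quals is None:
        q = np.full(len(bases), 20, dtype=np.int16)
    else:
        q = np.asarray(quals, dtype=np.int16)
    q[syms == 4] = -1
    return AlignedRead(name=name, strand=strand, mapq=mapq, start=start,
                       end=start + len(bases), syms=syms, quals=q,
                       insertions=dict(insertions or {}),
                       deletions=list(deletions or []),
                       haplotype=haplotype, truth_haplotype=truth_hap)


@pytest.fixture(scope="session")
def genome_50k():
    return sp.generate_diploid(50_000, snp_rate=0.001, het_fraction=2 / 3,
                               indel_rate=0.0002, seed=7)


@pytest.fixture(scope="session")
def readset_50k(genome_50k):
    return sp.simulate_reads(genome_50k, coverage=16.0,
                             error_model=(0.04, 0.01, 0.01), seed=3)


@pytest.fixture(scope="session")
def reads_50k(readset_50k):
    return readset_50k.aligned_reads()


@pytest.fixture(scope="session")
def pileup_50k(genome_50k, reads_50k):
    return sp.build_pileup(reads_50k, genome_50k.contig, 0, len(genome_50k),
                           reference=genome_50k.reference)
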