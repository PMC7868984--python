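import numpy as np
import pytest
from hypothesis import settings

from polysv import GenomeLayout, SimParams, SVCallSet, SVRecord

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def make_record(sample="s1", chrom="A01", pos=1000, svtype="DEL", svlen=700,
                filter_status="PASS", support=("AL",), read_support=10,
                precise=True):
    end = pos if svtype == "INS" else pos + svlen
    if svtype == "TRA":
        end = pos
    return SVRecord(sample_id=sample, chrom=chrom, pos=pos, end=end,
                    svtype=svtype, svlen=svlen, filter_status=filter_status,
                    support_types=frozenset(support),
                    read_support=read_support, precise=precise)


def random_callset(rng: np.random.Generator, sample="s1", n=50,
                   chroms=("A01", "C01"), pos_max=500_000,
                   types=("DEL", "INS", "INV")) -> SVCallSet:
    records = []
    for _ in range(n):
        svtype = str(rng.choice(types))
        svlen = int(rng.integers(30, 5000))
        pos = int(rng.integers(1, pos_max))
        records.append(make_record(
            sample=sample, chrom=str(rng.choice(chroms)), pos=pos,
            svtype=svtype, svlen=svlen,
            filter_status=str(rng.choice(["PASS", "UNRESOLVED"])),
            support=[("AL",), ("SR",), ("AL", "SR")][int(rng.integers(0, 3))],
            read_support=int(rng.integers(1, 40)),
            precise=bool(rng.integers(0, 2))))
    return SVCallSet(sample_id=sample, records=records)


@pytest.fixture
def small_layout():
    return GenomeLayout([("A01", 2_000_000), ("A02", 1_500_000),
                         ("C01", 2_000_000), ("C02", 1_500_000)])


@pytest.fixture
def small_params(small_layout):
    """Scaled-down panel for fast per-test runs; statistical structure is
    unchanged (3 groups x 4 samples, shared >> private, default decoys)."""
    return SimParams(seed=7, layout=small_layout, n_shared_per_group=30,
                     n_private_per_sample=7, gene_density=40.0)


@pytest.fixture
def small_panel(small_params):
    from polysv import simulate_panel

    return simulate_panel(small_params)
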