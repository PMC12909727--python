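import numpy as np
import pytest

from hapdiv.variant_io import VariantRecord


def make_record(pos=100, ref="A", alts=("G",), qual=50.0, depth=30.0, mq=50.0,
                genotypes=((0, 0), (0, 1)), chrom="chr04"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                         qual=qual, depth=depth, mapping_quality=mq,
                         genotypes=tuple(genotypes))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def random_records(rng):
    """100 records with randomised quality annotations straddling the filter
    thresholds, for brute-force filter-oracle comparison."""
    records = []
    pos = 0
    for _ in range(100):
        pos += int(rng.integers(1, 50))
        n_alts = int(rng.integers(1, 3))
        alts = tuple(np.random.default_rng(pos).choice(list("CGT"), n_alts, replace=False))
        is_indel = rng.random() < 0.2
        ref = "AT" if is_indel else "A"
        records.append(make_record(
            pos=pos, ref=ref, alts=alts,
            qual=float(rng.uniform(20, 40)),
            depth=float(rng.integers(5, 15)),
            mq=float(rng.uniform(35, 45)),
            genotypes=tuple(
                (int(a), int(a)) for a in rng.integers(0, n_alts + 1, size=4)
            ),
        ))
    return records
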