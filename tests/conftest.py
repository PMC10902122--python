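import numpy as np
import pytest

from drugmr.sumstats import HarmonizedRecord, HarmonizedSet, SummaryRecord


def make_record(
    variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
    beta=0.1, se=0.01, pval=1e-10, eaf=0.3, n=10000,
):
    return SummaryRecord(
        variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=oa, beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_hset(bx, sx, by, sy):
    records = [
        HarmonizedRecord(
            variant_id=f"rs{i + 1}", beta_exposure=float(x), se_exposure=float(s1),
            beta_outcome=float(y), se_outcome=float(s2), eaf=0.3, chrom="1",
            pos=1000 * (i + 1),
        )
        for i, (x, s1, y, s2) in enumerate(zip(bx, sx, by, sy))
    ]
    return HarmonizedSet(records=records)


def random_hset(rng, j=8, slope=0.5):
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.01, 0.06, j)
    by = slope * bx + rng.normal(0, sy)
    return make_hset(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hset8(rng):
    """Deterministic 8-instrument harmonized set with true slope 0.5."""
    return random_hset(rng, j=8, slope=0.5)
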