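import numpy as np
import pytest

from mrscreen.sumstats_io import (
    GwasRecord,
    HarmonizedSet,
    HarmonizedVariant,
    SummaryDataset,
)


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-6,
    n=10000,
):
    return GwasRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_harmonized(bx, by, sy, sx=None, n_exp=10000, n_out=100000, px=None, py=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    px = np.full_like(bx, 1e-8) if px is None else np.asarray(px, dtype=float)
    py = np.full_like(bx, 0.5) if py is None else np.asarray(py, dtype=float)
    variants = [
        HarmonizedVariant(
            variant_id=f"rs{i + 1}",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            pval_exp=float(px[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            pval_out=float(py[i]),
        )
        for i in range(len(bx))
    ]
    return HarmonizedSet(
        exposure_id="exp",
        outcome_id="out",
        variants=variants,
        n_exposure=n_exp,
        n_outcome=n_out,
    )


@pytest.fixture
def three_point_set():
    """The worked 3-variant fixture used across estimator tests."""
    return make_harmonized(
        bx=[0.1, 0.2, 0.3], by=[0.05, 0.12, 0.14], sy=[0.01, 0.02, 0.03]
    )


@pytest.fixture
def exact_ratio_set():
    """Five variants whose ratios all equal 0.4 exactly."""
    bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    return make_harmonized(bx=bx, by=0.4 * bx, sy=np.full(5, 0.02))


def random_harmonized(rng, k=None):
    """Random small instance for oracle-equivalence checks."""
    k = k or int(rng.integers(3, 9))
    bx = rng.normal(0.2, 0.05, k) * rng.choice([-1, 1], k)
    by = rng.normal(0.0, 0.05, k)
    sy = rng.uniform(0.01, 0.1, k)
    return make_harmonized(bx=bx, by=by, sy=sy)
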