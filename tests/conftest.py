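import numpy as np
import pytest

from cohortval.genotype_io import GenotypeMatrix, SampleMeta, VariantKey


def make_variants(n, chrom="1", start_pos=1000, ref="A", alt="G", prefix="v"):
    return [VariantKey(chrom, start_pos + 10 * j, ref, alt, id=f"{prefix}{j}")
            for j in range(n)]


def make_matrix(calls, chrom="1", sexes=None, ref="A", alt="G"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sexes = sexes or ["unknown"] * n
    samples = [SampleMeta(f"S{i}", reported_sex=sexes[i]) for i in range(n)]
    return GenotypeMatrix(calls, make_variants(m, chrom=chrom, ref=ref, alt=alt),
                          samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    # 3 samples x 4 variants with one missing call
    return make_matrix([[0, 1, 2, -1],
                        [1, 1, 0, 2],
                        [2, 0, 1, 1]])
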