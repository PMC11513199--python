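import numpy as np
import pytest

from opilio.core import EmbryoRecord, genotype


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170416)


def make_embryos(patterns, mother=(100, 102), loci=("L1", "L2", "L3"), fid="F1"):
    """Embryos from per-locus paternal-allele patterns; maternal alternates."""
    out = []
    for i, pat in enumerate(patterns):
        geno = {}
        for li, locus in enumerate(loci[: len(pat)]):
            mat = mother[i % 2]
            geno[locus] = genotype(mat, pat[li])
        out.append(EmbryoRecord(fid, f"E{i}", geno))
    return out


def hwe_sample(rng, freqs, n):
    """n diploid genotypes drawn from Hardy-Weinberg proportions."""
    labels = sorted(freqs)
    p = np.array([freqs[a] for a in labels])
    draws = rng.choice(len(labels), size=(n, 2), p=p)
    return [genotype(labels[i], labels[j]) for i, j in draws]
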