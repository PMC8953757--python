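import numpy as np
import pytest
from hypothesis import settings

import codonadapt as ca

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def host_profile() -> ca.CodonUsageVector:
    return ca.gen_host_profile(0.65, seed=11)


@pytest.fixture(scope="session")
def gene_set(host_profile):
    """Default-scale synthetic gene set: 156 genes, adaptation gradient,
    12 cognate-boosted hypothetical genes."""
    return ca.gen_gene_set(ca.GeneSetSpec(seed=11), host_profile)


@pytest.fixture(scope="session")
def small_gene_set(host_profile):
    return ca.gen_gene_set(ca.GeneSetSpec(n_genes=10, n_boosted=0, seed=7), host_profile)


def hypergeom_pmf_oracle(j: int, K: int, n: int, N: int) -> float:
    """Independent hypergeometric PMF from binomial coefficients."""
    from math import comb

    return comb(K, j) * comb(N - K, n - j) / comb(N, n)


def hypergeom_tails_oracle(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    lo, hi = max(0, n + K - N), min(n, K)
    p_enrich = sum(hypergeom_pmf_oracle(j, K, n, N) for j in range(k, hi + 1))
    p_deplete = sum(hypergeom_pmf_oracle(j, K, n, N) for j in range(lo, k + 1))
    return p_enrich, p_deplete
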