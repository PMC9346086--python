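import pytest

from unguardedx import LociCollection, LocusParams, LocusDistributionSpec, sample_loci


@pytest.fixture
def reference_locus() -> LocusParams:
    """A locus well inside the strong-selection regime: p_hat = 1e-4."""
    return LocusParams(mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.25)


@pytest.fixture
def identical_loci() -> LociCollection:
    """100 identical equal-sex loci with h = 0.25 (exact-identity case)."""
    locus = LocusParams(
        mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.25, alpha_f=0.3, alpha_m=0.3
    )
    return LociCollection.from_loci([locus] * 100)


@pytest.fixture(scope="session")
def distributed_loci() -> LociCollection:
    """10^4 loci with dominance spread around 0.25 on (0, 0.5)."""
    spec = LocusDistributionSpec(n_loci=10_000, seed=1)
    return sample_loci(spec)
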