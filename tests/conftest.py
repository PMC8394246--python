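import numpy as np
import pytest

from chen_ghcs import (
    ChenParams,
    GammaPrior,
    GHCSDesign,
    SufficientStats,
    apply_ghcs,
    load_electrical,
)


@pytest.fixture(scope="session")
def toy_stats() -> SufficientStats:
    """Hand-checkable reduction: times (ln2, ln3) with n=4, case III at r=2,
    beta=1 gives Q = 1 + 2 + 2*2 = 7."""
    return SufficientStats(m=2, Q=7.0)


@pytest.fixture(scope="session")
def toy_prior() -> GammaPrior:
    return GammaPrior(a=1.0, b=1.0)


@pytest.fixture(scope="session")
def electrical():
    return load_electrical()


@pytest.fixture(scope="session")
def electrical_sample(electrical):
    return apply_ghcs(electrical, GHCSDesign(n=60, k=15, r=18, T=2.0))


@pytest.fixture(scope="session")
def table1_settings():
    """The first simulation configuration of the study: lam=4.37, beta=1,
    n=50, r=40, k=30, T=0.2, prior (0.6119, 0.1523), h=1.5, c=1, t=0.07."""
    return dict(
        params=ChenParams(4.37, 1.0),
        design=GHCSDesign(n=50, k=30, r=40, T=0.2),
        prior=GammaPrior(0.6119, 0.1523),
        h=1.5,
        c=1.0,
        t=0.07,
    )
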