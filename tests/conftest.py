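import numpy as np
import pandas as pd
import pytest

from ecdose import (
    CountMatrix,
    PromoterArchitecture,
    ReceptorParams,
    SimulationSpec,
    simulate_counts,
    simulate_reporters,
)

#: Receptor/promoter values the archetype dose-response curves are
#: illustrated with (single functional ERE, no constitutive element).
FIG_PARAMS = dict(kappa_P=0.1, kappa_R_bar=1.0, C_ER=0.1, C_EA=10.0)


@pytest.fixture(scope="session")
def receptor() -> ReceptorParams:
    return ReceptorParams(kappa_R_bar=1.0, K_E=65.0)


@pytest.fixture(scope="session")
def ere_arch() -> PromoterArchitecture:
    return PromoterArchitecture(
        n_ere=1, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=0.1
    )


@pytest.fixture(scope="session")
def synthetic_counts():
    """Small labeled count matrix shared by pipeline tests."""
    spec = SimulationSpec(seed=11)
    return simulate_counts(spec)


@pytest.fixture(scope="session")
def clean_reporters():
    """Noise-free reporter dataset (exact model curves)."""
    return simulate_reporters(sigma=0.0, seed=5)


@pytest.fixture(scope="session")
def noisy_reporters():
    return simulate_reporters(sigma=0.10, replicates=3, seed=5)


@pytest.fixture()
def toy_counts() -> CountMatrix:
    """2 doses x 2 replicates, 4 genes, hand-checkable."""
    counts = pd.DataFrame(
        {
            "d0_r1": [10, 20, 30, 100],
            "d0_r2": [12, 18, 33, 90],
            "d20_r1": [20, 40, 60, 100],
            "d20_r2": [22, 38, 66, 110],
        },
        index=pd.Index(["a", "b", "c", "d"], name="gene"),
    )
    samples = pd.DataFrame(
        {
            "dose_nM": [0.0, 0.0, 20.0, 20.0],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return CountMatrix(counts=counts, samples=samples)
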