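import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from betadecay.incidence import IncidenceAssemblage
from betadecay.simulate import (
    StudyDesignConfig,
    TurnoverParams,
    TraitConfig,
    simulate_dataset,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked_assemblage():
    """T=4, Y=(1,1,2): S_obs=3, U=4, Q1=2, Q2=1, C_hat=0.625."""
    return IncidenceAssemblage(T=4, Y=np.array([1, 1, 2]))


def small_design() -> StudyDesignConfig:
    """A 9-region miniature of the full design (27 plots, T=16)."""
    return StudyDesignConfig(
        n_regions=9,
        landscape_quotas=(3, 3, 3),
        plots_per_landuse=(7, 7, 7, 6),
        rng_seed=11,
    )


def small_turnover(p_det: float = 0.3, pool: int = 80):
    return {
        "forest": TurnoverParams(sigma_km=110.0, p_det=p_det, pool_size=pool),
        "grassland": TurnoverParams(sigma_km=200.0, p_det=p_det, pool_size=pool),
        "arable": TurnoverParams(sigma_km=70.0, p_det=p_det, pool_size=pool),
        "settlement": TurnoverParams(sigma_km=70.0, p_det=p_det, pool_size=pool),
    }


@pytest.fixture(scope="session")
def small_dataset():
    """(metadata, unit incidence, pool, traits) at miniature scale."""
    return simulate_dataset(
        small_design(), small_turnover(), TraitConfig(), seed=7
    )


def random_unit_matrix(rng, S, T, p=0.4, require_nonempty=True) -> np.ndarray:
    """Random binary species x units matrix with at least one detection."""
    for _ in range(100):
        X = (rng.random((S, T)) < p).astype(np.uint8)
        if not require_nonempty or X.sum() > 0:
            return X
    raise RuntimeError("could not draw a non-empty matrix")
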