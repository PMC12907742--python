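import numpy as np
import pytest

from admarkov import uk_reference_parameters
from admarkov.bands import N_BANDS


@pytest.fixture(scope="session")
def ref_params():
    """Packaged UK reference parameter set (deterministic synthetic population)."""
    return uk_reference_parameters()


@pytest.fixture(scope="session")
def flat_pop_params(ref_params):
    """Reference parameters over a flat population: 100,000 persons per cell,
    constant over time — makes per-cell arithmetic transparent."""
    from dataclasses import replace

    pop = {
        y: np.full((N_BANDS, 2), 100_000.0)
        for y in range(ref_params.base_year, ref_params.horizon_year + 1)
    }
    return replace(ref_params, population=pop)
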