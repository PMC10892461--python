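import numpy as np
import pytest

from leafnir.simulate import DesignSpec, default_components, generate_nir_set
from leafnir.spectra import SampleMeta, SampleState, SpectraSet, SpectrumKind


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


def make_meta(i, level=None, rep=None, state=SampleState.DRY, cas=0.6, nit=0.2):
    return SampleMeta(
        sample_id=f"s{i}",
        level_id=level if level is not None else i,
        replicate_id=rep if rep is not None else 1,
        state=state,
        casein_conc=cas,
        nitrate_conc=nit,
    )


def make_set(matrix, grid=None, kind=SpectrumKind.ABSORBANCE, metas=None):
    matrix = np.asarray(matrix, dtype=float)
    if grid is None:
        grid = 4000.0 + 6.0 * np.arange(matrix.shape[1])
    if metas is None:
        metas = [make_meta(i) for i in range(matrix.shape[0])]
    return SpectraSet(grid=grid, matrix=matrix, samples=metas, kind=kind)


@pytest.fixture
def noise_free_design():
    """Deterministic Beer-Lambert mixtures: no noise, gain, drift or shifts."""
    return DesignSpec(
        noise_sd=0.0,
        scatter_sd=0.0,
        baseline_scale=0.0,
        cellulose_gain_sd=0.0,
        water_content_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def dry_campaign():
    """One moderate-noise dry campaign shared across read-only tests."""
    return generate_nir_set(DesignSpec(seed=5))


@pytest.fixture(scope="session")
def components():
    return default_components()
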