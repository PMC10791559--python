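import numpy as np
import pytest

from myoquant.imgeo import RegionMask
from myoquant.phantom import PhantomSpec, make_myocyte_stack


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free, blur-free myocyte phantom with known enrichment."""
    spec = PhantomSpec(
        cell_length_um=40.0, cell_width_um=15.0,
        lateral_enrichment=2.0, icd_enrichment=3.0,
        cluster_density_pct=5.0, cluster_radius_um=0.25,
        apply_psf=False, apply_noise=False, seed=11,
    )
    return make_myocyte_stack(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, shape=(48, 48), pitch=0.1):
    """Random connected-ish blob mask for geometry oracles."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    mask = field > np.quantile(field, 0.7)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return RegionMask(mask, pitch)
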