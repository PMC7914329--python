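import dataclasses

import numpy as np
import pytest

from petrad import PhantomConfig, SUVImage, VOIMask, generate_cohort
from petrad.discretization import DiscretizationSetting, DiscretizedVOI


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sphere_case():
    """Hard-edged sphere (radius 20 mm, SUV 20) on a SUV-2 background at
    4 mm isotropic voxels, with its exact truth mask."""
    sp = 4.0
    n = 33
    ax = (np.arange(n) - n // 2) * sp
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    truth = r <= 20.0
    image = SUVImage(np.where(truth, 20.0, 2.0), (sp,) * 3)
    return image, VOIMask(truth, (sp,) * 3, label="truth")


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-lesion cohort, enough to exercise every archetype cheaply."""
    cfg = dataclasses.replace(PhantomConfig(), n_lesions=6, n_patients=5, seed=7)
    records, manifest = generate_cohort(cfg)
    return records, manifest


def random_disc(rng, shape=(5, 5, 5), n_levels=6, mask_p=0.8) -> DiscretizedVOI:
    """A random small DiscretizedVOI for oracle comparisons."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedVOI(
        levels=levels,
        mask=mask,
        n_bins=64,
        setting=DiscretizationSetting(),
        bin_width=60.0 / 64,
        spacing=(4.0, 4.0, 4.0),
    )
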