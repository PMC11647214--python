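"""Shared fixtures: small phantoms and their fits, built once per session."""

import numpy as np
import pytest

from perilesion.phantom import (BundleDef, LesionDef, PhantomSpec,
                                default_spec, generate_phantom)
from perilesion.tensor import fit_dti, fit_free_water


@pytest.fixture(scope="session")
def registry():
    from perilesion.registry import load_registry
    return load_registry()


@pytest.fixture(scope="session")
def crossing_phantom():
    """Noiseless 15^3 phantom with two crossing bundles and a lesion."""
    spec = default_spec(grid_shape=(15, 15, 15), noise_sigma=0.0, seed=11)
    data, truth = generate_phantom(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def crossing_dti(crossing_phantom):
    _, data, _ = crossing_phantom
    return fit_dti(data)


@pytest.fixture(scope="session")
def single_bundle_spec():
    """One straight bundle filling the grid center, uniform free water."""
    return PhantomSpec(
        grid_shape=(5, 5, 5),
        bundle_defs=(BundleDef("CC_4", axis=(1, 0, 0), center_mm=(5, 5, 5),
                               radius_mm=20.0),),
        lesion_def=None, fw_background=0.3, noise_sigma=0.0, seed=5)


@pytest.fixture(scope="session")
def single_bundle_fw(single_bundle_spec):
    data, truth = generate_phantom(single_bundle_spec)
    maps = fit_free_water(data)
    return truth, maps
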