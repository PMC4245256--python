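import math

import numpy as np
import pytest

from microsurv import (
    CellSystemModel,
    DSMKParams,
    NTParams,
    SingleEventSpectrum,
)
from microsurv.io import load_bundled_dsmk, load_bundled_nt
from microsurv.synthetic import make_spectrum


@pytest.fixture(scope="session")
def photon_nucleus_spec() -> SingleEventSpectrum:
    return make_spectrum(2.0, 7.8, label="photon nucleus")


@pytest.fixture(scope="session")
def photon_domain_spec() -> SingleEventSpectrum:
    return make_spectrum(2.0, 0.0654, label="photon domain")


@pytest.fixture(scope="session")
def ion_nucleus_spec() -> SingleEventSpectrum:
    return make_spectrum(100.0, 7.8, label="ion nucleus")


@pytest.fixture(scope="session")
def ion_domain_spec() -> SingleEventSpectrum:
    return make_spectrum(100.0, 0.0654, label="ion domain")


@pytest.fixture(scope="session")
def narrow_unit_spectrum() -> SingleEventSpectrum:
    """Nearly degenerate spectrum: all mass in a 1% triangle around 1 Gy."""
    w = 0.01
    grid = np.array([1.0 - w, 1.0, 1.0 + w])
    density = np.array([0.0, 1.0 / w, 0.0])
    return SingleEventSpectrum(site_radius=0.5, zbar_F=1.0, grid=grid, density=density)


@pytest.fixture(scope="session")
def wi38_nt() -> NTParams:
    return load_bundled_nt("nt_wi38")


@pytest.fixture(scope="session")
def bcl2neo_nt() -> NTParams:
    return load_bundled_nt("nt_bcl2neo")


@pytest.fixture(scope="session")
def conventional_params() -> DSMKParams:
    return load_bundled_dsmk("targeted_conventional_zthre_inf")


@pytest.fixture(scope="session")
def bcl2_saturation_params() -> DSMKParams:
    return load_bundled_dsmk("targeted_bcl2_saturation")


@pytest.fixture(scope="session")
def bcl2_adaptive_params() -> DSMKParams:
    return load_bundled_dsmk("targeted_bcl2_adaptive")


@pytest.fixture(scope="session")
def cell_model(conventional_params, bcl2_adaptive_params, bcl2neo_nt) -> CellSystemModel:
    return CellSystemModel(
        targeted_conventional=conventional_params,
        targeted_bcl2=bcl2_adaptive_params,
        nontargeted=bcl2neo_nt,
        x=0.0,
    )
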