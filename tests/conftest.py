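import numpy as np
import pytest

from jetlight import (
    KMCoefficients,
    MCConfig,
    MCGeometry,
    MediumMC,
    TallySpec,
)

#: backward-scattering coefficients (mm^-1) measured for the common
#: high-viscosity jetting media at 515 nm (K fixed at 0: no absorber)
TABLE1_S = {
    "LCP": 0.089,
    "LCP + thaumatin": 0.204,
    "HEC": 0.016,
    "HEC + thaumatin": 0.371,
    "Super Lube": 0.185,
    "Super Lube + thaumatin": 2.344,
}

#: the one absorbing fixture: FAP crystals in LCP at 470 nm
FAP_S, FAP_K = 0.399, 0.585

FLAT_CELL_PATHLENGTHS_UM = (22.0, 100.0, 200.0, 500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)


@pytest.fixture
def superlube_optics():
    return KMCoefficients(S=2.344, K=1.0)


def small_tally() -> TallySpec:
    """Coarse tally for fast unit tests (same extents as the default)."""
    return TallySpec(nx=81, ny=81, nz=41)


def jet_config(mu_s: float, n_photons: int, seed: int,
               tally: TallySpec | None = None, **kw) -> MCConfig:
    """The jet simulation configuration: 200 um host slab
    (mu_a = mu_s = 0.1 mm^-1, n = 1, g = 0) around a 150 um cylinder
    (mu_a = 1 mm^-1, n = 1.4, g = 0.9) hit by an 85 x 85 um FWHM beam."""
    return MCConfig(
        geometry=MCGeometry(slab_thickness_um=200.0,
                            cylinder_diameter_um=150.0),
        slab=MediumMC(mu_a=0.1, mu_s=0.1, g=0.0, n=1.0),
        cylinder=MediumMC(mu_a=1.0, mu_s=mu_s, g=0.9, n=1.4),
        n_photons=n_photons,
        seed=seed,
        tally=tally or small_tally(),
        **kw,
    )
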