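import numpy as np
import pytest

import swerf


@pytest.fixture
def params():
    return swerf.ConventionParams()


@pytest.fixture
def quartz():
    return swerf.Material("quartz flour", swerf.QUARTZ_SG, cs_mass_fraction=1.0)


@pytest.fixture
def barite():
    return swerf.Material("barite", swerf.BARITE_SG, cs_mass_fraction=0.0)


@pytest.fixture
def diatomite():
    # porous flux-calcined diatomaceous earth: skeleton SG ~2.3 but high
    # internal porosity; effective density governs the settling behaviour
    return swerf.Material("diatomaceous earth", 2.3, effective_density=1000.0)


@pytest.fixture
def lognormal_9p3():
    """Median 9.3 µm, GSD 2 volume PSD (spherical-equivalent basis)."""
    return swerf.lognormal_psd(swerf.LognormalSpec(median=9.3, gsd=2.0))


@pytest.fixture
def water_plan():
    """Derived plan: quartz in water, h = 50 mm, H = 200 mm."""
    return swerf.SedimentationPlan.derive(
        liquid=swerf.WATER_20C,
        particle_density=2660.0,
        extraction_height=0.05,
        column_height=0.20,
    )


def uniform_aero_psd(upper_um: float, n_bins: int) -> swerf.SizeDistribution:
    edges = np.linspace(0.0, upper_um, n_bins + 1)
    return swerf.SizeDistribution(
        bin_edges=edges,
        bin_fractions=np.full(n_bins, 1.0 / n_bins),
        diameter_basis=swerf.DiameterBasis.AERODYNAMIC,
    )


def narrow_aero_psd(center_um: float, rel_width: float = 1e-5):
    lo = center_um * (1 - rel_width)
    hi = center_um / (1 - rel_width)
    return swerf.SizeDistribution(
        bin_edges=np.array([lo, hi]),
        bin_fractions=np.array([1.0]),
        diameter_basis=swerf.DiameterBasis.AERODYNAMIC,
    )


# Published validation series for the spiking-recovery and method-agreement
# statistics: percent SWeRF_CS by the calculated route vs the sedimentation
# route for quartz-spiked barite, percent SWeRF by both routes for five
# diatomaceous earth products, and seven repeatability runs of one sample.
SPIKING_CALCULATED = [0.0, 11.3, 21.9, 32.0, 41.4]
SPIKING_SEDIMENTATION = [0.0, 9.8, 22.2, 32.4, 38.4]
SPIKING_SWERF = [0.0, 34.5, 38.1, 40.8, 41.8]
SPIKING_FCS = [0.0, 28.3, 58.3, 79.4, 91.9]

DIATOMITE_SEDIMENTATION = [16.5, 15.4, 6.9, 4.7, 6.7]
DIATOMITE_CALCULATED = [19.4, 17.0, 8.5, 4.9, 8.0]

REPEATABILITY_RUNS = [17.6, 14.9, 14.8, 17.1, 14.9, 13.6, 15.2]
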