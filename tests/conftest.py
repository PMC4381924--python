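import numpy as np
import pytest

from memfret.photophysics import (BleedthroughCoefficients, FluorophorePair,
                                  Spectrum)
from memfret.reference import eyfp_mcherry_pair, mturquoise_eyfp_pair
from memfret.synthetic import (OpticsParams, SceneParams,
                               render_vesicle_images, scene_for_vesicle)


@pytest.fixture(scope="session")
def vesicle_pair() -> FluorophorePair:
    """EYFP/mCherry pair used by the confocal vesicle assay."""
    return eyfp_mcherry_pair()


@pytest.fixture(scope="session")
def spectral_pair() -> FluorophorePair:
    """mTurquoise/EYFP pair used by the two-photon live-cell assay."""
    return mturquoise_eyfp_pair()


@pytest.fixture(scope="session")
def toy_pair() -> FluorophorePair:
    """Symmetric toy pair (equal quantum yields, no bleed-through)."""
    wl = np.arange(450.0, 601.0, 1.0)
    donor = Spectrum(wl, np.exp(-0.5 * ((wl - 480.0) / 15.0) ** 2))
    acceptor = Spectrum(wl, np.exp(-0.5 * ((wl - 560.0) / 15.0) ** 2))
    ext = Spectrum(wl, 5e4 * np.exp(-0.5 * ((wl - 530.0) / 15.0) ** 2))
    return FluorophorePair.from_spectra(
        "toyD", "toyA", Q_D=0.5, Q_A=0.5, donor_emission=donor,
        acceptor_emission=acceptor, acceptor_extinction=ext,
        bleedthrough=BleedthroughCoefficients(0.0, 0.0))


@pytest.fixture(scope="session")
def standard_optics() -> OpticsParams:
    return OpticsParams(vesicle_radius=3.0)


@pytest.fixture(scope="session")
def noise_free_vesicle(vesicle_pair, standard_optics):
    """One noise-free rendered vesicle with its scene ground truth."""
    params = SceneParams(total_density=1000.0, x_a_true=0.5, Kd2d=150.0,
                         E_dimer=0.38, seed=5)
    scene = scene_for_vesicle(params, standard_optics, R0=vesicle_pair.R0)
    images = render_vesicle_images(scene, standard_optics, vesicle_pair,
                                   seed=7, noise=False)
    return scene, images
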