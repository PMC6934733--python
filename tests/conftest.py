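import numpy as np
import pytest

from fretmix.image_io import AcquisitionSet, ChannelImage, DEFAULT_CHANNEL_METADATA, LabelMask
from fretmix.sensor_model import SensorSpec
from fretmix.synthetic import DEFAULT_SIGNATURES, SimulationConfig
from fretmix.unmixing import SpectralSignature, build_mixing_matrix


def make_acquisition(donor, acceptor, autofluo, **kwargs) -> AcquisitionSet:
    """Assemble an AcquisitionSet from three 2-D arrays (or scalars + shape)."""
    channels = {}
    for role, pixels in (("donor", donor), ("acceptor", acceptor), ("autofluo", autofluo)):
        channels[role] = ChannelImage(
            pixels=np.asarray(pixels, dtype=float),
            channel_role=role,
            **DEFAULT_CHANNEL_METADATA[role],
        )
    return AcquisitionSet(**channels, **kwargs)


def constant_acquisition(values, shape=(8, 8), **kwargs) -> AcquisitionSet:
    d, a, af = values
    return make_acquisition(
        np.full(shape, float(d)), np.full(shape, float(a)), np.full(shape, float(af)), **kwargs
    )


@pytest.fixture
def signatures():
    return tuple(
        SpectralSignature(species=sp, coefficients=np.array(c))
        for sp, c in DEFAULT_SIGNATURES.items()
    )


@pytest.fixture
def mixing_matrix(signatures):
    return build_mixing_matrix(*signatures)


@pytest.fixture
def full_mask():
    def _make(shape=(8, 8)):
        return LabelMask(labels=np.ones(shape, dtype=np.int32))

    return _make


@pytest.fixture
def small_config():
    """Small, fast simulation scene with mild noise."""
    return SimulationConfig(
        height=48,
        width=48,
        n_cells=12,
        sensor=SensorSpec(fret_eff_unbound=0.45, fret_eff_bound=0.05),
        af_mean=80.0,
        af_heterogeneity=0.4,
        af_granule_density=0.01,
        photon_budget=500.0,
        seed=123,
    )
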