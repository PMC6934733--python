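"""Forward simulator of sensor-expressing tissue under three-channel acquisition.

Generates a Voronoi cell mosaic with per-cell sensor expression and
metabolite concentration, a spatially heterogeneous autofluorescence field
(smoothed lognormal plus bright granules), and renders the three emission
channels with Poisson photon noise and Gaussian read noise.  All stages are
bitwise-deterministic given the config seed; tissue generation and
rendering consume independent child streams so either can be re-run alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.ndimage
import scipy.spatial

from .image_io import AcquisitionSet, ChannelImage, DEFAULT_CHANNEL_METADATA, LabelMask
from .sensor_model import SensorSpec, fraction_bound
from .unmixing import SpectralSignature

__all__ = [
    "DEFAULT_SIGNATURES",
    "SimulationConfig",
    "TissueGroundTruth",
    "generate_tissue",
    "render_acquisition",
    "simulate_bleach",
    "scenario_expression_gradient",
]

#: plausible emission-weight test constants for CFP-like, YFP-like and
#: long-wavelength autofluorescence species in 490/530/600 nm windows
DEFAULT_SIGNATURES = {
    "donor_fluor": (0.80, 0.20, 0.00),
    "acceptor_fluor": (0.05, 0.90, 0.05),
    "autofluorescence": (0.30, 0.20, 0.50),
}

_GRANULE_AMPLITUDE = 5.0  # granule brightness, in units of af_mean


def _default_signatures() -> tuple[SpectralSignature, SpectralSignature, SpectralSignature]:
    return tuple(
        SpectralSignature(species=sp, coefficients=np.array(c))
        for sp, c in DEFAULT_SIGNATURES.items()
    )


@dataclass
class SimulationConfig:
    height: int = 96
    width: int = 96
    n_cells: int = 60
    #: per-cell sensor expression E ~ lognormal(mu, sigma)
    expression_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.3)
    #: per-cell metabolite concentration (mM): {"name": ..., **params};
    #: names: constant(value), uniform(low, high), lognormal(mu, sigma),
    #: choice(values[, probs])
    conc_distribution: dict[str, Any] = field(
        default_factory=lambda: {"name": "uniform", "low": 0.0, "high": 10.0}
    )
    sensor: SensorSpec = field(default_factory=SensorSpec)
    signatures: tuple[SpectralSignature, SpectralSignature, SpectralSignature] = field(
        default_factory=_default_signatures
    )
    af_mean: float = 100.0
    af_heterogeneity: float = 0.5  # coefficient of variation of the smooth AF field
    af_granule_density: float = 0.01
    af_smooth_sigma: float = 3.0  # px, correlation length of the smooth AF field
    photon_budget: float = 500.0  # expected sensor photons/pixel at E = 1
    read_noise_sd: float = 2.0
    gamma: float = 1.0  # acceptor/donor relative detection efficiency
    direct_excitation_coeff: float = 0.0  # acceptor photons per sensor photon budget
    specimen: str = "sensor"  # sensor | donor_only | acceptor_only | none
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_cells > self.height * self.width:
            raise ValueError("n_cells exceeds pixel count")
        if self.af_mean < 0 or self.af_heterogeneity < 0:
            raise ValueError("autofluorescence scales must be non-negative")
        if not 0 <= self.af_granule_density <= 1:
            raise ValueError("af_granule_density must be in [0, 1]")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.specimen not in ("sensor", "donor_only", "acceptor_only", "none"):
            raise ValueError(f"unknown specimen kind {self.specimen!r}")

    @property
    def donor_sig(self) -> SpectralSignature:
        return self.signatures[0]

    @property
    def acceptor_sig(self) -> SpectralSignature:
        return self.signatures[1]

    @property
    def af_sig(self) -> SpectralSignature:
        return self.signatures[2]


@dataclass
class TissueGroundTruth:
    """Synthetic scene ground truth.

    Per-cell arrays are indexed by label - 1.  ``expression_scale`` and
    ``acceptor_intact`` are per-pixel modifiers (both default to 1
    everywhere): the former supports expression-step scenarios, the latter
    records acceptor photobleaching (fraction of acceptors still intact).
    """

    cell_labels: LabelMask
    expression: np.ndarray  # per-cell E > 0
    concentration: np.ndarray  # per-cell c >= 0, mM
    bound_fraction: np.ndarray  # per-cell f = c / (c + kd)
    fret_eff: np.ndarray  # per-cell eps = (1-f) eps_unbound + f eps_bound
    af_field: np.ndarray  # per-pixel AF amplitude >= 0
    expression_scale: np.ndarray | None = None
    acceptor_intact: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.expression_scale is None:
            self.expression_scale = np.ones(self.cell_labels.shape)
        if self.acceptor_intact is None:
            self.acceptor_intact = np.ones(self.cell_labels.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_labels.shape

    def expression_map(self) -> np.ndarray:
        """Per-pixel sensor expression."""
        return self.expression[self.cell_labels.labels - 1] * self.expression_scale

    def fret_eff_map(self) -> np.ndarray:
        """Per-pixel intrinsic FRET efficiency (before any photobleaching)."""
        return self.fret_eff[self.cell_labels.labels - 1]


def _sample_concentration(rng: np.random.Generator, dist: dict[str, Any], n: int) -> np.ndarray:
    dist = dict(dist)
    name = dist.pop("name")
    if name == "constant":
        c = np.full(n, float(dist["value"]))
    elif name == "uniform":
        c = rng.uniform(dist["low"], dist["high"], size=n)
    elif name == "lognormal":
        c = rng.lognormal(dist["mu"], dist["sigma"], size=n)
    elif name == "choice":
        values = np.asarray(dist["values"], dtype=float)
        c = rng.choice(values, size=n, p=dist.get("probs"))
    else:
        raise ValueError(f"unknown concentration distribution {name!r}")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return c


def _af_unit_field(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Unit-mean heterogeneous field: smoothed lognormal + sparse granules."""
    shape = (config.height, config.width)
    cv = config.af_heterogeneity
    if cv > 0:
        g = rng.standard_normal(shape)
        g = scipy.ndimage.gaussian_filter(g, sigma=config.af_smooth_sigma, mode="reflect")
        sd = g.std()
        if sd > 0:
            g /= sd
        # lognormal with exact unit mean and CV = cv
        s = np.sqrt(np.log1p(cv**2))
        unit = np.exp(s * g - s**2 / 2.0)
    else:
        unit = np.ones(shape)
    if config.af_granule_density > 0:
        granules = rng.random(shape) < config.af_granule_density
        unit = unit + granules * _GRANULE_AMPLITUDE
    return unit


def generate_tissue(config: SimulationConfig) -> TissueGroundTruth:
    """Generate a seeded Voronoi cell mosaic with per-cell E, c, f, eps and the
    heterogeneous autofluorescence amplitude field."""
    rng = np.random.default_rng([config.seed, 0])
    h, w = config.height, config.width

    sites = np.column_stack(
        [rng.uniform(0, h, size=config.n_cells), rng.uniform(0, w, size=config.n_cells)]
    )
    rows, cols = np.mgrid[0:h, 0:w]
    pixels = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = scipy.spatial.cKDTree(sites).query(pixels)
    labels = (nearest + 1).reshape(h, w).astype(np.int32)

    mu, sigma = config.expression_lognormal_mu_sigma
    expression = rng.lognormal(mu, sigma, size=config.n_cells)
    concentration = _sample_concentration(rng, config.conc_distribution, config.n_cells)
    f = fraction_bound(concentration, config.sensor.kd)
    eps = (1.0 - f) * config.sensor.fret_eff_unbound + f * config.sensor.fret_eff_bound
    af_field = config.af_mean * _af_unit_field(rng, config)

    return TissueGroundTruth(
        cell_labels=LabelMask(labels=labels),
        expression=expression,
        concentration=concentration,
        bound_fraction=f,
        fret_eff=eps,
        af_field=af_field,
    )


def expected_channels(truth: TissueGroundTruth, config: SimulationConfig) -> np.ndarray:
    """Noise-free expected photon counts, shape (H, W, 3)."""
    e_px = truth.expression_map()
    eps_px = truth.fret_eff_map()
    intact = truth.acceptor_intact
    eps_eff = eps_px * intact  # FRET only to intact acceptors
    budget = config.photon_budget

    if config.specimen == "sensor":
        donor_photons = budget * e_px * (1.0 - eps_eff)
        acceptor_photons = budget * e_px * eps_eff * config.gamma
        acceptor_photons = acceptor_photons + budget * e_px * config.direct_excitation_coeff * intact
    elif config.specimen == "donor_only":
        donor_photons = budget * e_px
        acceptor_photons = np.zeros_like(e_px)
    elif config.specimen == "acceptor_only":
        donor_photons = np.zeros_like(e_px)
        acceptor_photons = budget * e_px * config.direct_excitation_coeff * intact
    else:  # sensor-free tissue
        donor_photons = np.zeros_like(e_px)
        acceptor_photons = np.zeros_like(e_px)

    expected = (
        donor_photons[..., None] * config.donor_sig.coefficients
        + acceptor_photons[..., None] * config.acceptor_sig.coefficients
        + truth.af_field[..., None] * config.af_sig.coefficients
    )
    return expected


def render_acquisition(
    truth: TissueGroundTruth, config: SimulationConfig, *, noise: bool = True
) -> AcquisitionSet:
    """Render the three-channel acquisition from ground truth.

    Per pixel in cell k, expected donor photons are
    ``photon_budget * E_k * (1 - eps_k)`` and expected sensitized acceptor
    photons ``photon_budget * E_k * eps_k * gamma``; each species is spread
    across channels by its signature and the AF field adds its own
    signature.  With ``noise=True`` photons are Poisson-sampled and
    Gaussian read noise added, then clamped at 0.
    """
    if truth.shape != (config.height, config.width):
        raise ValueError("truth and config dimensions disagree")
    expected = expected_channels(truth, config)
    if noise:
        rng = np.random.default_rng([config.seed, 1])
        counts = rng.poisson(expected).astype(float)
        if config.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, config.read_noise_sd, size=counts.shape)
        counts = np.maximum(counts, 0.0)
    else:
        counts = expected

    channels = {}
    for i, role in enumerate(("donor", "acceptor", "autofluo")):
        channels[role] = ChannelImage(
            pixels=counts[..., i], channel_role=role, **DEFAULT_CHANNEL_METADATA[role]
        )
    return AcquisitionSet(
        donor=channels["donor"],
        acceptor=channels["acceptor"],
        autofluo=channels["autofluo"],
        sample_id=f"synthetic-seed{config.seed}",
    )


def simulate_bleach(
    truth: TissueGroundTruth, bleach_mask: LabelMask, bleach_fraction: float
) -> TissueGroundTruth:
    """Photoinactivate a fraction ``b`` of acceptors inside the mask.

    Inside the mask the effective FRET efficiency becomes ``eps * (1 - b)``
    and sensitized acceptor emission scales by ``(1 - b)``; pixels outside
    the mask are unchanged.  Returns a new ground truth, leaving the input
    untouched.
    """
    if not 0.0 <= bleach_fraction <= 1.0:
        raise ValueError("bleach_fraction must be in [0, 1]")
    if bleach_mask.shape != truth.shape:
        raise ValueError("bleach mask dimensions must match the scene")
    bleached = copy.deepcopy(truth)
    sel = bleach_mask.labels > 0
    bleached.acceptor_intact[sel] *= 1.0 - bleach_fraction
    return bleached


def scenario_expression_gradient(
    config: SimulationConfig,
) -> tuple[TissueGroundTruth, AcquisitionSet]:
    """Two tissue halves with expression E and 2E, same concentration
    distribution, heterogeneous AF — the expression-independence fixture.

    Per-cell expression is pinned to exp(mu) so the mean expression ratio
    between halves is exactly 2 by construction; the right half of the
    frame carries the doubled dose.
    """
    truth = generate_tissue(config)
    mu = config.expression_lognormal_mu_sigma[0]
    truth.expression = np.full_like(truth.expression, np.exp(mu))
    scale = np.ones(truth.shape)
    scale[:, config.width // 2 :] = 2.0
    truth.expression_scale = scale
    acq = render_acquisition(truth, config)
    return truth, acq
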