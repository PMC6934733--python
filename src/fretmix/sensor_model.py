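"""Sensor biophysics and the validation analyses of the FRET signal.

Single-site binding of the metabolite separates the donor/acceptor pair of
the sensor and abolishes energy transfer, so the ratio decreases
monotonically with concentration.  This module holds the binding model,
dose-response calibration, and the three controls used to establish that
the measured ratio really reports FRET: acceptor photobleaching (donor
de-quenching), the direct acceptor-excitation control, and donor/acceptor
anti-correlation across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .image_io import AcquisitionSet, LabelMask
from .unmixing import MixingMatrix, SpectralSignature, unmix_image

__all__ = [
    "SensorSpec",
    "DoseResponseFit",
    "PhotobleachResult",
    "fraction_bound",
    "predicted_ratio",
    "fit_dose_response",
    "analyze_photobleach",
    "check_direct_excitation",
    "spectral_anticorrelation",
]


@dataclass
class SensorSpec:
    """Biophysical parameters of one FRET metabolite sensor.

    The defaults are uncalibrated placeholders (``calibrated=False``): no
    published Kd / ratio endpoints are assumed, and every simulation-backed
    test defines its own ground truth.
    """

    name: str = "placeholder-lactate-sensor"
    metabolite: str = "lactate"
    kd: float = 5.0  # mM
    ratio_unbound: float = 1.0  # r_max, high-FRET state
    ratio_bound: float = 0.4  # r_min, low-FRET state
    fret_eff_unbound: float = 0.35
    fret_eff_bound: float = 0.05
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not self.ratio_bound < self.ratio_unbound:
            raise ValueError("binding must reduce the ratio: ratio_bound < ratio_unbound")
        if not 0 <= self.fret_eff_bound < self.fret_eff_unbound <= 1:
            raise ValueError("need 0 <= fret_eff_bound < fret_eff_unbound <= 1")


@dataclass
class DoseResponseFit:
    kd_hat: float
    r_max_hat: float
    r_min_hat: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kd_hat <= 0:
            raise ValueError("kd_hat must be positive")
        if self.n_points < 4:
            raise ValueError("need at least 4 points")


@dataclass
class PhotobleachResult:
    donor_pre: float
    donor_post: float
    donor_pre_ctrl: float
    donor_post_ctrl: float
    relative_donor_increase: float
    fret_confirmed: bool


def fraction_bound(c, kd: float):
    """Equilibrium bound fraction ``c / (c + kd)`` for single-site binding."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive")
    out = c / (c + kd)
    return float(out) if out.ndim == 0 else out


def predicted_ratio(c, spec: SensorSpec):
    """Ratio at concentration c: r_max - (r_max - r_min) * f(c).

    Strictly decreasing in c (binding separates the fluorophores and FRET
    ceases), from r_max at c=0 to r_min at saturation.
    """
    f = fraction_bound(c, spec.kd)
    return spec.ratio_unbound - (spec.ratio_unbound - spec.ratio_bound) * f


def fit_dose_response(concs, ratios, init: tuple[float, float, float] | None = None) -> DoseResponseFit:
    """Nonlinear least-squares fit of the single-site binding curve.

    Parameters are (r_max, r_min, kd); ``init`` defaults to
    (max(ratios), min(ratios), median positive concentration).  The fit is
    deterministic given ``init``.  A flat response makes kd unidentifiable
    and raises.
    """
    concs = np.asarray(concs, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if concs.shape != ratios.shape or concs.ndim != 1:
        raise ValueError("concs and ratios must be 1-D and equal length")
    n = concs.size
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.unique(concs).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(ratios) <= 0:
        raise ValueError("flat response: kd is unidentifiable")

    if init is None:
        positive = concs[concs > 0]
        kd0 = float(np.median(positive)) if positive.size else 1.0
        init = (float(ratios.max()), float(ratios.min()), kd0)
    r_max0, r_min0, kd0 = init

    def model(c, r_max, r_min, kd):
        return r_max - (r_max - r_min) * c / (c + kd)

    kd_floor = 1e-9
    try:
        popt, _ = scipy.optimize.curve_fit(
            model,
            concs,
            ratios,
            p0=[r_max0, r_min0, max(kd0, kd_floor)],
            bounds=([-np.inf, -np.inf, kd_floor], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"dose-response fit did not converge: {exc}") from exc
    r_max_hat, r_min_hat, kd_hat = map(float, popt)
    if kd_hat <= 2 * kd_floor:
        raise RuntimeError("kd estimate collapsed to its lower bound; data uninformative")
    rss = float(np.sum((model(concs, *popt) - ratios) ** 2))
    return DoseResponseFit(kd_hat=kd_hat, r_max_hat=r_max_hat, r_min_hat=r_min_hat, rss=rss, n_points=n)


def _mean_donor(acq: AcquisitionSet, mask: LabelMask, M: MixingMatrix) -> float:
    sel = mask.labels > 0
    if not sel.any():
        raise ValueError("empty mask")
    unmixed = unmix_image(acq, M, nonneg="nnls")
    return float(unmixed.donor_abundance[sel].mean())


def analyze_photobleach(
    pre: AcquisitionSet,
    post: AcquisitionSet,
    bleach_mask: LabelMask,
    control_mask: LabelMask,
    M: MixingMatrix,
    min_rel_increase: float = 0.05,
) -> PhotobleachResult:
    """Acceptor-photobleaching control: donor de-quenching proves FRET.

    Both acquisitions are unmixed and mean donor abundance compared inside
    the bleached region and an untouched control region.  FRET is confirmed
    when the bleached-region donor rises by at least ``min_rel_increase``
    while the control region stays within ``min_rel_increase / 2``.
    """
    if pre.shape != post.shape:
        raise ValueError("pre and post acquisitions must be co-registered")
    if np.any((bleach_mask.labels > 0) & (control_mask.labels > 0)):
        raise ValueError("bleach and control masks must be disjoint")
    donor_pre = _mean_donor(pre, bleach_mask, M)
    donor_post = _mean_donor(post, bleach_mask, M)
    donor_pre_ctrl = _mean_donor(pre, control_mask, M)
    donor_post_ctrl = _mean_donor(post, control_mask, M)
    if donor_pre <= 0:
        raise ValueError("no donor signal in the bleach region before bleaching")
    rel = donor_post / donor_pre - 1.0
    ctrl_rel = donor_post_ctrl / donor_pre_ctrl - 1.0 if donor_pre_ctrl > 0 else np.inf
    confirmed = bool(rel >= min_rel_increase and abs(ctrl_rel) <= min_rel_increase / 2.0)
    return PhotobleachResult(
        donor_pre=donor_pre,
        donor_post=donor_post,
        donor_pre_ctrl=donor_pre_ctrl,
        donor_post_ctrl=donor_post_ctrl,
        relative_donor_increase=rel,
        fret_confirmed=confirmed,
    )


def _af_corrected_acceptor_channel(acq: AcquisitionSet, af_sig: SpectralSignature | None) -> np.ndarray:
    pixels = acq.acceptor.pixels
    if af_sig is None:
        return pixels
    if af_sig.coefficients[2] <= 0:
        raise ValueError("autofluorescence signature has zero weight in the autofluo channel")
    af_amplitude = acq.autofluo.pixels / af_sig.coefficients[2]
    return np.maximum(pixels - af_amplitude * af_sig.coefficients[1], 0.0)


def check_direct_excitation(
    acceptor_only: AcquisitionSet,
    reference: AcquisitionSet,
    threshold: float = 0.05,
    af_sig: SpectralSignature | None = None,
) -> bool:
    """Direct acceptor-excitation control.

    An acceptor-only specimen is excited at the donor wavelength; the
    control passes when its median acceptor-channel signal (after AF
    subtraction when ``af_sig`` is given) is at most ``threshold`` times
    the median of a co-acquired sensor-expressing reference.  A pass means
    acceptor emission in real samples arises from energy transfer, not
    direct excitation.
    """
    if reference is None:
        raise ValueError("a donor-expressing reference acquisition is required")
    signal = float(np.median(_af_corrected_acceptor_channel(acceptor_only, af_sig)))
    scale = float(np.median(_af_corrected_acceptor_channel(reference, af_sig)))
    if scale <= 0:
        raise ValueError("reference acquisition carries no acceptor-channel signal")
    return signal <= threshold * scale


def spectral_anticorrelation(donor_means, acceptor_means) -> float:
    """Pearson correlation of expression-normalized donor vs acceptor
    fractions across cells.

    Each cell's donor and acceptor abundances are divided by their sum,
    removing expression; genuine FRET-state variation then forces the two
    fractions to move in opposite directions, giving a negative
    correlation.  Cells differing only in expression have zero variance in
    the fractions, which is an error.
    """
    donor_means = np.asarray(donor_means, dtype=float)
    acceptor_means = np.asarray(acceptor_means, dtype=float)
    if donor_means.shape != acceptor_means.shape or donor_means.ndim != 1:
        raise ValueError("need matching 1-D per-cell donor and acceptor abundances")
    if donor_means.size < 5:
        raise ValueError("need at least 5 cells")
    total = donor_means + acceptor_means
    if np.any(total <= 0):
        raise ValueError("each cell needs positive total abundance")
    d_frac = donor_means / total
    a_frac = acceptor_means / total
    if np.std(d_frac) == 0 or np.std(a_frac) == 0:
        raise ValueError("zero variance in normalized fractions (no FRET-state variation)")
    r, _ = scipy.stats.pearsonr(d_frac, a_frac)
    return float(r)
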