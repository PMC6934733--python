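"""Per-pixel three-species spectral linear unmixing and FRET-map construction.

Each pixel's three measured channel intensities are modelled as a
non-negative combination of three spectral species — donor fluorophore,
acceptor fluorophore and autofluorescence — whose relative emission across
the (donor-window, acceptor-window, autofluo-window) channels is described
by a unit-sum signature.  Solving the resulting 3x3 linear system per pixel
yields abundance maps from which an expression-independent FRET ratio is
computed.  A constant-background baseline (one scalar per channel) is also
provided for comparison; it is only exact when autofluorescence is
spatially uniform.

The autofluorescence spectral *shape* is assumed spatially uniform — only
its per-pixel amplitude varies.  This is the key assumption of the
three-channel design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .image_io import AcquisitionSet, ChannelImage, LabelMask

__all__ = [
    "SPECIES",
    "SpectralSignature",
    "MixingMatrix",
    "UnmixedImage",
    "FretMap",
    "estimate_af_signature",
    "estimate_sensor_signatures",
    "build_mixing_matrix",
    "unmix_image",
    "constant_background_subtract",
    "compute_fret_map",
]

SPECIES = ("donor_fluor", "acceptor_fluor", "autofluorescence")

_SUM_TOL = 1e-9


@dataclass
class SpectralSignature:
    """Relative emission of one species across the three channels.

    Coefficients are ordered (donor-window, acceptor-window,
    autofluo-window), are non-negative and sum to 1.
    """

    species: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (3,):
            raise ValueError("coefficients must have exactly 3 entries")
        if np.any(coeffs < 0):
            raise ValueError("coefficients must be non-negative")
        if abs(coeffs.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"coefficients must sum to 1 (got {coeffs.sum()!r})")
        self.coefficients = coeffs

    @classmethod
    def from_counts(cls, species: str, counts) -> "SpectralSignature":
        """Build a signature by normalizing raw per-channel counts to sum 1."""
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize non-positive counts into a signature")
        return cls(species=species, coefficients=counts / total)


@dataclass
class MixingMatrix:
    """3x3 species-by-channel coefficient matrix with its condition number."""

    matrix: np.ndarray
    condition_number: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if np.any(self.matrix < 0):
            raise ValueError("matrix coefficients must be non-negative")
        if not np.isfinite(self.condition_number) or self.condition_number <= 0:
            raise ValueError("condition number must be finite and positive")

    def signatures(self) -> tuple[SpectralSignature, SpectralSignature, SpectralSignature]:
        return tuple(
            SpectralSignature(species=sp, coefficients=row)
            for sp, row in zip(SPECIES, self.matrix)
        )


@dataclass
class UnmixedImage:
    """Per-pixel species abundances plus the per-pixel model-mismatch norm."""

    donor_abundance: np.ndarray
    acceptor_abundance: np.ndarray
    autofluo_abundance: np.ndarray
    residual_norm: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            self.donor_abundance.shape,
            self.acceptor_abundance.shape,
            self.autofluo_abundance.shape,
            self.residual_norm.shape,
        }
        if len(shapes) != 1:
            raise ValueError("abundance grids must share dimensions")
        for grid in (self.donor_abundance, self.acceptor_abundance, self.autofluo_abundance):
            if np.any(grid < 0):
                raise ValueError("abundances must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor_abundance.shape


@dataclass
class FretMap:
    """Per-pixel FRET ratio with a validity mask."""

    ratio: np.ndarray
    valid: np.ndarray
    min_intensity_used: float

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio and valid grids must share dimensions")
        if not np.all(np.isfinite(self.ratio[self.valid])):
            raise ValueError("ratio must be finite wherever valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratio.shape

    def mean_ratio(self, where: np.ndarray | None = None) -> float:
        """Mean over valid pixels, optionally restricted to a boolean region."""
        sel = self.valid if where is None else (self.valid & np.asarray(where, dtype=bool))
        if not sel.any():
            return float("nan")
        return float(self.ratio[sel].mean())


def estimate_af_signature(
    control: AcquisitionSet, mask: LabelMask, min_pixels: int = 50
) -> SpectralSignature:
    """Estimate the autofluorescence signature from sensor-free control tissue.

    Per-channel medians over the masked pixels (median: robust against the
    bright autofluorescent granules seen in tissue), normalized to sum 1.
    """
    if mask.shape != control.shape:
        raise ValueError("mask dimensions must match the acquisition")
    sel = mask.labels > 0
    n = int(sel.sum())
    if n < min_pixels:
        raise ValueError(f"mask selects {n} pixels; need >= {min_pixels}")
    stack = control.stack()[sel]  # (n, 3)
    medians = np.median(stack, axis=0)
    if np.any(medians <= 0):
        raise ValueError(f"non-positive channel median in control tissue: {medians}")
    return SpectralSignature.from_counts("autofluorescence", medians)


def _estimate_single_fluor(
    acq: AcquisitionSet,
    af_sig: SpectralSignature,
    mask: LabelMask,
    species: str,
    principal_channel: int,
) -> SpectralSignature:
    if mask.shape != acq.shape:
        raise ValueError("mask dimensions must match the acquisition")
    sel = mask.labels > 0
    if not sel.any():
        raise ValueError("empty mask")
    stack = acq.stack()[sel]  # (n, 3)
    af_in_af_channel = af_sig.coefficients[2]
    if af_in_af_channel <= 0:
        raise ValueError("autofluorescence signature has zero weight in the autofluo channel")
    # AF amplitude inferred from the dedicated 600 nm channel, then its
    # spectral footprint removed from all three channels.  This is exact
    # when the fluorophore does not bleed into the 600 nm window; with
    # nonzero bleed the two-species decomposition is not identifiable from
    # these data and the estimator returns the AF-orthogonalized member of
    # the solution family, i.e. normalize(sig - (sig[2]/af[2]) * af), which
    # spans the same model subspace and unmixes equivalently.
    af_amplitude = stack[:, 2] / af_in_af_channel
    remainder = stack - af_amplitude[:, None] * af_sig.coefficients[None, :]
    medians = np.median(remainder, axis=0)
    if medians[principal_channel] <= 0:
        raise ValueError(
            f"{species} remainder non-positive in its principal channel "
            f"(medians {medians}); reference acquisition unusable"
        )
    return SpectralSignature.from_counts(species, np.maximum(medians, 0.0))


def estimate_sensor_signatures(
    donor_only: AcquisitionSet,
    acceptor_only: AcquisitionSet,
    af_sig: SpectralSignature,
    masks: LabelMask | tuple[LabelMask, LabelMask],
) -> tuple[SpectralSignature, SpectralSignature]:
    """Estimate donor and acceptor signatures from single-fluorophore references.

    For each reference acquisition the autofluorescence contribution
    inferred from the autofluo channel is subtracted, per-channel medians
    of the remainder are taken, negatives clamped to 0 and the result
    normalized to sum 1.
    """
    if isinstance(masks, LabelMask):
        donor_mask = acceptor_mask = masks
    else:
        donor_mask, acceptor_mask = masks
    donor_sig = _estimate_single_fluor(donor_only, af_sig, donor_mask, "donor_fluor", 0)
    acceptor_sig = _estimate_single_fluor(acceptor_only, af_sig, acceptor_mask, "acceptor_fluor", 1)
    return donor_sig, acceptor_sig


def build_mixing_matrix(
    donor_sig: SpectralSignature,
    acceptor_sig: SpectralSignature,
    af_sig: SpectralSignature,
    cond_cap: float = 1e3,
) -> MixingMatrix:
    """Stack the three signatures as rows and validate invertibility.

    An ill-conditioned matrix means the species are spectrally
    indistinguishable with these three emission windows, so unmixing
    would amplify noise unboundedly; such matrices are rejected.
    """
    matrix = np.vstack(
        [donor_sig.coefficients, acceptor_sig.coefficients, af_sig.coefficients]
    )
    cond = float(np.linalg.cond(matrix))
    if not np.isfinite(cond) or cond > cond_cap:
        raise ValueError(
            f"mixing matrix singular or ill-conditioned (cond={cond:.3g}, cap={cond_cap:.3g})"
        )
    return MixingMatrix(matrix=matrix, condition_number=cond)


def unmix_image(acq: AcquisitionSet, M: MixingMatrix, nonneg: str = "nnls") -> UnmixedImage:
    """Solve the per-pixel linear model ``intensities = M.T @ abundances``.

    nonneg policy ``"clamp"`` solves the exactly-determined system
    unconstrained and clamps negative abundances to 0; ``"nnls"`` (default)
    solves with non-negativity constraints, which yields physically
    interpretable abundances.  ``residual_norm`` is the per-pixel Euclidean
    norm of the model mismatch of the reported (non-negative) abundances.
    """
    if nonneg not in ("clamp", "nnls"):
        raise ValueError(f"nonneg policy must be 'clamp' or 'nnls', got {nonneg!r}")
    shape = acq.shape
    intensities = acq.stack().reshape(-1, 3)  # (N, 3)
    MT = M.matrix.T  # channels x species

    # exactly-determined solve, vectorized over pixels
    raw = np.linalg.solve(MT, intensities.T).T  # (N, 3)

    if nonneg == "clamp":
        abundances = np.maximum(raw, 0.0)
    else:
        abundances = raw.copy()
        # NNLS only where the unconstrained solution is infeasible
        needs_nnls = np.flatnonzero((raw < 0).any(axis=1))
        for i in needs_nnls:
            abundances[i], _ = scipy.optimize.nnls(MT, intensities[i])
        abundances = np.maximum(abundances, 0.0)  # scrub -0.0 / fp dust

    residual = np.linalg.norm(abundances @ M.matrix - intensities, axis=1)
    return UnmixedImage(
        donor_abundance=abundances[:, 0].reshape(shape),
        acceptor_abundance=abundances[:, 1].reshape(shape),
        autofluo_abundance=abundances[:, 2].reshape(shape),
        residual_norm=residual.reshape(shape),
        saturated=acq.saturation_mask,
    )


def constant_background_subtract(acq: AcquisitionSet, background) -> AcquisitionSet:
    """Baseline method: subtract one scalar per channel, clamping at 0.

    The output is marked ``background_corrected`` so that
    :func:`compute_fret_map` treats its donor/acceptor channels directly as
    abundances.  Exact only when autofluorescence is spatially uniform.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (3,):
        raise ValueError("background must supply one constant per channel")
    if np.any(background < 0):
        raise ValueError("background constants must be non-negative")

    def _sub(ch: ChannelImage, b: float) -> ChannelImage:
        return ChannelImage(
            pixels=np.maximum(ch.pixels - b, 0.0),
            channel_role=ch.channel_role,
            emission_center_nm=ch.emission_center_nm,
            emission_halfwidth_nm=ch.emission_halfwidth_nm,
            excitation_nm=ch.excitation_nm,
        )

    return AcquisitionSet(
        donor=_sub(acq.donor, background[0]),
        acceptor=_sub(acq.acceptor, background[1]),
        autofluo=_sub(acq.autofluo, background[2]),
        time_index=acq.time_index,
        sample_id=acq.sample_id,
        saturation_mask=acq.saturation_mask,
        background_corrected=True,
    )


def compute_fret_map(
    source: UnmixedImage | AcquisitionSet,
    min_intensity: float,
    orientation: str = "acceptor_over_donor",
) -> FretMap:
    """Build the per-pixel FRET ratio map from unmixed abundances (or from a
    background-corrected acquisition for the constant-background baseline).

    Pixels are invalid when donor + acceptor falls below ``min_intensity``,
    when the denominator is 0, or when flagged as saturated.  With the
    default orientation (sensitized-emission ratio, acceptor/donor) high
    ratio means high FRET; for the metabolite sensors modelled here binding
    abolishes FRET, so high ratio corresponds to low metabolite.
    """
    if min_intensity <= 0:
        raise ValueError("min_intensity must be > 0")
    if orientation not in ("acceptor_over_donor", "donor_over_acceptor"):
        raise ValueError(f"unknown ratio orientation {orientation!r}")

    if isinstance(source, UnmixedImage):
        donor = source.donor_abundance
        acceptor = source.acceptor_abundance
        saturated = source.saturated
    elif isinstance(source, AcquisitionSet):
        if not source.background_corrected:
            raise ValueError(
                "raw acquisitions must be unmixed (or background-corrected) "
                "before computing a FRET map"
            )
        donor = source.donor.pixels
        acceptor = source.acceptor.pixels
        saturated = source.saturation_mask
    else:
        raise TypeError(f"unsupported source type {type(source)!r}")

    numerator, denominator = (
        (acceptor, donor) if orientation == "acceptor_over_donor" else (donor, acceptor)
    )
    valid = (denominator > 0) & (donor + acceptor >= min_intensity)
    if saturated is not None:
        valid &= ~saturated
    ratio = np.full(donor.shape, np.nan)
    np.divide(numerator, denominator, out=ratio, where=valid)
    return FretMap(ratio=ratio, valid=valid, min_intensity_used=float(min_intensity))
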