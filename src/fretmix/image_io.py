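"""Reading and writing of multi-channel acquisitions, FRET maps and label masks.

All raster I/O goes through plain (multi-page) grayscale TIFF. Channel
identity is always supplied explicitly by the caller via a page-index ->
role mapping; it is never guessed from file metadata, because microscope
TIFF dialects are inconsistent. Pixel grids are row-major, (row, column)
indexed. No operation rescales or clips intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "ChannelImage",
    "AcquisitionSet",
    "LabelMask",
    "CHANNEL_ROLES",
    "DEFAULT_CHANNEL_METADATA",
    "read_acquisition",
    "write_acquisition",
    "write_fret_map",
    "read_fret_map",
    "read_label_mask",
    "write_label_mask",
]

CHANNEL_ROLES = ("donor", "acceptor", "autofluo")

#: emission windows (center, half-width) and excitation used when the caller
#: does not supply wavelength metadata
DEFAULT_CHANNEL_METADATA = {
    "donor": {"emission_center_nm": 490.0, "emission_halfwidth_nm": 5.0, "excitation_nm": 458.0},
    "acceptor": {"emission_center_nm": 530.0, "emission_halfwidth_nm": 5.0, "excitation_nm": 458.0},
    "autofluo": {"emission_center_nm": 600.0, "emission_halfwidth_nm": 5.0, "excitation_nm": 458.0},
}


@dataclass
class ChannelImage:
    """A single emission-window image of non-negative photon counts."""

    pixels: np.ndarray
    channel_role: str
    emission_center_nm: float
    emission_halfwidth_nm: float
    excitation_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid of size >= 1x1")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")
        if not self.emission_center_nm > self.excitation_nm:
            raise ValueError("emission_center_nm must exceed excitation_nm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AcquisitionSet:
    """Three co-registered channel images forming one acquisition.

    ``saturation_mask`` flags pixels that sat at the detector dtype maximum
    in *any* channel of an integer-typed source file; these are excluded
    from downstream ratio computation.  ``background_corrected`` marks the
    output of constant-background subtraction, whose donor/acceptor channels
    are treated directly as abundances by ``compute_fret_map``.
    """

    donor: ChannelImage
    acceptor: ChannelImage
    autofluo: ChannelImage
    time_index: int | None = None
    sample_id: str = ""
    saturation_mask: np.ndarray | None = None
    background_corrected: bool = False

    def __post_init__(self) -> None:
        shapes = {self.donor.shape, self.acceptor.shape, self.autofluo.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel images must share dimensions, got {shapes}")
        roles = (self.donor.channel_role, self.acceptor.channel_role, self.autofluo.channel_role)
        if roles != CHANNEL_ROLES:
            raise ValueError(f"channel roles misassigned: {roles}")
        excitations = {self.donor.excitation_nm, self.acceptor.excitation_nm, self.autofluo.excitation_nm}
        if len(excitations) != 1:
            raise ValueError("excitation_nm must be identical across channels of one acquisition")
        if self.time_index is not None and self.time_index < 0:
            raise ValueError("time_index must be non-negative")
        if self.saturation_mask is not None:
            self.saturation_mask = np.asarray(self.saturation_mask, dtype=bool)
            if self.saturation_mask.shape != self.donor.shape:
                raise ValueError("saturation_mask dimensions must match the channel images")

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor.shape

    def stack(self) -> np.ndarray:
        """Channels as an (H, W, 3) array in (donor, acceptor, autofluo) order."""
        return np.stack([self.donor.pixels, self.acceptor.pixels, self.autofluo.pixels], axis=-1)


@dataclass
class LabelMask:
    """Integer ROI mask: 0 = background, k > 0 = ROI/cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int64)
            if not np.array_equal(as_int, labels):
                raise ValueError("label values must be integers")
            labels = as_int
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _make_channel(plane: np.ndarray, role: str, metadata: Mapping[str, Mapping[str, float]] | None) -> ChannelImage:
    meta = dict(DEFAULT_CHANNEL_METADATA[role])
    if metadata is not None and role in metadata:
        meta.update(metadata[role])
    return ChannelImage(pixels=plane, channel_role=role, **meta)


def read_acquisition(
    path: str | os.PathLike,
    channel_order: Mapping[int, str],
    metadata: Mapping[str, Mapping[str, float]] | None = None,
    time_index: int | None = None,
    sample_id: str | None = None,
) -> AcquisitionSet:
    """Read a multi-page TIFF into an :class:`AcquisitionSet`.

    Parameters
    ----------
    path:
        Multi-page (or 3-D multi-channel) grayscale TIFF with >= 3 planes.
    channel_order:
        Mapping of page index -> channel role covering each of
        ``donor``, ``acceptor``, ``autofluo`` exactly once.
    metadata:
        Optional per-role wavelength settings overriding the defaults.

    Pixel data are cast to float64 without rescaling.  For integer-typed
    files, pixels equal to the dtype maximum in any selected plane are
    flagged in the acquisition's saturation mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    planes = tifffile.imread(str(path))
    planes = np.asarray(planes)
    if planes.ndim == 2:
        planes = planes[None, ...]
    if planes.ndim != 3:
        raise ValueError(f"expected a stack of 2-D planes, got array of shape {planes.shape}")
    if planes.shape[0] < 3:
        raise ValueError(f"need >= 3 planes, file has {planes.shape[0]}")

    roles = list(channel_order.values())
    if sorted(roles) != sorted(CHANNEL_ROLES):
        raise ValueError(f"channel_order must cover {CHANNEL_ROLES} exactly once, got {roles}")
    for idx in channel_order:
        if not 0 <= idx < planes.shape[0]:
            raise ValueError(f"channel_order page index {idx} out of range for {planes.shape[0]} planes")

    saturation = np.zeros(planes.shape[1:], dtype=bool)
    if np.issubdtype(planes.dtype, np.integer):
        dtype_max = np.iinfo(planes.dtype).max
        for idx in channel_order:
            saturation |= planes[idx] == dtype_max

    by_role = {role: _make_channel(planes[idx], role, metadata) for idx, role in channel_order.items()}
    return AcquisitionSet(
        donor=by_role["donor"],
        acceptor=by_role["acceptor"],
        autofluo=by_role["autofluo"],
        time_index=time_index,
        sample_id=sample_id if sample_id is not None else path.stem,
        saturation_mask=saturation if saturation.any() else None,
    )


def write_acquisition(acq: AcquisitionSet, path: str | os.PathLike) -> None:
    """Write an acquisition as a 3-page float32 TIFF (donor, acceptor, autofluo)."""
    stack = np.stack(
        [acq.donor.pixels, acq.acceptor.pixels, acq.autofluo.pixels]
    ).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric='minisblack')


def _mask_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_mask" + path.suffix)


def write_fret_map(fret_map, path: str | os.PathLike) -> None:
    """Write a FRET map as a float32 TIFF, NaN at invalid pixels, plus a
    uint8 sidecar validity-mask TIFF at ``<stem>_mask<suffix>``."""
    path = Path(path)
    ratio = np.array(fret_map.ratio, dtype=np.float32)
    ratio[~fret_map.valid] = np.nan
    tifffile.imwrite(str(path), ratio, photometric='minisblack')
    tifffile.imwrite(str(_mask_sidecar_path(path)), fret_map.valid.astype(np.uint8), photometric='minisblack')


def read_fret_map(path: str | os.PathLike, min_intensity_used: float = 0.0):
    """Read back a FRET map written by :func:`write_fret_map`."""
    from .unmixing import FretMap  # local import to avoid a cycle

    path = Path(path)
    ratio = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    mask_path = _mask_sidecar_path(path)
    if mask_path.exists():
        valid = np.asarray(tifffile.imread(str(mask_path))).astype(bool)
    else:
        valid = np.isfinite(ratio)
    return FretMap(ratio=ratio, valid=valid, min_intensity_used=min_intensity_used)


def read_label_mask(path: str | os.PathLike, reference_shape: tuple[int, int] | None = None) -> LabelMask:
    """Read a single-plane integer TIFF as a :class:`LabelMask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = np.asarray(tifffile.imread(str(path)))
    if labels.ndim == 3 and labels.shape[0] == 1:
        labels = labels[0]
    mask = LabelMask(labels=labels)  # validates integrality
    if reference_shape is not None and mask.shape != tuple(reference_shape):
        raise ValueError(f"mask shape {mask.shape} does not match reference {tuple(reference_shape)}")
    return mask


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.int32
    tifffile.imwrite(str(path), labels.astype(dtype), photometric='minisblack')
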