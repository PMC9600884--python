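"""Preprocessing: spatial crop, craniocaudal cutoff, resampling, HU normalization.

The pipeline that feeds the segmentation model is::

    crop -> craniocaudal cutoff -> in-plane resample -> slice resample -> normalize

A 512x512 scan cropped by 20 % per edge becomes 307x307, then is resampled to
256x256; the stack keeps only the cranial 40 cm and is resampled to 128 slices,
giving the model grid (128, 256, 256).  Intensities are rescaled to [0, 1]
either with a fixed HU window (hard: 1..2500 HU, clipping outside — metal ends
up at 1.0) or the volume's own min/max (soft).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .volume_io import CTVolume, MaskVolume


@dataclasses.dataclass
class NormalizationScheme:
    """Intensity rescaling scheme: fixed HU window (``hard``) or per-volume min/max (``soft``)."""

    mode: str = "hard"
    hard_min_hu: float = 1.0
    hard_max_hu: float = 2500.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"mode must be 'hard' or 'soft', got {self.mode!r}")
        if not self.hard_min_hu < self.hard_max_hu:
            raise ValueError("hard_min_hu must be < hard_max_hu")


@dataclasses.dataclass
class PreprocessConfig:
    crop_fraction: float = 0.2
    target_slice_shape: tuple[int, int] = (256, 256)
    target_n_slices: int = 128
    craniocaudal_cutoff_mm: float = 400.0
    normalization: NormalizationScheme = dataclasses.field(default_factory=NormalizationScheme)

    def __post_init__(self) -> None:
        if not 0 <= self.crop_fraction < 0.5:
            raise ValueError(f"crop_fraction must be in [0, 0.5), got {self.crop_fraction}")
        if min(self.target_slice_shape) < 1 or self.target_n_slices < 1:
            raise ValueError("all target extents must be >= 1")
        if self.craniocaudal_cutoff_mm <= 0:
            raise ValueError("craniocaudal_cutoff_mm must be > 0")
        if isinstance(self.normalization, dict):
            self.normalization = NormalizationScheme(**self.normalization)


def _array_of(obj):
    if isinstance(obj, CTVolume):
        return obj.voxels, False
    if isinstance(obj, MaskVolume):
        return obj.labels, True
    raise TypeError(f"expected CTVolume or MaskVolume, got {type(obj)}")


def crop_window(extent: int, crop_fraction: float) -> tuple[int, int]:
    """Centered retained window ``[start, stop)`` for one in-plane extent.

    The retained extent is ``floor(d * (1 - 2f))`` with the leading margin
    ``floor(d * f)``; any rounding remainder trails (512 at f=0.2 -> 307 kept,
    margins 102/103).
    """
    keep = math.floor(extent * (1.0 - 2.0 * crop_fraction))
    lead = math.floor(extent * crop_fraction)
    return lead, lead + keep


def spatial_crop(volume_or_mask, crop_fraction: float):
    """Crop the same centered fraction off all four in-plane edges."""
    if not 0 <= crop_fraction < 0.5:
        raise ValueError(f"crop_fraction must be in [0, 0.5), got {crop_fraction}")
    arr, _ = _array_of(volume_or_mask)
    _, h, w = arr.shape
    r0, r1 = crop_window(h, crop_fraction)
    c0, c1 = crop_window(w, crop_fraction)
    if r1 - r0 < 1 or c1 - c0 < 1:
        raise ValueError("in-plane extent would drop below 1 after cropping")
    return volume_or_mask.copy_with(arr[:, r0:r1, c0:c1].copy())


def craniocaudal_cutoff(volume: CTVolume, mask: MaskVolume | None = None,
                        cutoff_mm: float = 400.0):
    """Keep only the slices within ``cutoff_mm`` of the cranial end of the stack.

    Retains the first ``min(n, ceil(cutoff / thickness))`` cranial slices (the
    boundary slice whose center sits exactly at the cutoff offset is excluded).
    A mask, if given, is cut identically.
    """
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be > 0")
    n = volume.n_slices
    keep = min(n, math.ceil(cutoff_mm / volume.slice_thickness_mm))
    sl = slice(0, keep) if volume.cranial_first else slice(n - keep, n)
    out_vol = volume.copy_with(volume.voxels[sl].copy())
    if mask is None:
        return out_vol
    if mask.labels.shape != volume.voxels.shape:
        raise ValueError("mask and volume shapes differ")
    return out_vol, mask.copy_with(mask.labels[sl].copy())


def _zoom(arr: np.ndarray, factors, is_mask: bool) -> np.ndarray:
    out = ndimage.zoom(arr, factors, order=0 if is_mask else 1, mode="nearest")
    return out


def resample_inplane(volume_or_mask, target_shape: tuple[int, int]):
    """Resample each slice to ``target_shape`` (bilinear for HU, nearest for labels)."""
    th, tw = target_shape
    if th < 1 or tw < 1:
        raise ValueError("target extents must be >= 1")
    arr, is_mask = _array_of(volume_or_mask)
    _, h, w = arr.shape
    if (h, w) == (th, tw):
        return volume_or_mask.copy_with(arr.copy())
    out = _zoom(arr, (1.0, th / h, tw / w), is_mask)
    assert out.shape[1:] == (th, tw)
    st, ph, pw = volume_or_mask.spacing
    new_spacing = (st, ph * h / th, pw * w / tw)
    return volume_or_mask.copy_with(out, spacing=new_spacing)


def resample_slices(volume_or_mask, target_n_slices: int):
    """Resample the slice axis to ``target_n_slices`` (linear for HU, nearest for labels)."""
    if target_n_slices < 1:
        raise ValueError("target_n_slices must be >= 1")
    arr, is_mask = _array_of(volume_or_mask)
    n = arr.shape[0]
    if n == target_n_slices:
        return volume_or_mask.copy_with(arr.copy())
    out = _zoom(arr, (target_n_slices / n, 1.0, 1.0), is_mask)
    assert out.shape[0] == target_n_slices
    st, ph, pw = volume_or_mask.spacing
    return volume_or_mask.copy_with(out, spacing=(st * n / target_n_slices, ph, pw))


def normalize(volume: CTVolume, scheme: NormalizationScheme) -> CTVolume:
    """Map HU to [0, 1].

    hard
        Clip to ``[hard_min_hu, hard_max_hu]`` then rescale linearly so the
        window endpoints map to 0 and 1.
    soft
        Rescale the volume's own min to 0 and max to 1.  A constant volume
        maps to all zeros (documented degenerate case, not an error).
    """
    x = volume.voxels
    if scheme.mode == "hard":
        lo, hi = scheme.hard_min_hu, scheme.hard_max_hu
        out = (np.clip(x, lo, hi) - lo) / (hi - lo)
    else:
        lo, hi = float(x.min()), float(x.max())
        out = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return volume.copy_with(out.astype(np.float32))


def preprocess_volume(volume: CTVolume, mask: MaskVolume | None = None,
                      config: PreprocessConfig | None = None):
    """Run the full preprocessing chain on a volume (and optionally its mask)."""
    cfg = config or PreprocessConfig()
    vol = spatial_crop(volume, cfg.crop_fraction)
    msk = spatial_crop(mask, cfg.crop_fraction) if mask is not None else None
    if msk is not None:
        vol, msk = craniocaudal_cutoff(vol, msk, cfg.craniocaudal_cutoff_mm)
    else:
        vol = craniocaudal_cutoff(vol, None, cfg.craniocaudal_cutoff_mm)
    vol = resample_inplane(vol, cfg.target_slice_shape)
    vol = resample_slices(vol, cfg.target_n_slices)
    vol = normalize(vol, cfg.normalization)
    if msk is None:
        return vol
    msk = resample_inplane(msk, cfg.target_slice_shape)
    msk = resample_slices(msk, cfg.target_n_slices)
    return vol, msk


class CTPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the full preprocessing chain to CT volumes.

    Parameters mirror :class:`PreprocessConfig`; ``transform`` consumes a
    :class:`CTVolume` (or list of volumes) and returns the preprocessed
    object(s); ``transform_pair`` preprocesses a volume together with its mask
    so the two stay voxel-aligned.
    """

    def __init__(self, crop_fraction: float = 0.2,
                 target_slice_shape: tuple[int, int] = (256, 256),
                 target_n_slices: int = 128,
                 craniocaudal_cutoff_mm: float = 400.0,
                 normalization_mode: str = "hard",
                 hard_min_hu: float = 1.0,
                 hard_max_hu: float = 2500.0):
        self.crop_fraction = crop_fraction
        self.target_slice_shape = target_slice_shape
        self.target_n_slices = target_n_slices
        self.craniocaudal_cutoff_mm = craniocaudal_cutoff_mm
        self.normalization_mode = normalization_mode
        self.hard_min_hu = hard_min_hu
        self.hard_max_hu = hard_max_hu

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            crop_fraction=self.crop_fraction,
            target_slice_shape=tuple(self.target_slice_shape),
            target_n_slices=self.target_n_slices,
            craniocaudal_cutoff_mm=self.craniocaudal_cutoff_mm,
            normalization=NormalizationScheme(
                mode=self.normalization_mode,
                hard_min_hu=self.hard_min_hu,
                hard_max_hu=self.hard_max_hu,
            ),
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        cfg = self._config()
        if isinstance(X, CTVolume):
            return preprocess_volume(X, None, cfg)
        return [preprocess_volume(v, None, cfg) for v in X]

    def transform_pair(self, volume: CTVolume, mask: MaskVolume):
        return preprocess_volume(volume, mask, self._config())
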