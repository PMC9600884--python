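"""Training-time augmentation: random resize-crop, horizontal flip, rotation.

Every geometric transform is applied identically to the image slice and its
label slice; images are interpolated bilinearly, labels with nearest-neighbor
so the label set never grows.  Augmentation is train-time only — prediction
always sees the unaugmented grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class AugmentConfig:
    """Magnitudes of the three augmentations.

    resize_margin_fraction
        The slice is upscaled by this fraction before a random crop back to the
        original size (a patch-style crop).  0 disables.
    hflip_probability
        Chance of a left-right flip.
    rotation_max_deg
        Rotation angle drawn uniformly from ``[-max, max]`` degrees; exposed
        corners are filled with background (0).
    """

    resize_margin_fraction: float = 0.1
    hflip_probability: float = 0.5
    rotation_max_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resize_margin_fraction < 0:
            raise ValueError("resize_margin_fraction must be >= 0")
        if not 0 <= self.hflip_probability <= 1:
            raise ValueError("hflip_probability must be in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")


def augment_pair(image_slice: np.ndarray, mask_slice: np.ndarray,
                 config: AugmentConfig, rng: np.random.Generator):
    """Apply one random resize-crop / flip / rotation draw to an (image, mask) pair.

    Output shapes equal input shapes; the same geometric transform hits both
    arrays; a given generator state yields identical outputs.  Transforms whose
    magnitude is zero are skipped exactly (identity configuration returns the
    inputs unchanged).
    """
    img = np.asarray(image_slice)
    msk = np.asarray(mask_slice)
    if img.shape != msk.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {msk.shape}")
    h, w = img.shape

    if config.resize_margin_fraction > 0:
        h2 = int(round(h * (1.0 + config.resize_margin_fraction)))
        w2 = int(round(w * (1.0 + config.resize_margin_fraction)))
        img = ndimage.zoom(img, (h2 / h, w2 / w), order=1, mode="nearest")
        msk = ndimage.zoom(msk, (h2 / h, w2 / w), order=0, mode="nearest")
        r0 = int(rng.integers(0, h2 - h + 1))
        c0 = int(rng.integers(0, w2 - w + 1))
        img = img[r0:r0 + h, c0:c0 + w]
        msk = msk[r0:r0 + h, c0:c0 + w]

    if config.hflip_probability > 0 and rng.random() < config.hflip_probability:
        img = img[:, ::-1]
        msk = msk[:, ::-1]

    if config.rotation_max_deg > 0:
        angle = float(rng.uniform(-config.rotation_max_deg, config.rotation_max_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant", cval=0)

    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


class SliceAugmenter:
    """Callable wrapper holding an :class:`AugmentConfig` and a stepped generator.

    Repeated calls consume the generator, so the same slice receives a
    different draw in every epoch; :meth:`reseed` restores determinism for a
    whole training run.
    """

    def __init__(self, config: AugmentConfig | None = None):
        self.config = config or AugmentConfig()
        self.reseed(self.config.seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def __call__(self, image_slice, mask_slice):
        return augment_pair(image_slice, mask_slice, self.config, self._rng)
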