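"""Reading and writing images, masks and component planes."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio


def imread_rgb(path) -> np.ndarray:
    """Load an 8-bit PNG/JPEG as an (H, W, 3) float image in [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:
        raw = raw[..., :3]
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    return np.clip(raw.astype(float), 0.0, 1.0)


def imwrite_rgb(path, image: np.ndarray) -> None:
    """Write a [0, 1] float RGB image as 8-bit PNG/JPEG."""
    iio.imwrite(path, (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8))


def imread_mask(path) -> np.ndarray:
    """Load a binary mask PNG (any nonzero pixel is foreground)."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 0


def imwrite_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit PNG (0 / 255)."""
    iio.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)


def imwrite_plane16(path, plane: np.ndarray) -> None:
    """Export a [0, 1] component plane as 16-bit grayscale PNG."""
    iio.imwrite(path, (np.clip(plane, 0.0, 1.0) * 65535).round().astype(np.uint16))
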