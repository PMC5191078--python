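"""Pixel classification and binary-mask cleanup.

The strong classifier is swept over the image with a sliding 7x7
window: each pixel's feature vector is the window mean of every
component plane the classifier needs, and the pixel is set to 1 (grape)
where the weighted vote is strictly positive.  The raw mask is then
denoised by relative-size region filtering, disc opening/closing and
hole filling before regions are extracted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .boost import StrongClassifier
from .color import extract_components, window_mean


def classify_pixels(
    image: np.ndarray, clf: StrongClassifier, window: int = 7
) -> np.ndarray:
    """Classify every pixel of an RGB image; returns a boolean mask.

    Features are window means (reflective padding at the borders rather
    than shrinking the mask) of the component planes required by the
    classifier.  Mask value True means grape (vote score > 0).
    """
    if min(image.shape[:2]) < window:
        raise ValueError(
            f"image {image.shape[:2]} smaller than the {window}x{window} window"
        )
    planes = extract_components(image, clf.required_components)
    features = {cid: window_mean(plane, window) for cid, plane in planes.items()}
    return np.asarray(clf.classify(features)) == 1


def filter_small_regions(
    mask: np.ndarray, fraction: float = 1 / 10, connectivity: int = 8
) -> np.ndarray:
    """Drop connected regions smaller than ``fraction`` of the biggest.

    The largest region always survives.  An empty mask passes through
    unchanged.  ``connectivity`` is 4 or 8 (pixel adjacency).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=_skimage_connectivity(connectivity))
    if labels.max() == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    cutoff = fraction * areas.max()
    keep = areas >= cutoff
    keep[0] = False
    return keep[labels]


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def disc_element(radius: int) -> np.ndarray:
    """Disc structuring element {(dx, dy): dx^2 + dy^2 <= r^2}."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    coords = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(coords, coords)
    return (dx**2 + dy**2) <= radius**2


def morphological_clean(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Binary opening then closing with a disc element of ``radius``.

    Opening discards adhesion specks narrower than the disc; closing
    seals cracks and recovers the cluster contour.
    """
    mask = np.asarray(mask, dtype=bool)
    selem = disc_element(radius)
    opened = morphology.opening(mask, selem)
    return morphology.closing(opened, selem).astype(bool)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not connected to the image border."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(mask)


def clean_mask(
    mask: np.ndarray,
    fraction: float = 1 / 10,
    radius: int = 5,
    connectivity: int = 8,
) -> np.ndarray:
    """Full noise-elimination chain: region filter, open/close, fill."""
    mask = filter_small_regions(mask, fraction=fraction, connectivity=connectivity)
    mask = morphological_clean(mask, radius=radius)
    return fill_holes(mask)
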