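"""Color-component transforms and image preprocessing.

Pixel classification works on scalar color components derived from RGB:
hue ``H`` (HSI), chroma-blue ``Cb`` (YCbCr), the yellow-blue axis ``b*``
(CIELab), and the raw normalized ``R``, ``G``, ``B`` channels.  Dark
purple grape berries are well separated from leaf/branch/sky/soil
backgrounds on each of these axes, though imperfectly on any single one.

All transforms take RGB in [0, 1] and return values normalized to [0, 1]
so that thresholds learned on training samples apply directly to
component planes of whole images.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

#: Component identifiers accepted throughout the package.
COMPONENTS = ("H", "Cb", "bstar", "R", "G", "B")

_ALIASES = {"b*": "bstar", "Lab_b": "bstar"}

# RGB -> XYZ matrix, scaled by 1/0.17697 so that Y is on the same scale
# as the classic CIE RGB definition.
_XYZ_MATRIX = (
    np.array(
        [
            [0.49, 0.31, 0.20],
            [0.17697, 0.8124, 0.01063],
            [0.00, 0.01, 0.99],
        ]
    )
    / 0.17697
)

#: Affine normalization constants mapping raw b* onto [0, 1]:
#: normalized = (b_raw - BSTAR_LO) / (BSTAR_HI - BSTAR_LO), then clipped.
BSTAR_LO = -128.0
BSTAR_HI = 127.0


def canonical_component(cid: str) -> str:
    """Resolve a component id (accepting the ``b*`` alias) or raise."""
    cid = _ALIASES.get(cid, cid)
    if cid not in COMPONENTS:
        raise ValueError(f"unknown color component {cid!r}; expected one of {COMPONENTS}")
    return cid


def _as_float(*channels):
    arrays = np.broadcast_arrays(*(np.asarray(c, dtype=float) for c in channels))
    return arrays


def rgb_to_hue(r, g, b):
    """HSI hue of RGB values in [0, 1], returned normalized to [0, 1].

    theta = arccos{ 0.5[(R-G)+(R-B)] / sqrt[(R-G)^2 + (R-B)(G-B)] };
    H = theta if B <= G else 360 - theta (degrees), divided by 360.

    Achromatic pixels (zero denominator, i.e. R = G = B) return 0 by
    convention: any constant would do, since such pixels carry no hue
    information, and 0 is conventional.  The arccos argument is clamped
    to [-1, 1] to absorb floating-point drift.
    """
    r, g, b = _as_float(r, g, b)
    num = 0.5 * ((r - g) + (r - b))
    den_sq = (r - g) ** 2 + (r - b) * (g - b)
    den = np.sqrt(np.maximum(den_sq, 0.0))
    achromatic = den == 0
    arg = np.clip(np.divide(num, np.where(achromatic, 1.0, den)), -1.0, 1.0)
    theta = np.degrees(np.arccos(arg))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(achromatic, 0.0, hue) / 360.0
    return hue if hue.ndim else float(hue)


def rgb_to_cb(r, g, b):
    """YCbCr chroma-blue of RGB in [0, 1], normalized to [0, 1].

    Cb = (-0.1687 R - 0.3313 G + 0.500 B) + 128 on the 0-255 scale,
    clipped to [0, 255], then divided by 255.  The coefficients cancel
    exactly for gray pixels, which map to 128/255.
    """
    r, g, b = _as_float(r, g, b)
    cb = (-0.1687 * r - 0.3313 * g + 0.500 * b) * 255.0 + 128.0
    cb = np.clip(cb, 0.0, 255.0) / 255.0
    return cb if cb.ndim else float(cb)


def _lab_f(t):
    t = np.asarray(t, dtype=float)
    return np.where(t > 0.008856, np.cbrt(np.maximum(t, 0.0)), 7.787 * t + 0.138)


def rgb_to_bstar(r, g, b, normalized: bool = True):
    """CIELab b* of RGB in [0, 1].

    [X Y Z] = (1/0.17697) M [R G B]; b* = 200 [f(Y) - f(Z/1.192)] with
    f(t) = t^(1/3) for t > 0.008856 else 7.787 t + 0.138.

    With ``normalized=True`` (default) the raw value is mapped onto
    [0, 1] by the fixed affine map (b* - BSTAR_LO)/(BSTAR_HI - BSTAR_LO)
    and clipped; the constants are module attributes because no single
    canonical scale exists for this quantity.
    """
    r, g, b = _as_float(r, g, b)
    rgb = np.stack([r, g, b], axis=-1)
    xyz = rgb @ _XYZ_MATRIX.T
    y = xyz[..., 1]
    z = xyz[..., 2]
    bstar = 200.0 * (_lab_f(y) - _lab_f(z / 1.192))
    if normalized:
        bstar = np.clip((bstar - BSTAR_LO) / (BSTAR_HI - BSTAR_LO), 0.0, 1.0)
    return bstar if bstar.ndim else float(bstar)


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return image


def extract_components(image: np.ndarray, ids: Iterable[str]) -> dict[str, np.ndarray]:
    """Compute the requested component planes of an RGB image.

    Parameters
    ----------
    image : (H, W, 3) float array with values in [0, 1]
    ids : iterable of component ids from :data:`COMPONENTS` (``b*`` is
        accepted as an alias of ``bstar``)

    Returns
    -------
    dict mapping each canonical id to an (H, W) plane in [0, 1];
    R/G/B are returned as the raw channels.
    """
    image = _validate_image(image)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    planes: dict[str, np.ndarray] = {}
    for cid in ids:
        cid = canonical_component(cid)
        if cid in planes:
            continue
        if cid == "H":
            planes[cid] = rgb_to_hue(r, g, b)
        elif cid == "Cb":
            planes[cid] = rgb_to_cb(r, g, b)
        elif cid == "bstar":
            planes[cid] = rgb_to_bstar(r, g, b)
        else:
            planes[cid] = image[..., "RGB".index(cid)].copy()
    return planes


def mean_filter(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Per-channel box mean over a ``kernel`` x ``kernel`` neighborhood.

    Reflective border padding keeps output size equal to input;
    ``kernel=1`` is the identity.  Used to suppress illumination noise
    before component extraction.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    image = _validate_image(image)
    if kernel == 1:
        return image.copy()
    return ndimage.uniform_filter(image, size=(kernel, kernel, 1), mode="reflect")


def window_mean(plane: np.ndarray, window: int = 7) -> np.ndarray:
    """Mean of the ``window`` x ``window`` neighborhood centered on each pixel.

    This is the feature fed to the classifiers: training samples are the
    window means of hand-cropped patches, and sliding-window inference
    uses the same statistic at every pixel (stride 1, reflective
    padding).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    if min(plane.shape) < window:
        raise ValueError(f"plane {plane.shape} smaller than window {window}")
    if window == 1:
        return plane.copy()
    return ndimage.uniform_filter(plane, size=window, mode="reflect")


def resize_bicubic(image: np.ndarray, target: tuple[int, int] = (600, 800)) -> np.ndarray:
    """Bicubic resample of an RGB image to ``target`` (rows, cols) in [0, 1]."""
    image = _validate_image(image)
    rows, cols = target
    if rows <= 0 or cols <= 0:
        raise ValueError(f"target dimensions must be positive, got {target}")
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    out = _skimage_resize(image, (rows, cols), order=3, mode="reflect", anti_aliasing=None)
    return np.clip(out, 0.0, 1.0)


def sample_features(
    image: np.ndarray, ids: Iterable[str], window: int = 7
) -> dict[str, np.ndarray]:
    """Component planes followed by the 7x7 window mean of each plane."""
    planes = extract_components(image, ids)
    return {cid: window_mean(plane, window) for cid, plane in planes.items()}


def features_at(planes: Mapping[str, np.ndarray], row: int, col: int) -> dict[str, float]:
    """Scalar feature vector of one pixel from precomputed planes."""
    return {cid: float(p[row, col]) for cid, p in planes.items()}
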