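"""Cluster extraction: regions, barycenter splitting, enclosing rectangles.

After segmentation, each 8-connected foreground region becomes a
candidate grape cluster marked by its tightest axis-aligned bounding
box (the "enclosing rectangle" handed to a harvesting robot).  A region
judged to hold two adjoining clusters — by the width/height ratio
heuristic, since adjoining clusters merge side by side into one wide
region — is split by a vertical line through its barycenter and each
half gets its own rectangle.

Coordinates are 0-based (row, col); bounding boxes are
(top, left, height, width), half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .boost import StrongClassifier
from .color import mean_filter
from .segment import classify_pixels, clean_mask, _skimage_connectivity


@dataclass(frozen=True)
class Region:
    """Connected pixel region with area, barycenter and bounding box."""

    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.rows) == 0 or len(self.rows) != len(self.cols):
            raise ValueError("a region needs at least one pixel")

    @property
    def area(self) -> int:
        return len(self.rows)

    @property
    def barycenter(self) -> tuple[float, float]:
        return (float(self.rows.mean()), float(self.cols.mean()))

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(top, left, height, width) — the tightest enclosing rectangle."""
        top = int(self.rows.min())
        left = int(self.cols.min())
        return (top, left, int(self.rows.max()) - top + 1, int(self.cols.max()) - left + 1)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.rows, self.cols] = True
        return mask


@dataclass(frozen=True)
class Detection:
    """One detected cluster: enclosing rectangle + provenance."""

    bbox: tuple[int, int, int, int]
    region_id: int
    split: bool = False

    def bbox_1based_inclusive(self) -> tuple[int, int, int, int]:
        """(top, left, bottom, right), 1-based inclusive, for reports."""
        top, left, h, w = self.bbox
        return (top + 1, left + 1, top + h, left + w)


@dataclass
class DetectConfig:
    """Constants of the detection chain, with the method's defaults."""

    window: int = 7
    mean_kernel: int = 3
    region_fraction: float = 1 / 10
    disc_radius: int = 5
    connectivity: int = 8
    split_ratio: float = 1.4


def extract_regions(mask: np.ndarray, connectivity: int = 8) -> list[Region]:
    """Connected components of a mask, ordered by first raster pixel."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=_skimage_connectivity(connectivity))
    regions = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        regions.append(Region(rows=rows, cols=cols))
    # label order is already raster order of first encounter; make the
    # contract explicit by sorting on the topmost-leftmost pixel
    regions.sort(key=lambda r: (int(r.rows.min()), int(r.cols[r.rows == r.rows.min()].min())))
    return regions


def is_adjoining_pair(region: Region, ratio_threshold: float = 1.4) -> bool:
    """Heuristic: a region wider than tall (width/height > threshold)
    is taken to be two clusters merged side by side.

    Single hanging clusters are taller than wide, so a strongly
    landscape box signals lateral adhesion.  The criterion and its
    default threshold are this package's choice of trigger for the
    barycenter split.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    _, _, height, width = region.bbox
    return width / height > ratio_threshold


def split_at_barycenter(region: Region) -> tuple[Region, Region]:
    """Split a region by the vertical line through its barycenter.

    Pixels with column < barycenter column form the left part; pixels
    on or right of it form the right part (deterministic tie rule).
    """
    _, _, _, width = region.bbox
    if width < 2:
        raise ValueError("cannot split a region spanning a single column")
    _, bary_col = region.barycenter
    left_sel = region.cols < bary_col
    if not left_sel.any() or left_sel.all():
        # centroid coincides with the extreme column (degenerate mass
        # distribution): fall back to the bbox midline
        top, left, _, w = region.bbox
        left_sel = region.cols < left + w / 2
    assert left_sel.any() and not left_sel.all()
    left = Region(rows=region.rows[left_sel], cols=region.cols[left_sel])
    right = Region(rows=region.rows[~left_sel], cols=region.cols[~left_sel])
    return left, right


def regions_to_detections(
    regions: Sequence[Region], split_ratio: float = 1.4
) -> list[Detection]:
    detections = []
    for i, region in enumerate(regions):
        if is_adjoining_pair(region, split_ratio):
            left, right = split_at_barycenter(region)
            detections.append(Detection(left.bbox, region_id=i, split=True))
            detections.append(Detection(right.bbox, region_id=i, split=True))
        else:
            detections.append(Detection(region.bbox, region_id=i, split=False))
    return detections


def detect_clusters(
    image: np.ndarray,
    clf: StrongClassifier,
    config: DetectConfig | None = None,
    return_stages: bool = False,
):
    """Full detection chain on an RGB image in [0, 1].

    mean filter -> pixel classification -> region-size filter ->
    disc open/close -> hole fill -> region extraction -> conditional
    barycenter split -> enclosing rectangles.

    Returns the list of :class:`Detection`; with ``return_stages=True``
    also a dict of intermediate masks for inspection.
    """
    config = config or DetectConfig()
    smoothed = mean_filter(image, config.mean_kernel)
    raw = classify_pixels(smoothed, clf, window=config.window)
    cleaned = clean_mask(
        raw,
        fraction=config.region_fraction,
        radius=config.disc_radius,
        connectivity=config.connectivity,
    )
    regions = extract_regions(cleaned, connectivity=config.connectivity)
    detections = regions_to_detections(regions, split_ratio=config.split_ratio)
    if return_stages:
        return detections, {"raw": raw, "cleaned": cleaned, "regions": regions}
    return detections


def draw_detections(
    image: np.ndarray, detections: Sequence[Detection], thickness: int = 2
) -> np.ndarray:
    """Overlay detection rectangles (red) on a copy of the image."""
    out = np.asarray(image, dtype=float).copy()
    color = np.array([1.0, 0.1, 0.1])
    h_img, w_img = out.shape[:2]
    for det in detections:
        top, left, h, w = det.bbox
        bottom, right = min(top + h, h_img), min(left + w, w_img)
        for t in range(thickness):
            r0, r1 = max(top - t, 0), min(bottom + t, h_img - 1)
            c0, c1 = max(left - t, 0), min(right + t, w_img - 1)
            out[r0, c0 : c1 + 1] = color
            out[r1, c0 : c1 + 1] = color
            out[r0 : r1 + 1, c0] = color
            out[r0 : r1 + 1, c1] = color
    return out
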