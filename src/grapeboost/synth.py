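"""Synthetic vineyard fixtures: labeled pixel samples and whole scenes.

Real training data for this method is a set of 7x7 windows hand-cropped
from vineyard photographs (dark purple berries vs. leaf / branch / sky
/ soil backgrounds under three illumination regimes), plus whole images
for detection.  This module emulates that dataset so the full pipeline
is trainable and testable without any download:

* class colors are Gaussians in RGB, clipped to [0, 1], with defaults
  chosen so each of the four color-component families (H, Cb, b*, B/R
  line) is individually informative but none is perfect;
* illumination regimes are affine intensity transforms (gain/offset)
  plus sparse specular highlight pixels — enough to stress classifier
  robustness, with no claim to physical rendering;
* scenes render clusters as unions of overlapping berry discs over
  layered backgrounds, with exact ground-truth masks and boxes.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .color import COMPONENTS, extract_components

#: (gain, offset, highlight probability) per illumination regime.
ILLUMINATION = {
    "frontlight": (1.15, 0.03, 0.010),
    "overshadow": (0.72, -0.03, 0.000),
    "overcast": (0.95, 0.00, 0.002),
    "none": (1.0, 0.0, 0.0),
}

REGIMES = ("frontlight", "overshadow", "overcast")

#: Mixing weights of the three regimes in a mixed sample draw,
#: proportional to the 60/60/80 composition of the emulated image set.
REGIME_WEIGHTS = {"frontlight": 60, "overshadow": 60, "overcast": 80}


@dataclass(frozen=True)
class ColorClass:
    """Gaussian RGB color model of one scene material."""

    mean: tuple[float, float, float]
    std: float  # instance-to-instance spread of the base color
    jitter: float = 0.04  # per-pixel texture noise


#: Dark purple berries: low G, B slightly above R.
GRAPE = ColorClass(mean=(0.26, 0.10, 0.30), std=0.07)

BACKGROUND_LAYERS = {
    "leaf": ColorClass(mean=(0.25, 0.55, 0.20), std=0.08),
    "branch": ColorClass(mean=(0.45, 0.30, 0.16), std=0.08),
    "sky": ColorClass(mean=(0.72, 0.82, 0.94), std=0.08),
    "soil": ColorClass(mean=(0.52, 0.42, 0.33), std=0.08),
}

#: How often each background material appears among cropped samples,
#: mirroring the material composition of the rendered scenes.
BACKGROUND_WEIGHTS = {"leaf": 0.50, "branch": 0.12, "sky": 0.23, "soil": 0.15}


@dataclass
class SceneSpec:
    """Everything that determines one synthetic scene (plus its seed).

    Geometry defaults are for a 300 x 400 working image: clusters are
    vertical ellipses of overlapping berry discs, roughly a third of
    the image tall, as hanging clusters appear at the method's working
    distance.
    """

    height: int = 300
    width: int = 400
    n_clusters: int = 2
    berries_per_cluster: int = 100
    berry_radius: tuple[int, int] = (6, 9)
    cluster_rx: int = 32  # horizontal semi-axis of the berry ellipse
    cluster_ry: int = 48  # vertical semi-axis
    adjoining: bool = False  # render 2 clusters touching side by side
    grape: ColorClass = GRAPE
    layers: dict = field(default_factory=lambda: dict(BACKGROUND_LAYERS))
    illumination: str = "overcast"
    pepper_density: float = 0.0  # fraction of pixels covered by grape-colored specks
    highlight_prob: float | None = None  # None: use the regime's value
    seed: int = 0


def _apply_illumination(rng, pixels: np.ndarray, regime: str, highlight_prob=None):
    if regime == "mixed":
        raise ValueError("'mixed' is only valid for sample generation")
    try:
        gain, offset, h_prob = ILLUMINATION[regime]
    except KeyError:
        raise ValueError(f"unknown illumination regime {regime!r}") from None
    if highlight_prob is not None:
        h_prob = highlight_prob
    out = pixels * gain + offset
    if h_prob > 0:
        flat = out.reshape(-1, 3)
        hits = rng.random(len(flat)) < h_prob
        flat[hits] = rng.uniform(0.92, 1.0, size=(hits.sum(), 3))
    return np.clip(out, 0.0, 1.0)


def _window_features(window: np.ndarray) -> dict[str, float]:
    planes = extract_components(window, COMPONENTS)
    return {cid: float(plane.mean()) for cid, plane in planes.items()}


def generate_samples(
    spec: SceneSpec | None = None,
    n_grape: int = 400,
    n_background: int = 800,
    seed: int = 0,
    window: int = 7,
    illumination: str = "mixed",
) -> pd.DataFrame:
    """Draw labeled 7x7-window samples from the class color models.

    Each sample is one window: a base color from the class Gaussian,
    per-pixel jitter, an illumination transform, then the window mean
    of every color component.  Default sizes mirror the emulated
    training set (400 grape / 800 background).  ``illumination`` may be
    a regime name or ``"mixed"`` (draw regimes with the 60/60/80 image
    weights).
    """
    if n_grape < 1 or n_background < 1:
        raise ValueError("need at least one sample per class")
    spec = spec or SceneSpec()
    for cls in [spec.grape, *spec.layers.values()]:
        if cls.std < 0 or cls.jitter < 0:
            raise ValueError("color spreads must be nonnegative")
    rng = np.random.default_rng(seed)
    regimes = list(REGIME_WEIGHTS)
    regime_p = np.array([REGIME_WEIGHTS[r] for r in regimes], dtype=float)
    regime_p /= regime_p.sum()
    layer_names = list(spec.layers)
    layer_p = np.array([BACKGROUND_WEIGHTS.get(n, 0.1) for n in layer_names])
    layer_p /= layer_p.sum()

    rows = []
    for label, n in ((1, n_grape), (-1, n_background)):
        for _ in range(n):
            if label == 1:
                cls = spec.grape
            else:
                cls = spec.layers[rng.choice(layer_names, p=layer_p)]
            base = np.asarray(cls.mean) + rng.normal(0.0, cls.std, size=3)
            window_px = base + rng.normal(0.0, cls.jitter, size=(window, window, 3))
            window_px = np.clip(window_px, 0.0, 1.0)
            regime = (
                rng.choice(regimes, p=regime_p) if illumination == "mixed" else illumination
            )
            window_px = _apply_illumination(rng, window_px, regime)
            features = _window_features(window_px)
            features["label"] = label
            rows.append(features)
    return pd.DataFrame(rows, columns=[*COMPONENTS, "label"]).astype({"label": int})


# -- whole scenes -----------------------------------------------------


def _paint_disc(image, mask, row, col, radius, color):
    h, w = mask.shape
    r0, r1 = max(row - radius, 0), min(row + radius + 1, h)
    c0, c1 = max(col - radius, 0), min(col + radius + 1, w)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    disc = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    if color is not None:
        image[r0:r1, c0:c1][disc] = color
    mask[r0:r1, c0:c1] |= disc


def _render_background(rng, spec: SceneSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    leaf = spec.layers["leaf"]
    # leaf wall with low-frequency lighting variation + pixel texture
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=18.0)
    lowfreq = 0.35 * lowfreq / max(np.abs(lowfreq).max(), 1e-9)
    image = np.asarray(leaf.mean) + lowfreq[..., None] * 0.2
    image = image + rng.normal(0.0, leaf.jitter, size=(h, w, 3))
    # sky band at the top, soil band at the bottom
    sky, soil = spec.layers["sky"], spec.layers["soil"]
    sky_rows = max(int(0.14 * h), 1)
    soil_rows = max(int(0.10 * h), 1)
    image[:sky_rows] = np.asarray(sky.mean) + rng.normal(0.0, sky.jitter, (sky_rows, w, 3))
    image[-soil_rows:] = np.asarray(soil.mean) + rng.normal(
        0.0, soil.jitter, (soil_rows, w, 3)
    )
    # a few branches: thin brown near-vertical strips
    branch = spec.layers["branch"]
    for _ in range(rng.integers(2, 5)):
        col = int(rng.integers(0, w))
        slope = rng.uniform(-0.2, 0.2)
        width = int(rng.integers(2, 4))
        rows = np.arange(sky_rows, h - soil_rows)
        cols = (col + slope * (rows - sky_rows)).astype(int)
        for dr in range(width):
            cc = np.clip(cols + dr, 0, w - 1)
            image[rows, cc] = np.asarray(branch.mean) + rng.normal(
                0.0, branch.jitter, (len(rows), 3)
            )
    return np.clip(image, 0.0, 1.0)


def _cluster_centers(rng, spec: SceneSpec) -> list[tuple[int, int]]:
    h, w = spec.height, spec.width
    if spec.adjoining:
        if spec.n_clusters != 2:
            raise ValueError("adjoining scenes render exactly 2 clusters")
        row = int(0.5 * h)
        gap = int(1.6 * spec.cluster_rx)  # ellipses overlap, masks touch
        mid = w // 2
        return [(row, mid - gap // 2), (row, mid + gap - gap // 2)]
    margin_c = spec.cluster_rx + spec.berry_radius[1] + 2
    margin_r = spec.cluster_ry + spec.berry_radius[1] + 2
    if spec.n_clusters == 0:
        return []
    slot = w / spec.n_clusters
    if slot < 2 * margin_c:
        raise ValueError(
            f"cannot place {spec.n_clusters} non-overlapping clusters in width {w}"
        )
    centers = []
    for i in range(spec.n_clusters):
        col = int((i + 0.5) * slot + rng.uniform(-0.08, 0.08) * slot)
        col = int(np.clip(col, margin_c, w - margin_c))
        row = int(np.clip(0.5 * h + rng.uniform(-0.06, 0.06) * h, margin_r, h - margin_r))
        centers.append((row, col))
    return centers


def generate_scene(spec: SceneSpec):
    """Render one scene.

    Returns (image, mask, boxes): RGB image in [0, 1], boolean
    ground-truth mask (union of berry discs), and one (top, left,
    height, width) box per true cluster.
    """
    rng = np.random.default_rng(spec.seed)
    image = _render_background(rng, spec)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    # adjoining pairs are rendered squatter so the merged region is
    # clearly landscape (width/height well above the split threshold)
    rx = spec.cluster_rx
    ry = spec.cluster_ry if not spec.adjoining else int(0.62 * spec.cluster_ry)
    boxes = []
    gain, offset, regime_h_prob = ILLUMINATION[
        spec.illumination if spec.illumination != "mixed" else "overcast"
    ]
    h_prob = spec.highlight_prob if spec.highlight_prob is not None else regime_h_prob
    for row, col in _cluster_centers(rng, spec):
        cluster_mask = np.zeros_like(mask)
        for _ in range(spec.berries_per_cluster):
            for _try in range(50):
                dr = rng.normal(0.0, ry / 2.2)
                dc = rng.normal(0.0, rx / 2.2)
                if (dr / ry) ** 2 + (dc / rx) ** 2 <= 1.0:
                    break
            radius = int(rng.integers(spec.berry_radius[0], spec.berry_radius[1] + 1))
            # berries vary independently, like the windows of a cropped
            # training set drawn from many berries and clusters
            color = np.clip(
                np.asarray(spec.grape.mean) + rng.normal(0.0, spec.grape.std, 3),
                0.0,
                1.0,
            )
            _paint_disc(image, cluster_mask, int(row + dr), int(col + dc), radius, color)
            if rng.random() < 40 * h_prob:  # one glint per few berries
                _paint_disc(
                    image,
                    np.zeros_like(mask),
                    int(row + dr - radius // 2),
                    int(col + dc - radius // 2),
                    1,
                    np.array([0.95, 0.93, 0.96]),
                )
        rows_idx, cols_idx = np.nonzero(cluster_mask)
        top, left = rows_idx.min(), cols_idx.min()
        boxes.append(
            (int(top), int(left), int(rows_idx.max() - top + 1), int(cols_idx.max() - left + 1))
        )
        mask |= cluster_mask
    # pepper noise: small grape-colored specks off the true clusters
    if spec.pepper_density > 0:
        guard = ndimage.binary_dilation(mask, iterations=10)
        covered = 0
        budget = spec.pepper_density * spec.height * spec.width
        while covered < budget:
            r = int(rng.integers(0, spec.height))
            c = int(rng.integers(0, spec.width))
            radius = int(rng.integers(1, 4))
            if guard[r, c]:
                continue
            _paint_disc(image, np.zeros_like(mask), r, c, radius, np.asarray(spec.grape.mean))
            covered += np.pi * radius**2
    image = image * gain + offset
    return np.clip(image, 0.0, 1.0), mask, boxes


def generate_suite(
    out_dir,
    seeds,
    regimes=REGIMES,
    spec: SceneSpec | None = None,
    n_grape: int = 120,
    n_background: int = 240,
) -> dict:
    """Write a scene corpus (PNG images + masks, CSV samples, manifest).

    One scene and one sample table per (regime, seed); the manifest
    records every file with its seed, regime and SHA-256, so a re-run
    with the same seeds is verifiably identical.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec or SceneSpec()
    entries = []
    for regime in regimes:
        if regime not in ILLUMINATION:
            raise ValueError(f"unknown illumination regime {regime!r}")
        for seed in seeds:
            scene_spec = replace(base, illumination=regime, seed=int(seed))
            image, mask, boxes = generate_scene(scene_spec)
            stem = f"{regime}_{int(seed):03d}"
            image_path = out_dir / f"scene_{stem}.png"
            mask_path = out_dir / f"mask_{stem}.png"
            samples_path = out_dir / f"samples_{stem}.csv"
            iio.imwrite(image_path, (image * 255).round().astype(np.uint8))
            iio.imwrite(mask_path, mask.astype(np.uint8) * 255)
            samples = generate_samples(
                scene_spec,
                n_grape=n_grape,
                n_background=n_background,
                seed=int(seed),
                illumination=regime,
            )
            samples.to_csv(samples_path, index=False)
            entries.append(
                {
                    "regime": regime,
                    "seed": int(seed),
                    "image": image_path.name,
                    "mask": mask_path.name,
                    "samples": samples_path.name,
                    "boxes": [list(b) for b in boxes],
                    "sha256": {
                        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                        for p in (image_path, mask_path, samples_path)
                    },
                }
            )
    manifest = {"spec": {"height": base.height, "width": base.width,
                         "n_clusters": base.n_clusters}, "scenes": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
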