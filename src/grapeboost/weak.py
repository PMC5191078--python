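"""Linear weak classifiers over color components and their LCE training.

Three model kinds are supported, matching the structure of the dividing
lines fitted to grape/background sample scatter:

* ``threshold_above`` — grape side is high values: L(x) = v - th
  (hue and Cb behave this way for dark purple berries);
* ``threshold_below`` — grape side is low values: L(x) = th - v
  (the b* axis: berries are bluish, foliage yellowish);
* ``line`` — a two-channel linear rule L(x) = a*v1 + b*v2 + c.

The decision rule is h(x) = +1 (grape) if L(x) >= 0 else -1.

Training is the lowest-classification-error (LCE) search: an exhaustive
scan over every threshold that can change the 0-1 loss, generalized to
weighted samples so the same trainer serves inside AdaBoost; uniform
weights reduce to the plain error rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .color import canonical_component

KINDS = ("threshold_above", "threshold_below", "line")

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class WeakModel:
    """One linear classification model: kind, component(s), parameters.

    ``params`` is ``(threshold,)`` for the threshold kinds and
    ``(a, b, c)`` for the line kind.
    """

    kind: str
    components: tuple[str, ...]
    params: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown weak-model kind {self.kind!r}")
        n_expected = 2 if self.kind == "line" else 1
        if len(self.components) != n_expected:
            raise ValueError(
                f"{self.kind} model needs {n_expected} component(s), got {self.components}"
            )
        object.__setattr__(
            self, "components", tuple(canonical_component(c) for c in self.components)
        )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    # -- evaluation ---------------------------------------------------

    def decision_values(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """Signed margin L(x, p); positive means grape-side."""
        try:
            if self.kind == "threshold_above":
                (th,) = self.params
                return np.asarray(features[self.components[0]], dtype=float) - th
            if self.kind == "threshold_below":
                (th,) = self.params
                return th - np.asarray(features[self.components[0]], dtype=float)
            a, b, c = self.params
            v1 = np.asarray(features[self.components[0]], dtype=float)
            v2 = np.asarray(features[self.components[1]], dtype=float)
            return a * v1 + b * v2 + c
        except KeyError as exc:
            raise KeyError(
                f"sample is missing component {exc.args[0]!r} required by this model"
            ) from None

    def classify(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """+1 where the margin is >= 0 (boundary counts as grape), else -1."""
        margin = self.decision_values(features)
        return np.where(np.asarray(margin) >= 0, 1, -1)

    def describe(self) -> str:
        if self.kind == "threshold_above":
            return f"{self.components[0]}(x) - {self.params[0]:.4f} = 0"
        if self.kind == "threshold_below":
            return f"{self.params[0]:.4f} - {self.components[0]}(x) = 0"
        a, b, c = self.params
        return (
            f"{a:.4f}*{self.components[0]}(x) + {b:.4f}*{self.components[1]}(x)"
            f" + {c:.4f} = 0"
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "components": list(self.components), "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeakModel":
        return cls(kind=d["kind"], components=tuple(d["components"]), params=tuple(d["params"]))


def decision_value(model: WeakModel, sample: Mapping[str, float]) -> float:
    """Scalar signed margin of one sample under a weak model."""
    return float(model.decision_values(sample))


def weak_classify(model: WeakModel, sample: Mapping[str, float]) -> int:
    """Label +-1 of one sample; a margin of exactly 0 classifies as grape."""
    return int(model.classify(sample))


# -- training ---------------------------------------------------------


def _check_training_inputs(
    samples: pd.DataFrame, weights: np.ndarray | None, require_both_classes: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(samples[LABEL_COLUMN], dtype=int)
    if not np.all(np.isin(labels, (-1, 1))):
        raise ValueError("labels must be +1 (grape) or -1 (background)")
    if require_both_classes and not ((labels == 1).any() and (labels == -1).any()):
        raise ValueError("training requires at least one sample of each class")
    if weights is None:
        weights = np.full(len(labels), 1.0 / len(labels))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != labels.shape:
            raise ValueError("weights must have one entry per sample")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must sum to a positive number")
        weights = weights / total
    return labels, weights


def _best_cut(values: np.ndarray, labels: np.ndarray, weights: np.ndarray):
    """Exact weighted 0-1-loss minimization for the rule +1 iff v >= th.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values plus sentinels beyond the extremes (the two constant
    classifiers).  Ties are broken toward the cut with the widest gap to
    the nearest sample (max margin); sentinel cuts only win ties if no
    interior cut matches, keeping the result deterministic.

    Returns (threshold, weighted_error, gap).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w_pos = np.where(labels[order] > 0, weights[order], 0.0)
    w_neg = np.where(labels[order] > 0, 0.0, weights[order])
    n = len(v)
    # cut k: samples [0, k) predicted -1, [k, n) predicted +1
    cum_pos = np.concatenate(([0.0], np.cumsum(w_pos)))
    cum_neg = np.concatenate(([0.0], np.cumsum(w_neg)))
    errors = cum_pos + (cum_neg[-1] - cum_neg)

    interior = np.flatnonzero(v[1:] > v[:-1]) + 1  # cuts between distinct values
    cuts = np.concatenate(([0], interior, [n]))
    gaps = np.empty(len(cuts))
    gaps[0] = gaps[-1] = -1.0  # sentinels lose ties against interior cuts
    gaps[1:-1] = v[interior] - v[interior - 1]

    errs = errors[cuts]
    best_err = errs.min()
    tied = np.flatnonzero(errs <= best_err + 1e-12)
    k_idx = tied[np.argmax(gaps[tied])]
    k = cuts[k_idx]
    if k == 0:
        threshold = v[0] - 1.0
    elif k == n:
        threshold = v[-1] + 1.0
    else:
        threshold = 0.5 * (v[k - 1] + v[k])
    return float(threshold), float(errs[k_idx]), float(gaps[k_idx])


def train_lce_threshold(
    samples: pd.DataFrame,
    weights: np.ndarray | None,
    component: str,
    kind: str = "threshold_above",
) -> tuple[WeakModel, float]:
    """Optimal single-component threshold model under weighted 0-1 loss.

    The search is exact: it evaluates every threshold at which the loss
    can change.  With uniform weights the returned error is the plain
    misclassification rate.
    """
    if kind not in ("threshold_above", "threshold_below"):
        raise ValueError(f"kind must be a threshold kind, got {kind!r}")
    component = canonical_component(component)
    labels, weights = _check_training_inputs(samples, weights)
    values = np.asarray(samples[component], dtype=float)
    if kind == "threshold_above":
        th, err, _ = _best_cut(values, labels, weights)
    else:
        # +1 iff v <= th  <=>  +1 iff (-v) >= (-th), boundary included
        th_neg, err, _ = _best_cut(-values, labels, weights)
        th = -th_neg
    return WeakModel(kind, (component,), (th,)), err


def train_lce_line(
    samples: pd.DataFrame,
    weights: np.ndarray | None,
    components: tuple[str, str] = ("B", "R"),
    n_directions: int = 180,
) -> tuple[WeakModel, float]:
    """Optimal two-channel line a*v1 + b*v2 + c under weighted 0-1 loss.

    Directions (a, b) are scanned on a uniform angle grid over the
    half-circle, both orientations of each; for every direction the
    intercept c is exactly optimized by the 1-D threshold search on the
    projected values.  Dense in angle, exact in c.
    """
    if len(components) != 2:
        raise ValueError("line model needs exactly two components")
    c1, c2 = (canonical_component(c) for c in components)
    labels, weights = _check_training_inputs(samples, weights)
    v1 = np.asarray(samples[c1], dtype=float)
    v2 = np.asarray(samples[c2], dtype=float)

    best = None  # (err, -gap, angle index) minimized lexicographically
    for i, phi in enumerate(np.linspace(0.0, np.pi, n_directions, endpoint=False)):
        a, b = np.cos(phi), np.sin(phi)
        for sign in (1.0, -1.0):
            proj = sign * (a * v1 + b * v2)
            th, err, gap = _best_cut(proj, labels, weights)
            key = (err, -gap, i, sign)
            if best is None or key < best[0]:
                best = (key, (sign * a, sign * b, -th), err)
    _, params, err = best
    return WeakModel("line", (c1, c2), params), err


def weighted_error(
    model: WeakModel, samples: pd.DataFrame, weights: np.ndarray | None = None
) -> float:
    """Sum of (normalized) weights of samples the model misclassifies."""
    labels, weights = _check_training_inputs(samples, weights, require_both_classes=False)
    predictions = model.classify(samples)
    return float(weights[np.asarray(predictions) != labels].sum())


def samples_from_csv(path) -> pd.DataFrame:
    """Read a sample table (component columns + ``label``) from CSV."""
    df = pd.read_csv(path)
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"sample CSV is missing the {LABEL_COLUMN!r} column")
    df = df.rename(columns={c: canonical_component(c) for c in df.columns if c != LABEL_COLUMN})
    return df


def samples_to_csv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)
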