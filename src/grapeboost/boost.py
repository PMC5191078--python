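"""AdaBoost assembly of color-component weak classifiers.

The training loop reweights the sample distribution each round, fits
every weak-model family in the pool under the current weights by the
LCE search, keeps the family with minimal weighted error eps_t, gives
it weight

    alpha_t = 0.5 * ln((1 - eps_t) / eps_t)      (natural log),

and updates sample weights by e^{-alpha_t} (correct) / e^{+alpha_t}
(misclassified), renormalized to a distribution.  The strong classifier
is H(x) = sign(sum_t alpha_t h_t(x)), with a score of exactly 0
classified as background (the sign rule is a strict >).

Two entry points are provided: the functional :func:`train` and a
model/results pair (:class:`GrapeBoost` / :class:`GrapeBoostResults`)
in the style of statistical modelling packages, which adds a summary
table, prediction helpers and JSON persistence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weak import (
    LABEL_COLUMN,
    WeakModel,
    samples_from_csv,
    train_lce_line,
    train_lce_threshold,
    weighted_error as _model_weighted_error,
)

#: Default pool of weak-model families: hue and Cb are high for dark
#: purple berries, b* is low, and a B/R line captures the remaining
#: two-channel structure.
DEFAULT_POOL: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("threshold_above", ("H",)),
    ("threshold_above", ("Cb",)),
    ("threshold_below", ("bstar",)),
    ("line", ("B", "R")),
)

HARD_ROUND_CAP = 5000


@dataclass
class BoostConfig:
    """Training configuration.

    max_rounds defaults to the pool size (each family used once);
    target_error is the strong classifier's training-error stopping
    criterion; without_replacement removes a family from the pool once
    selected, reproducing the one-round-per-family structure, while
    False allows classical with-replacement boosting.
    """

    max_rounds: int = 4
    target_error: float = 0.05
    pool: Sequence[tuple[str, tuple[str, ...]]] = DEFAULT_POOL
    without_replacement: bool = True
    n_directions: int = 180
    frozen_pool: Sequence[WeakModel] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.max_rounds <= HARD_ROUND_CAP:
            raise ValueError(f"max_rounds must be in [1, {HARD_ROUND_CAP}]")
        if not 0.0 < self.target_error < 0.5:
            raise ValueError("target_error must be in (0, 0.5)")


@dataclass(frozen=True)
class BoostRound:
    model: WeakModel
    alpha: float
    error: float
    family: tuple[str, tuple[str, ...]]
    weights_after: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass
class StrongClassifier:
    """Ordered list of (weak model, alpha) votes combined by sign."""

    rounds: list[tuple[WeakModel, float]]

    def __post_init__(self):
        if not self.rounds:
            raise ValueError("a strong classifier needs at least one round")
        if any(alpha <= 0 for _, alpha in self.rounds):
            raise ValueError("all round weights must be positive")

    @property
    def required_components(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for model, _ in self.rounds:
            for c in model.components:
                seen[c] = None
        return tuple(seen)

    def decision_values(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """Weighted vote score sum_t alpha_t h_t(x)."""
        score = None
        for model, alpha in self.rounds:
            vote = alpha * model.classify(features)
            score = vote if score is None else score + vote
        return score

    def classify(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """+1 where the score is strictly positive, else -1 (background)."""
        return np.where(np.asarray(self.decision_values(features)) > 0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {**model.to_dict(), "alpha": alpha} for model, alpha in self.rounds
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StrongClassifier":
        return cls(
            rounds=[(WeakModel.from_dict(r), float(r["alpha"])) for r in d["rounds"]]
        )


def strong_classify(clf: StrongClassifier, sample: Mapping[str, float]) -> int:
    """Label of one sample under the strong classifier (0 score -> -1)."""
    return int(clf.classify(sample))


# -- Algorithm steps --------------------------------------------------


def init_weights(n: int) -> np.ndarray:
    """Uniform initial distribution D_1 = 1/N over N samples."""
    if n < 1:
        raise ValueError("need at least one sample")
    return np.full(n, 1.0 / n)


def weighted_error(
    model: WeakModel, samples: pd.DataFrame, weights: np.ndarray
) -> float:
    """eps = sum of weights of samples the weak model misclassifies."""
    return _model_weighted_error(model, samples, weights)


def alpha_from_error(error: float, n_samples: int | None = None) -> float:
    """Weak-classifier weight alpha = 0.5 * ln((1 - eps)/eps).

    eps must lie in [0, 0.5).  A perfect weak learner (eps = 0) would
    get infinite weight; it is smoothed to eps_min = 1/(2N) when the
    sample count is supplied (and eps is floored at eps_min generally),
    otherwise eps = 0 raises.
    """
    if not 0.0 <= error < 0.5:
        raise ValueError(f"error must be in [0, 0.5), got {error}")
    if n_samples is not None:
        error = max(error, 1.0 / (2 * n_samples))
    elif error == 0.0:
        raise ValueError("error 0 needs n_samples for the smoothing floor")
    return 0.5 * math.log((1.0 - error) / error)


def update_weights(
    weights: np.ndarray,
    model: WeakModel,
    samples: pd.DataFrame,
    alpha: float,
) -> np.ndarray:
    """Reweight: misclassified samples gain, correct ones lose, sum = 1."""
    labels = np.asarray(samples[LABEL_COLUMN], dtype=int)
    predictions = np.asarray(model.classify(samples))
    factors = np.where(predictions == labels, math.exp(-alpha), math.exp(alpha))
    new = np.asarray(weights, dtype=float) * factors
    return new / new.sum()


@dataclass
class BoostTrace:
    """Per-round record of the training run."""

    rounds: list[BoostRound] = field(default_factory=list)
    training_errors: list[float] = field(default_factory=list)
    stop_reason: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(1, len(self.rounds) + 1),
                "classifier": [r.model.describe() for r in self.rounds],
                "family": [f"{r.family[0]}:{'&'.join(r.family[1])}" for r in self.rounds],
                "error": [r.error for r in self.rounds],
                "alpha": [r.alpha for r in self.rounds],
                "strong_training_error": self.training_errors,
            }
        )


def _fit_family(
    family: tuple[str, tuple[str, ...]],
    samples: pd.DataFrame,
    weights: np.ndarray,
    n_directions: int,
) -> tuple[WeakModel, float]:
    kind, components = family
    if kind == "line":
        return train_lce_line(samples, weights, components, n_directions=n_directions)
    return train_lce_threshold(samples, weights, components[0], kind)


def train(
    samples: pd.DataFrame, config: BoostConfig | None = None
) -> tuple[StrongClassifier, BoostTrace]:
    """Run the boosting loop over the configured weak-model pool.

    Each round every available family is LCE-trained under the current
    weights and the lowest weighted error wins.  Stopping: best eps of a
    round >= 0.5 (round discarded), strong training error below
    target_error, pool exhausted (without replacement), or max_rounds.
    """
    config = config or BoostConfig()
    labels = np.asarray(samples[LABEL_COLUMN], dtype=int)
    n = len(labels)
    weights = init_weights(n)

    if config.frozen_pool is not None:
        pool: list = list(range(len(config.frozen_pool)))
    else:
        pool = list(config.pool)
    trace = BoostTrace()
    rounds: list[tuple[WeakModel, float]] = []

    for _ in range(config.max_rounds):
        if not pool:
            trace.stop_reason = "pool exhausted"
            break
        fits = []
        for entry in pool:
            if config.frozen_pool is not None:
                model = config.frozen_pool[entry]
                err = weighted_error(model, samples, weights)
                family = (model.kind, model.components)
            else:
                model, err = _fit_family(entry, samples, weights, config.n_directions)
                family = entry
            fits.append((err, entry, model, family))
        best_err, best_entry, best_model, best_family = min(fits, key=lambda f: f[0])

        if best_err >= 0.5:
            if not rounds:
                raise ValueError("no weak learner better than chance on this data")
            trace.stop_reason = "no remaining learner better than chance"
            break

        alpha = alpha_from_error(best_err, n_samples=n)
        weights = update_weights(weights, best_model, samples, alpha)
        rounds.append((best_model, alpha))
        if config.without_replacement:
            pool.remove(best_entry)

        strong = StrongClassifier(rounds=list(rounds))
        train_err = float(np.mean(np.asarray(strong.classify(samples)) != labels))
        trace.rounds.append(
            BoostRound(best_model, alpha, best_err, best_family, weights.copy())
        )
        trace.training_errors.append(train_err)
        if train_err < config.target_error:
            trace.stop_reason = "target training error reached"
            break
    else:
        trace.stop_reason = "max rounds reached"
    if not trace.stop_reason:
        trace.stop_reason = "pool exhausted"
    return StrongClassifier(rounds=rounds), trace


# -- persistence ------------------------------------------------------


def save_model(
    clf: StrongClassifier, path, metadata: Mapping | None = None
) -> None:
    """Serialize a strong classifier (and optional metadata) as JSON."""
    payload = clf.to_dict()
    payload["metadata"] = dict(metadata or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> StrongClassifier:
    """Load a strong classifier saved by :func:`save_model`."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model file {path}: {exc}") from exc
    return StrongClassifier.from_dict(payload)


# -- model / results interface ----------------------------------------


class GrapeBoost:
    """Boosted color-component classifier, built from a sample table.

    Parameters
    ----------
    samples : DataFrame with one row per pixel sample: component columns
        (subset of H, Cb, bstar, R, G, B, values in [0, 1]) and a
        ``label`` column of +1 (grape) / -1 (background).
    pool : optional weak-model family pool; defaults to the four
        families of :data:`DEFAULT_POOL`.

    Examples
    --------
    >>> model = GrapeBoost(samples)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict(test_samples)
    """

    def __init__(self, samples: pd.DataFrame, pool=None):
        if LABEL_COLUMN not in samples.columns:
            raise ValueError("samples must contain a 'label' column")
        self.samples = samples.reset_index(drop=True)
        self.pool = tuple(pool) if pool is not None else DEFAULT_POOL

    @classmethod
    def from_csv(cls, path, pool=None) -> "GrapeBoost":
        return cls(samples_from_csv(path), pool=pool)

    def fit(
        self,
        max_rounds: int | None = None,
        target_error: float = 0.05,
        without_replacement: bool = True,
        n_directions: int = 180,
        frozen_pool: Sequence[WeakModel] | None = None,
        seed: int = 0,
    ) -> "GrapeBoostResults":
        config = BoostConfig(
            max_rounds=max_rounds if max_rounds is not None else len(self.pool),
            target_error=target_error,
            pool=self.pool,
            without_replacement=without_replacement,
            n_directions=n_directions,
            frozen_pool=frozen_pool,
            seed=seed,
        )
        clf, trace = train(self.samples, config)
        return GrapeBoostResults(self, clf, trace, config)


class GrapeBoostResults:
    """Fitted strong classifier with its training trace.

    Attributes
    ----------
    classifier : the :class:`StrongClassifier` (rounds of weak model +
        alpha)
    trace : :class:`BoostTrace` with per-round errors, alphas and weight
        vectors
    """

    def __init__(self, model, classifier: StrongClassifier, trace: BoostTrace, config):
        self.model = model
        self.classifier = classifier
        self.trace = trace
        self.config = config

    @property
    def alphas_(self) -> np.ndarray:
        return np.array([alpha for _, alpha in self.classifier.rounds])

    @property
    def errors_(self) -> np.ndarray:
        return np.array([r.error for r in self.trace.rounds])

    @property
    def training_error_(self) -> float:
        return self.trace.training_errors[-1]

    def decision_function(self, samples: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.classifier.decision_values(samples), dtype=float)

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.classifier.classify(samples))

    def score(self, samples: pd.DataFrame) -> float:
        """Fraction of samples classified correctly (accuracy in [0, 1])."""
        labels = np.asarray(samples[LABEL_COLUMN], dtype=int)
        return float(np.mean(self.predict(samples) == labels))

    def summary(self) -> str:
        frame = self.trace.as_frame()
        lines = ["Boosted color-component classifier", "=" * 70]
        lines.append(f"{'t':>2}  {'classifier':<42}{'eps_t':>9}{'alpha_t':>9}")
        lines.append("-" * 70)
        for _, row in frame.iterrows():
            lines.append(
                f"{row['round']:>2}  {row['classifier']:<42}"
                f"{row['error']:>9.4f}{row['alpha']:>9.4f}"
            )
        lines.append("-" * 70)
        votes = " + ".join(
            f"{alpha:.3f}*h{t + 1}(x)" for t, (_, alpha) in enumerate(self.classifier.rounds)
        )
        lines.append(f"H(x) = sign({votes})")
        lines.append(
            f"training error: {self.training_error_:.4f}"
            f"   stop: {self.trace.stop_reason}"
        )
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "seed": self.config.seed,
            "max_rounds": self.config.max_rounds,
            "target_error": self.config.target_error,
            "without_replacement": self.config.without_replacement,
            "n_directions": self.config.n_directions,
            "training_error": self.training_error_,
        }
        save_model(self.classifier, path, metadata=meta)

    @staticmethod
    def load_classifier(path) -> StrongClassifier:
        return load_model(path)

    def detect(self, image: np.ndarray, config=None):
        """Run the full detection chain on an RGB image; see
        :func:`grapeboost.detect.detect_clusters`."""
        from .detect import detect_clusters

        return detect_clusters(image, self.classifier, config)
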