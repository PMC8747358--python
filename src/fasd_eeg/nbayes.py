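"""Gaussian naive Bayes, written out from Bayes' theorem.

The classifier assumes the features are conditionally independent given
the class, so the posterior factorises as

    P(c | x_1..x_n)  ~  P(c) * prod_i P(x_i | c),

with each per-feature likelihood modelled as a normal distribution whose
mean and variance are estimated per class.  Prediction is the argmax of
the (log) posterior.  All scoring is done in the log domain: with 900
features the direct product underflows double precision.

Variances are clamped from below by a *relative* floor — 1e-9 times the
largest variance observed for that feature across classes — because the
features span many orders of magnitude (microvolts vs. squared
microvolts); an absolute smoothing constant would swamp the small ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ParameterError

_FLOOR_REL = 1e-9
_FLOOR_ABS = 1e-300  # last-resort guard when a feature is constant in every class


@dataclass(frozen=True)
class NBModel:
    classes: tuple[str, ...]
    priors: np.ndarray          # (n_classes,)
    means: np.ndarray           # (n_classes, n_features)
    variances: np.ndarray       # (n_classes, n_features), already floored
    variance_floor: np.ndarray  # (n_features,)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "classes": list(self.classes),
                    "priors": self.priors.tolist(),
                    "means": self.means.tolist(),
                    "variances": self.variances.tolist(),
                    "variance_floor": self.variance_floor.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["classes"]),
            np.asarray(d["priors"]),
            np.asarray(d["means"]),
            np.asarray(d["variances"]),
            np.asarray(d["variance_floor"]),
        )


@dataclass(frozen=True)
class Posterior:
    """Per-class log-scores and normalised probabilities for one input."""

    classes: tuple[str, ...]
    log_scores: np.ndarray
    probabilities: np.ndarray


def fit(X: np.ndarray, y) -> NBModel:
    """Estimate priors, per-class means and population variances.

    Classes are ordered by first appearance in ``y``; that order is also
    the documented tie-break in :func:`predict`.  Requires at least two
    classes and two samples per class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ParameterError("X must be (n_samples, n_features) aligned with y")
    classes = tuple(dict.fromkeys(y.tolist()))
    if len(classes) < 2:
        raise ParameterError("need at least two classes to fit")
    priors = np.empty(len(classes))
    means = np.empty((len(classes), X.shape[1]))
    variances = np.empty_like(means)
    for k, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ParameterError(f"class {c!r} has fewer than 2 samples")
        priors[k] = Xc.shape[0] / X.shape[0]
        means[k] = Xc.mean(axis=0)
        variances[k] = Xc.var(axis=0)  # population (ddof=0)
    floor = _FLOOR_REL * variances.max(axis=0)
    floor[floor == 0.0] = max(_FLOOR_REL * variances.max(), _FLOOR_ABS)
    return NBModel(classes, priors, means, np.maximum(variances, floor), floor)


def _log_scores(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Joint log P(c) + sum_i log N(x_i; mu_ci, var_ci) for rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ParameterError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ParameterError("inputs must be finite")
    diff = X[:, None, :] - model.means[None, :, :]          # (n, C, d)
    log_lik = -0.5 * (
        np.log(2.0 * np.pi * model.variances)[None] + diff**2 / model.variances[None]
    ).sum(axis=2)
    return np.log(model.priors)[None, :] + log_lik          # (n, C)


def log_posterior(model: NBModel, x: np.ndarray) -> Posterior:
    """Log-scores and normalised posterior probabilities for one vector."""
    scores = _log_scores(model, x)[0]
    shifted = scores - scores.max()
    probs = np.exp(shifted)
    probs /= probs.sum()
    return Posterior(model.classes, scores, probs)


def predict(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Argmax-posterior class for each row of ``X``.

    Exact ties resolve to the earlier class in ``model.classes``
    (``np.argmax`` keeps the first maximum).
    """
    single = np.asarray(X).ndim == 1
    idx = np.argmax(_log_scores(model, X), axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels[0] if single else labels
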