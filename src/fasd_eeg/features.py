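"""Time-domain features per (channel, band) signal and study-vector assembly.

Ten statistics are computed for every band-filtered channel signal:

==============  =============================================================
rms             sqrt(mean(x^2))
skewness        m3 / m2^1.5            (population moments, no bias correction)
kurtosis        m4 / m2^2              (raw, Gaussian -> 3, sine -> 1.5)
crest_factor    max|x| / rms           (peak-magnitude-to-RMS ratio, >= 1)
peak_to_peak    max - min
upper_env_power mean(upper_envelope^2)
lower_env_power mean(lower_envelope^2)
signal_power    mean(x^2)              (identically rms^2; kept for fidelity
                                        to the published feature list)
min, max        extreme sample values
==============  =============================================================

Envelopes are cubic splines through the local maxima (upper) and local
minima (lower), with the endpoints included as knots — unlike the analytic
signal magnitude this yields genuinely distinct upper and lower envelopes
for asymmetric signals.  With the default 18-channel montage and five
bands, one recording maps to an 18 x 5 x 10 = 900-value study vector,
ordered channel-major, then band (delta, theta, alpha, beta, gamma), then
feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .bands import BandDecomposition
from .core import DegenerateSignalError, ParameterError

FEATURE_ORDER = (
    "rms",
    "skewness",
    "kurtosis",
    "crest_factor",
    "peak_to_peak",
    "upper_env_power",
    "lower_env_power",
    "signal_power",
    "min",
    "max",
)

_MIN_LENGTH = 16


def envelopes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower signal envelopes via splines through local extrema.

    Knots are the strict local maxima (upper) / minima (lower) plus both
    endpoints; between sparse extrema the splines may cross, which is
    accepted.  Raises :class:`DegenerateSignalError` if the signal has
    fewer than two interior maxima or minima.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("envelopes expects a 1-D signal")
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    if maxima.size < 2 or minima.size < 2:
        raise DegenerateSignalError(
            f"need >=2 local maxima and minima, found {maxima.size}/{minima.size}"
        )
    idx = np.arange(x.size)

    def spline_through(knots: np.ndarray) -> np.ndarray:
        k = np.unique(np.concatenate(([0], knots, [x.size - 1])))
        return CubicSpline(k, x[k])(idx)

    return spline_through(maxima), spline_through(minima)


def feature_set(x: np.ndarray) -> np.ndarray:
    """The ten per-signal statistics, in :data:`FEATURE_ORDER`."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("feature_set expects a 1-D signal")
    if x.size < _MIN_LENGTH:
        raise ParameterError(f"signal too short ({x.size} < {_MIN_LENGTH})")
    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    if m2 == 0.0:
        raise DegenerateSignalError("constant signal: second moment is zero")
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    power = np.mean(x**2)
    rms = np.sqrt(power)
    upper, lower = envelopes(x)
    return np.array(
        [
            rms,
            m3 / m2**1.5,
            m4 / m2**2,
            np.max(np.abs(x)) / rms,
            np.max(x) - np.min(x),
            np.mean(upper**2),
            np.mean(lower**2),
            power,
            np.min(x),
            np.max(x),
        ]
    )


def feature_names(
    channel_labels: tuple[str, ...], band_names: tuple[str, ...]
) -> list[str]:
    """Column names matching the study-vector ordering contract."""
    return [
        f"{ch}|{band}|{feat}"
        for ch in channel_labels
        for band in band_names
        for feat in FEATURE_ORDER
    ]


@dataclass(frozen=True)
class FeatureVector:
    """One subject's ordered study descriptor plus its class label."""

    subject_id: str
    values: np.ndarray
    names: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if values.ndim != 1 or values.size != len(self.names):
            raise ParameterError("values and names must align")
        if not np.all(np.isfinite(values)):
            raise ParameterError("feature values must be finite")


def build_study_vector(decomposition: BandDecomposition) -> FeatureVector:
    """Concatenate the per-(channel, band) features into one study vector."""
    band_names = decomposition.band_names()
    rows = []
    for ch_idx, ch in enumerate(decomposition.channel_labels):
        for band in band_names:
            sig = decomposition.bands[band][ch_idx]
            try:
                rows.append(feature_set(sig))
            except (DegenerateSignalError, ParameterError) as exc:
                raise type(exc)(f"channel {ch}, band {band}: {exc}") from exc
    names = feature_names(decomposition.channel_labels, band_names)
    return FeatureVector(
        decomposition.source_id, np.concatenate(rows), tuple(names),
        decomposition.label,
    )


@dataclass(frozen=True)
class FeatureMatrix:
    """Stacked study vectors with aligned labels, ready for classification."""

    values: np.ndarray  # (n_subjects, n_features)
    labels: tuple[str, ...]
    names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if values.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        if values.shape[0] != len(self.labels) or len(self.labels) != len(
            self.subject_ids
        ):
            raise ParameterError("rows, labels and subject ids must align")
        if values.shape[1] != len(self.names):
            raise ParameterError("columns and feature names must align")

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector]) -> "FeatureMatrix":
        if not vectors:
            raise ParameterError("need at least one feature vector")
        names = vectors[0].names
        for v in vectors:
            if v.names != names:
                raise ParameterError(
                    f"inconsistent feature ordering for subject {v.subject_id}"
                )
        return cls(
            np.vstack([v.values for v in vectors]),
            tuple(v.label for v in vectors),
            names,
            tuple(v.subject_id for v in vectors),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "subject_id", list(self.subject_ids))
        df["label"] = list(self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            df[names].to_numpy(float),
            tuple(df["label"]),
            tuple(names),
            tuple(df["subject_id"].astype(str)),
        )
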