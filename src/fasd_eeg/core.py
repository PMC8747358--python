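"""Core containers: multichannel recordings and the bipolar montage.

A :class:`Recording` holds one subject's multichannel EEG as a
``channels x time`` array in microvolts, together with the sampling rate,
the ordered channel labels and the class label.  Everything downstream
(preprocessing, band decomposition, feature extraction) consumes and
returns these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The 18 longitudinal bipolar ("double banana") derivations, in acquisition
#: order: right temporal chain, left temporal chain, right parasagittal chain,
#: left parasagittal chain, midline.
DOUBLE_BANANA_18: tuple[str, ...] = (
    "Fp2-F8", "F8-T4", "T4-T6", "T6-O2",
    "Fp1-F7", "F7-T3", "T3-T5", "T5-O1",
    "Fp2-F4", "F4-C4", "C4-P4", "P4-O2",
    "Fp1-F3", "F3-C3", "C3-P3", "P3-O1",
    "Fz-Cz", "Cz-Pz",
)

#: Class labels used throughout: the study class is "fasd", the reference
#: class is "control"; "unknown" marks raw simulated material before a
#: class has been assigned.
LABELS = ("control", "fasd", "unknown")


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateSignalError(ValueError):
    """The signal has no usable structure (constant, too few extrema, ...)."""


@dataclass(frozen=True)
class Recording:
    """One subject's multichannel EEG.

    Parameters
    ----------
    subject_id
        Free-form identifier; file stems and manifest keys derive from it.
    samples
        ``(n_channels, n_times)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered labels, one per row of ``samples``.
    label
        ``"control"``, ``"fasd"`` or ``"unknown"``.
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    label: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if samples.ndim != 2:
            raise ParameterError("samples must be a 2-D channels x time array")
        if samples.shape[0] != len(self.channel_labels):
            raise ParameterError(
                f"{samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(samples)):
            raise ParameterError("samples contain non-finite values")
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of this recording with ``samples`` replaced."""
        return replace(self, samples=samples)

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_times) / self.fs


@dataclass(frozen=True)
class Montage:
    """Expected channel layout against which recordings are validated."""

    expected_labels: tuple[str, ...] = DOUBLE_BANANA_18

    def __post_init__(self) -> None:
        labels = tuple(self.expected_labels)
        object.__setattr__(self, "expected_labels", labels)
        if len(set(labels)) != len(labels):
            raise ParameterError("montage labels must be unique")


@dataclass(frozen=True)
class MontageReport:
    """Outcome of checking a recording against a montage."""

    ok: bool
    missing: tuple[str, ...] = ()
    extra: tuple[str, ...] = ()
    misordered: bool = False

    def message(self) -> str:
        if self.ok:
            return "montage OK"
        parts = []
        if self.missing:
            parts.append("missing: " + ", ".join(self.missing))
        if self.extra:
            parts.append("extra: " + ", ".join(self.extra))
        if self.misordered:
            parts.append("channels out of expected order")
        return "montage mismatch (" + "; ".join(parts) + ")"


def validate_montage(recording: Recording, montage: Montage | None = None) -> MontageReport:
    """Check that a recording carries exactly the expected channels, in order.

    Reports missing and extra labels and flags reordering; it never raises,
    so callers decide whether a mismatch is fatal.
    """
    montage = montage or Montage()
    expected = montage.expected_labels
    got = recording.channel_labels
    missing = tuple(l for l in expected if l not in got)
    extra = tuple(l for l in got if l not in expected)
    misordered = not missing and not extra and got != expected
    ok = not missing and not extra and not misordered
    return MontageReport(ok=ok, missing=missing, extra=extra, misordered=misordered)
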