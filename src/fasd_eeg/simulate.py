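"""Synthetic EEG cohort generator.

The clinical recordings behind this analysis (children with fetal alcohol
spectrum disorders vs. healthy controls, ~15 min of 18-channel bipolar EEG
at 250 Hz) are not publicly available, so this module generates labelled
cohorts with the same statistical structure:

* a 1/f^beta Gaussian background on every channel (pink noise, beta=1 by
  default) — the broadband floor of resting EEG;
* band-limited Gaussian oscillations in the five clinical bands, with the
  FASD class's alpha (7-12 Hz) variance scaled down by ``alpha_reduction``
  — the one spectral group difference the source data show;
* positive frontal eye-blink transients, Poisson in time and more frequent
  in the FASD class, on the Fp* channels only;
* per-subject log-normal variability of band powers (shared across
  channels) plus smaller independent per-channel jitter, so that subjects
  of the same class are not clones and classification is non-trivial.

Each operation is deterministic given its seed; a whole cohort is
bit-reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .bands import BAND_ORDER, DEFAULT_BANDS, bandpass
from .core import DOUBLE_BANANA_18, ParameterError, Recording

_BAND_EDGES = {b.name: (b.low_hz, b.high_hz) for b in DEFAULT_BANDS}

#: Default per-band oscillation variances, uV^2.  Chosen to mimic the usual
#: low-frequency dominance of the resting paediatric EEG spectrum; the class
#: effect enters only through ``alpha_reduction``.
DEFAULT_BAND_POWERS: dict[str, float] = {
    "delta": 25.0,
    "theta": 9.0,
    "alpha": 16.0,
    "beta": 4.0,
    "gamma": 1.0,
}

BLINK_DURATION_S = 0.3


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``blink_rate`` maps class label to events/min; ``band_powers`` gives the
    shared per-band oscillation variance (uV^2), with the FASD alpha variance
    additionally scaled by ``1 - alpha_reduction``.  ``subject_sigma`` is the
    standard deviation of the per-subject, per-band log-normal power
    multiplier, shared by all channels of that band (0 makes all subjects of
    a class identical in distribution); ``channel_sigma`` adds independent
    log-normal jitter per channel on top, mimicking topographic variation.
    """

    n_control: int = 50
    n_fasd: int = 50
    duration_s: float = 60.0
    fs: float = 250.0
    channel_labels: tuple[str, ...] = DOUBLE_BANANA_18
    spectral_exponent: float = 1.0
    background_rms: float = 5.0
    band_powers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS)
    )
    alpha_reduction: float = 0.3
    blink_rate: dict[str, float] = field(
        default_factory=lambda: {"control": 2.0, "fasd": 6.0}
    )
    blink_amplitude: float = 100.0
    subject_sigma: float = 0.35
    channel_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if self.n_control <= 0 or self.n_fasd <= 0:
            raise ParameterError("both class sizes must be positive")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ParameterError("duration and sampling rate must be positive")
        if not 0 <= self.alpha_reduction < 1:
            raise ParameterError("alpha_reduction must lie in [0, 1)")
        if any(v < 0 for v in self.band_powers.values()):
            raise ParameterError("band variances must be non-negative")
        unknown = set(self.band_powers) - set(BAND_ORDER)
        if unknown:
            raise ParameterError(f"unknown bands in band_powers: {sorted(unknown)}")
        top_edge = max(_BAND_EDGES[b][1] for b in self.band_powers)
        if self.fs <= 2 * top_edge:
            raise ParameterError(
                f"fs={self.fs} must exceed twice the highest band edge ({top_edge} Hz)"
            )

    def null_variant(self) -> "SimConfig":
        """Copy with no class effect: alpha_reduction 0 and equal blink rates.

        Both classes are then exchangeable in distribution, so any downstream
        classifier should sit at chance.
        """
        cfg = SimConfig(**self.to_dict())
        cfg.alpha_reduction = 0.0
        rate = cfg.blink_rate["control"]
        cfg.blink_rate = {"control": rate, "fasd": rate}
        return cfg

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_background(
    duration_s: float,
    fs: float,
    n_channels: int,
    spectral_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Gaussian noise with power spectral density ~ 1/f^beta, unit variance.

    Shaping is done in the frequency domain: white Gaussian noise is
    transformed, each FFT bin is weighted by ``|f|^(-beta/2)`` (the DC bin is
    zeroed), and the weights are normalised so the expected per-channel
    variance is exactly 1.  Channels are independent realisations.
    """
    if duration_s <= 0 or fs <= 0:
        raise ParameterError("duration and sampling rate must be positive")
    if n_channels <= 0:
        raise ParameterError("need at least one channel")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    with np.errstate(divide="ignore"):
        w = np.abs(freqs) ** (-spectral_exponent / 2.0)
    w[0] = 0.0
    # E[var] = (1/n) * sum(w^2) for unit-variance white input; normalise to 1
    w *= np.sqrt(n / np.sum(w**2))
    white = rng.standard_normal((n_channels, n))
    shaped = np.real(np.fft.ifft(np.fft.fft(white, axis=1) * w[None, :], axis=1))
    labels = tuple(f"ch{i:02d}" for i in range(n_channels))
    return Recording("background", shaped, fs, labels, label="unknown")


def add_band_oscillation(
    recording: Recording,
    low_hz: float,
    high_hz: float,
    variance: float,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Add independent band-limited Gaussian noise of the given variance.

    White noise is passed through the same zero-phase Butterworth band-pass
    the analysis uses, then rescaled channel-by-channel so the added
    component has exactly the requested sample variance.
    """
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < 0):
        raise ParameterError("variance must be non-negative")
    if np.all(variance == 0):
        return recording
    rng = _as_rng(seed)
    n_ch, n = recording.samples.shape
    white = rng.standard_normal((n_ch, n))
    banded = np.vstack([bandpass(row, low_hz, high_hz, recording.fs) for row in white])
    std = banded.std(axis=1, keepdims=True)
    banded = banded / std * np.sqrt(np.broadcast_to(variance, (n_ch,)))[:, None]
    return recording.with_samples(recording.samples + banded)


def blink_waveform(fs: float, amplitude: float) -> np.ndarray:
    """One positive-going squared-sine blink transient, ~300 ms long."""
    t = np.arange(int(round(BLINK_DURATION_S * fs))) / fs
    return amplitude * np.sin(np.pi * t / BLINK_DURATION_S) ** 2


def inject_blinks(
    recording: Recording,
    rate_per_min: float,
    amplitude: float,
    seed: int | np.random.Generator = 0,
) -> tuple[Recording, np.ndarray]:
    """Add Poisson-timed frontal blink artifacts; returns the event times.

    Only channels whose label contains ``"Fp"`` receive the transient (the
    frontopolar derivations, where ocular artifacts dominate in real EEG).
    Returns the modified recording and the array of event onset times (s).
    """
    if rate_per_min < 0:
        raise ParameterError("blink rate must be non-negative")
    if rate_per_min == 0:
        return recording, np.empty(0)
    rng = _as_rng(seed)
    duration = recording.duration_s
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    bump = blink_waveform(recording.fs, amplitude)
    max_onset = max(duration - BLINK_DURATION_S, 0.0)
    onsets = np.sort(rng.uniform(0.0, max_onset, size=n_events))
    frontal = [i for i, lab in enumerate(recording.channel_labels) if "Fp" in lab]
    samples = recording.samples.copy()
    for t0 in onsets:
        i0 = int(round(t0 * recording.fs))
        i1 = min(i0 + bump.size, samples.shape[1])
        for ch in frontal:
            samples[ch, i0:i1] += bump[: i1 - i0]
    return recording.with_samples(samples), onsets


def _simulate_subject(
    config: SimConfig,
    subject_id: str,
    label: str,
    ss: np.random.SeedSequence,
) -> Recording:
    rng = np.random.default_rng(ss)
    n_ch = len(config.channel_labels)
    rec = generate_background(
        config.duration_s, config.fs, n_ch, config.spectral_exponent, rng
    )
    rec = rec.with_samples(rec.samples * config.background_rms)

    for band in BAND_ORDER:
        if band not in config.band_powers:
            continue
        var = config.band_powers[band]
        if label == "fasd" and band == "alpha":
            var *= 1.0 - config.alpha_reduction
        if config.subject_sigma > 0:
            # log-normal multiplier with unit mean: subjects differ in band power
            var *= rng.lognormal(-config.subject_sigma**2 / 2.0, config.subject_sigma)
        var_ch = np.full(n_ch, var)
        if config.channel_sigma > 0:
            var_ch *= rng.lognormal(
                -config.channel_sigma**2 / 2.0, config.channel_sigma, size=n_ch
            )
        low, high = _BAND_EDGES[band]
        rec = add_band_oscillation(rec, low, high, var_ch, rng)

    rec, _ = inject_blinks(
        rec, config.blink_rate.get(label, 0.0), config.blink_amplitude, rng
    )
    return Recording(subject_id, rec.samples, config.fs, config.channel_labels, label)


def generate_cohort(config: SimConfig) -> list[Recording]:
    """Generate the full labelled cohort described by ``config``.

    Controls come first, then the FASD class; each subject has an
    independent random stream spawned from ``config.seed``, so the cohort is
    bit-reproducible and individual subjects do not share noise.
    """
    n_total = config.n_control + config.n_fasd
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    cohort: list[Recording] = []
    for i in range(config.n_control):
        cohort.append(
            _simulate_subject(config, f"control{i + 1:03d}", "control", streams[i])
        )
    for j in range(config.n_fasd):
        cohort.append(
            _simulate_subject(
                config, f"fasd{j + 1:03d}", "fasd", streams[config.n_control + j]
            )
        )
    return cohort
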