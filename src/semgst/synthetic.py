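"""Synthetic multi-channel surface-EMG generator with known gesture structure.

Emulates the acquisition layout of hand-gesture sEMG databases: a continuous
recording in which labeled gesture blocks alternate with rest blocks, each of
the K gesture classes executed for a fixed number of repetitions, on a grid of
electrodes whose per-class activation pattern is controlled by an explicit
amplitude map.  The signal model is

    s(t, c) = g_subj * A[k(t), c] * env(t) * carrier(t, c) + noise(t, c)

where ``carrier`` is white Gaussian noise band-passed to the sEMG band,
``env`` is a raised-cosine on/off envelope per gesture block, ``A`` is the
class-by-channel activation map, ``g_subj`` a per-subject gain and ``noise``
additive Gaussian measurement noise.  Not modelled: motor-unit physiology,
electrode-skin impedance, fatigue drift.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["SynthConfig", "Recording", "generate_recording", "generate_cohort"]


@dataclass
class Recording:
    """A continuous multi-channel sEMG recording with per-sample annotations.

    ``samples`` is time x channels in mV; ``labels`` holds the gesture class
    per sample (0 = rest); ``repetition`` the 1-based trial index per sample,
    0 during rest.
    """

    samples: np.ndarray
    fs: float
    labels: np.ndarray
    repetition: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetition = np.asarray(self.repetition, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channels)")
        n = self.samples.shape[0]
        if self.labels.shape != (n,) or self.repetition.shape != (n,):
            raise ValueError("labels and repetition must match samples in time length")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _default_activation_map(n_classes: int, n_channels: int) -> np.ndarray:
    """One dominant channel group per class, weak co-activation elsewhere."""
    amap = np.full((n_classes, n_channels), 0.1)
    for k in range(n_classes):
        amap[k, np.arange(n_channels) % n_classes == k] = 1.0
    return amap


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror a 100 Hz, 10-electrode acquisition: each gesture is held
    for 5 s with a 3 s rest pause after every movement, and every class is
    repeated 10 times, matching the stimulus protocol of the low-density
    benchmark databases this package targets.
    """

    n_channels: int = 10
    fs: float = 100.0
    n_classes: int = 4  # gesture classes, excluding rest (rest = class 0)
    n_repetitions: int = 10
    gesture_dur: float = 5000.0  # ms
    rest_dur: float = 3000.0  # ms
    activation_map: np.ndarray | None = None
    noise_sd: float = 0.05  # mV
    subject_gain_sd: float = 0.1
    seed: int = 0
    carrier_band: tuple[float, float | None] = (20.0, None)  # Hz; None -> min(450, 0.45 fs)
    envelope_ramp_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.gesture_dur <= 0 or self.rest_dur < 0:
            raise ValueError("durations must be positive")
        if self.activation_map is None:
            self.activation_map = _default_activation_map(self.n_classes, self.n_channels)
        self.activation_map = np.asarray(self.activation_map, dtype=np.float64)
        if self.activation_map.shape != (self.n_classes, self.n_channels):
            raise ValueError(
                f"activation_map must have shape ({self.n_classes}, {self.n_channels}), "
                f"got {self.activation_map.shape}"
            )
        if np.any(self.activation_map < 0) or np.any(self.activation_map > 1):
            raise ValueError("activation_map entries must lie in [0, 1]")

    @property
    def gesture_samples(self) -> int:
        return int(round(self.gesture_dur * self.fs / 1000.0))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_dur * self.fs / 1000.0))


def _subject_index(subject_id: str) -> int:
    return zlib.crc32(str(subject_id).encode("utf-8"))


def _band_limited_noise(rng: np.random.Generator, n: int, n_channels: int,
                        fs: float, band: tuple[float, float | None]) -> np.ndarray:
    lo, hi = band
    if hi is None:
        hi = min(450.0, 0.45 * fs)
    white = rng.standard_normal((n, n_channels))
    nyq = fs / 2.0
    lo = max(lo, 1e-3)
    if hi >= nyq:
        hi = 0.49 * fs
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    # renormalize so band-limiting does not silently change signal power
    sd = carrier.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return carrier / sd


def _raised_cosine_envelope(n: int, ramp_frac: float) -> np.ndarray:
    ramp = max(1, int(round(ramp_frac * n)))
    env = np.ones(n)
    t = np.linspace(0.0, np.pi, ramp)
    env[:ramp] = 0.5 * (1 - np.cos(t))
    env[-ramp:] = 0.5 * (1 + np.cos(t))
    return env


def _block_schedule(cfg: SynthConfig) -> list[tuple[int, int]]:
    """(class_id, repetition) blocks in stimulus order, rest interleaved.

    Layout: R G(1,r1) R G(2,r1) ... R G(K,rR) R — an initial rest, then each
    gesture followed by a rest pause, cycling through all classes once per
    repetition.
    """
    blocks = []
    for rep in range(1, cfg.n_repetitions + 1):
        for k in range(1, cfg.n_classes + 1):
            blocks.append((k, rep))
    return blocks


def generate_recording(config: SynthConfig, subject_id: str) -> Recording:
    """Generate one subject's recording; deterministic given (seed, subject_id).

    Two independent seeded streams are used: one for the noise carrier and
    measurement noise, one for the subject gain, so that the same subject is
    reproducible inside any cohort.
    """
    sidx = _subject_index(subject_id)
    rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, sidx, 1]))
    rng_gain = np.random.default_rng(np.random.SeedSequence([config.seed, sidx, 2]))

    gain = float(np.exp(config.subject_gain_sd * rng_gain.standard_normal()))

    g, r = config.gesture_samples, config.rest_samples
    blocks = _block_schedule(config)
    total = r + len(blocks) * (g + r)

    labels = np.zeros(total, dtype=np.int64)
    repetition = np.zeros(total, dtype=np.int64)
    activation = np.zeros((total, config.n_channels))
    env_one = _raised_cosine_envelope(g, config.envelope_ramp_frac)

    pos = r
    for class_id, rep in blocks:
        labels[pos:pos + g] = class_id
        repetition[pos:pos + g] = rep
        activation[pos:pos + g] = env_one[:, None] * config.activation_map[class_id - 1][None, :]
        pos += g + r

    if np.any(config.activation_map > 0):
        carrier = _band_limited_noise(rng_noise, total, config.n_channels,
                                      config.fs, config.carrier_band)
    else:
        carrier = np.zeros((total, config.n_channels))
    noise = config.noise_sd * rng_noise.standard_normal((total, config.n_channels)) \
        if config.noise_sd > 0 else 0.0
    samples = gain * activation * carrier + noise

    return Recording(samples=samples, fs=config.fs, labels=labels,
                     repetition=repetition, subject_id=str(subject_id))


def generate_cohort(config: SynthConfig, n_subjects: int) -> list[Recording]:
    """One Recording per subject, ids "S01".."Snn"."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [generate_recording(config, f"S{i + 1:02d}") for i in range(n_subjects)]
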