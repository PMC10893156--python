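"""Per-window, per-channel feature extraction: raw RMS, DFT, and CWT paths.

Each window of each channel is collapsed to a single scalar so that a window
of a C-channel recording becomes a length-C feature vector, later arranged on
the electrode grid as a "matrix signal".  Three pathways are provided:

raw
    root-mean-square amplitude of the window;
fft
    magnitude spectrum |F(k)| = |sum_n x[n] e^{-j 2 pi k n / N}|, aggregated
    as the mean magnitude over the positive-frequency bins 1..N/2 (the DC bin
    is excluded so baseline offset does not dominate);
cwt
    continuous wavelet transform against a Morlet or Mexican-hat mother
    wavelet, c(a, b) = a^{-1/2} * sum_t s(t) psi((t - b) / a), aggregated as
    the mean absolute coefficient over all scales and shifts.  Default scales
    are the integers 1..10 with the Mexican hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import WindowSet

__all__ = [
    "FeatureVector", "SpectrumFrame", "ScalogramFrame",
    "dft", "mother_wavelet", "cwt", "aggregate", "featurize_windowset",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(range(1, 11))


@dataclass
class FeatureVector:
    """One scalar per channel for one window, with its label carried along."""

    values: np.ndarray
    label: int
    subject_id: str
    repetition: int = 0


@dataclass
class SpectrumFrame:
    """DFT magnitudes of one window: (N, channels), all bins 0..N-1."""

    magnitudes: np.ndarray
    N: int
    fs: float


@dataclass
class ScalogramFrame:
    """CWT coefficients of one window: (scales, N, channels)."""

    coefficients: np.ndarray
    scales: np.ndarray
    wavelet: str


def dft(window: np.ndarray, fs: float = 1.0) -> SpectrumFrame:
    """Magnitude spectrum of each channel of a (N, channels) window."""
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if window.shape[0] < 2:
        raise ValueError("window must have at least 2 samples")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    mags = np.abs(np.fft.fft(window, axis=0))
    return SpectrumFrame(magnitudes=mags, N=window.shape[0], fs=fs)


def mother_wavelet(t, kind: str) -> np.ndarray:
    """Evaluate the Morlet or Mexican-hat mother wavelet pointwise.

    Morlet: psi(t) = exp(-t^2/2) cos(5 t)
    Mexh:   psi(t) = 2 / (sqrt(3) * pi^(1/4)) * exp(-t^2/2) * (1 - t^2)
    """
    t = np.asarray(t, dtype=np.float64)
    if kind == "morl":
        return np.exp(-t ** 2 / 2.0) * np.cos(5.0 * t)
    if kind == "mexh":
        return (2.0 / (np.sqrt(3.0) * np.pi ** 0.25)) * np.exp(-t ** 2 / 2.0) * (1.0 - t ** 2)
    raise ValueError(f"unknown mother wavelet {kind!r}")


def cwt(window: np.ndarray, kind: str = "mexh",
        scales=DEFAULT_SCALES, prefactor: str = "sqrt") -> ScalogramFrame:
    """Discrete CWT of each channel of a (N, channels) window.

    For scale a and shift b (both in sample units):

        c(a, b) = w(a) * sum_k s(b + k) * psi(k / a),   |k| <= 8 a

    where w(a) = 1/sqrt(a) for the standard energy normalization
    (``prefactor="sqrt"``) or w(a) = a for the literal variant
    (``prefactor="literal"``).  The wavelet support is truncated at
    |t/a| <= 8 where both mother wavelets are below 1e-13; samples outside
    the window are treated as zero.
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    n = window.shape[0]
    if n < 2:
        raise ValueError("window must have at least 2 samples")
    scales = np.asarray(scales, dtype=np.float64)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if prefactor not in ("sqrt", "literal"):
        raise ValueError(f"unknown prefactor {prefactor!r}")

    coeffs = np.empty((scales.size, n, window.shape[1]))
    for i, a in enumerate(scales):
        half = int(np.ceil(8.0 * a))
        k = np.arange(-half, half + 1)
        psi = mother_wavelet(k / a, kind)
        w = (1.0 / np.sqrt(a)) if prefactor == "sqrt" else a
        # correlation with zero padding: c[b] = sum_k s[b+k] psi[k]
        coeffs[i] = w * ndimage.correlate1d(window, psi, axis=0,
                                            mode="constant", cval=0.0)
    return ScalogramFrame(coefficients=coeffs, scales=scales, wavelet=kind)


def aggregate(frame) -> np.ndarray:
    """Collapse a window representation to one scalar per channel."""
    if isinstance(frame, SpectrumFrame):
        if frame.N < 2:
            raise ValueError("empty spectrum")
        return frame.magnitudes[1:frame.N // 2 + 1].mean(axis=0)
    if isinstance(frame, ScalogramFrame):
        if frame.coefficients.size == 0:
            raise ValueError("empty scalogram")
        return np.abs(frame.coefficients).mean(axis=(0, 1))
    window = np.atleast_2d(np.asarray(frame, dtype=np.float64))
    if window.size == 0:
        raise ValueError("empty window")
    return np.sqrt(np.mean(window ** 2, axis=0))


def featurize_windowset(ws: WindowSet, method: str = "cwt",
                        **params) -> list[FeatureVector]:
    """One FeatureVector per window; labels and trial indices pass through."""
    out = []
    for i in range(len(ws)):
        w = ws.windows[i]
        if method == "raw":
            values = aggregate(w)
        elif method == "fft":
            values = aggregate(dft(w, fs=ws.fs))
        elif method == "cwt":
            values = aggregate(cwt(w, **params))
        else:
            raise ValueError(f"unknown feature method {method!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite feature values")
        out.append(FeatureVector(values=values, label=int(ws.labels[i]),
                                 subject_id=ws.subject_id,
                                 repetition=int(ws.repetitions[i])))
    return out
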