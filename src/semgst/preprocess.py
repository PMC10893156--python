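"""Filtering, rectification, normalization, rest downsampling and windowing.

The preprocessing chain for gesture recognition is: drop redundant rest
periods (the rest class otherwise dominates training roughly 2:1), zero-phase
Butterworth low-pass filtering, optional rectification / amplitude
normalization, then overlapping-window segmentation.  The canonical window is
320 ms with 100 ms overlap, which at 100 Hz gives 32-sample windows with 10
overlapped samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic import Recording

__all__ = [
    "WindowSet",
    "lowpass_filter",
    "rectify",
    "normalize",
    "downsample_rest",
    "segment_windows",
    "default_cutoff",
]


@dataclass
class WindowSet:
    """Fixed-length overlapping segments cut from a Recording.

    ``windows`` is (n_windows, window_samples, channels); each window carries
    one majority-vote class label and the trial (repetition) index of that
    class within the window.
    """

    windows: np.ndarray
    labels: np.ndarray
    repetitions: np.ndarray
    subject_id: str
    window_samples: int
    step_samples: int
    fs: float

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]


def default_cutoff(fs: float) -> float:
    """Low-pass cutoff covering the useful sEMG band at this sampling rate."""
    return min(450.0, 0.45 * fs)


def lowpass_filter(recording: Recording, cutoff: float | None = None,
                   order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth low-pass, per channel."""
    if cutoff is None:
        cutoff = default_cutoff(recording.fs)
    nyq = recording.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    sos = sps.butter(order, cutoff / nyq, btype="lowpass", output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=0)
    return replace(recording, samples=filtered)


def rectify(recording: Recording, mode: str = "full") -> Recording:
    """Full-wave (|x|) or half-wave (max(x, 0)) rectification."""
    if mode == "full":
        out = np.abs(recording.samples)
    elif mode == "half":
        out = np.maximum(recording.samples, 0.0)
    else:
        raise ValueError(f"unknown rectification mode {mode!r}")
    return replace(recording, samples=out)


def normalize(recording: Recording, reference="auto") -> Recording:
    """Divide each channel by a reference amplitude.

    ``reference`` is a per-channel value in mV, a scalar, or "auto", which
    uses the per-channel maximum of the rectified signal over the whole
    recording (so the post-normalization rectified maximum is 1 per channel).
    """
    if isinstance(reference, str):
        if reference != "auto":
            raise ValueError(f"unknown reference {reference!r}")
        ref = np.abs(recording.samples).max(axis=0)
        ref[ref == 0] = 1.0
    else:
        ref = np.broadcast_to(np.asarray(reference, dtype=np.float64),
                              (recording.n_channels,)).copy()
        if np.any(ref <= 0):
            raise ValueError("reference must be positive per channel")
    return replace(recording, samples=recording.samples / ref[None, :])


def _label_blocks(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode labels into (class_id, start, stop) blocks."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def downsample_rest(recording: Recording, keep_every: int | None = None
                    ) -> tuple[Recording, np.ndarray]:
    """Remove redundant rest blocks so rest does not dominate training.

    Keeps every gesture-labeled sample; among rest blocks, by default keeps
    only the single rest block immediately following the first gesture block,
    discarding all other rests.  ``keep_every=k`` instead keeps every k-th
    post-gesture rest block (sensitivity-check option).  Returns the
    time-contiguous downsampled Recording and an index map back into the
    original sample positions.
    """
    blocks = _label_blocks(recording.labels)
    if not any(c > 0 for c, _, _ in blocks):
        raise ValueError("recording contains no gesture blocks")
    if not any(c == 0 for c, _, _ in blocks):
        idx = np.arange(recording.n_samples)
        return recording, idx

    keep: list[np.ndarray] = []
    post_gesture_rest_seen = 0
    gesture_seen = False
    for class_id, a, b in blocks:
        if class_id > 0:
            gesture_seen = True
            keep.append(np.arange(a, b))
        else:
            if not gesture_seen:
                continue  # leading rest dropped
            post_gesture_rest_seen += 1
            if keep_every is None:
                if post_gesture_rest_seen == 1:
                    keep.append(np.arange(a, b))
            elif (post_gesture_rest_seen - 1) % keep_every == 0:
                keep.append(np.arange(a, b))
    idx = np.concatenate(keep)
    out = replace(recording,
                  samples=recording.samples[idx],
                  labels=recording.labels[idx],
                  repetition=recording.repetition[idx])
    return out, idx


def _ms_to_samples(ms: float, fs: float) -> int:
    """Round-half-up so 320 ms at 100 Hz gives exactly 32 samples."""
    return int(np.floor(ms * fs / 1000.0 + 0.5))


def _majority(values: np.ndarray) -> int:
    counts = np.bincount(values)
    return int(counts.argmax())  # ties resolve to the smaller class id


def segment_windows(recording: Recording, window_ms: float = 320.0,
                    overlap_ms: float = 100.0) -> WindowSet:
    """Cut the recording into overlapping fixed-length windows.

    Windows start at multiples of ``step = window - overlap`` samples; an
    incomplete trailing window is dropped.  Each window is labeled by the
    majority vote of its per-sample labels (ties go to the smaller class id)
    and carries the majority repetition index among the samples of the
    winning class.
    """
    if not window_ms > overlap_ms >= 0:
        raise ValueError("require window_ms > overlap_ms >= 0")
    w = _ms_to_samples(window_ms, recording.fs)
    o = _ms_to_samples(overlap_ms, recording.fs)
    step = w - o
    if step < 1:
        raise ValueError("window and overlap sizes leave a step < 1 sample")
    n = recording.n_samples
    if w > n:
        raise ValueError(f"window of {w} samples exceeds recording length {n}")

    starts = np.arange(0, n - w + 1, step)
    view = np.lib.stride_tricks.sliding_window_view(
        recording.samples, w, axis=0)[starts]  # (n_win, channels, w)
    windows = np.ascontiguousarray(np.swapaxes(view, 1, 2))

    labels = np.empty(len(starts), dtype=np.int64)
    reps = np.empty(len(starts), dtype=np.int64)
    for i, s in enumerate(starts):
        lab = recording.labels[s:s + w]
        win_label = _majority(lab)
        labels[i] = win_label
        rep = recording.repetition[s:s + w][lab == win_label]
        reps[i] = _majority(rep) if rep.size else 0

    return WindowSet(windows=windows, labels=labels, repetitions=reps,
                     subject_id=recording.subject_id, window_samples=w,
                     step_samples=step, fs=recording.fs)
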