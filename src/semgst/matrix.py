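"""Electrode-grid "matrix signals": gridding, resizing, normalization, augmentation.

A length-C feature vector is arranged on the physical electrode grid (2 x 5
for a 10-electrode forearm band, 8 x 16 for a high-density array), upsampled
to the classifier's input resolution (72 x 72 by default) with bilinear
interpolation, normalized, and optionally augmented with random horizontal
flips and small rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .features import FeatureVector

__all__ = [
    "MatrixSignal", "to_grid", "from_grid", "resize", "normalize_matrix",
    "augment", "build_matrix_signals", "electrode_patch_indices",
]

DEFAULT_SIZE = 72


@dataclass
class MatrixSignal:
    """An image-like H x W x C grid (C = 1) with its gesture label."""

    pixels: np.ndarray  # (H, W, C)
    label: int
    subject_id: str
    source_grid: tuple[int, int]
    repetition: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")


def to_grid(fv: FeatureVector, grid_shape: tuple[int, int],
            mapping: np.ndarray | None = None) -> np.ndarray:
    """Place channel values on the electrode grid, row-major by default.

    ``mapping`` is a permutation of channel indices: grid cell (r, c) receives
    ``fv.values[mapping[r * cols + c]]``.
    """
    rows, cols = grid_shape
    values = np.asarray(fv.values, dtype=np.float64)
    if rows * cols != values.size:
        raise ValueError(f"grid {rows}x{cols} does not hold {values.size} channels")
    if mapping is None:
        mapping = np.arange(values.size)
    mapping = np.asarray(mapping)
    if sorted(mapping.tolist()) != list(range(values.size)):
        raise ValueError("mapping must be a permutation of channel indices")
    return values[mapping].reshape(rows, cols)


def from_grid(matrix: np.ndarray, mapping: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`to_grid`: recover the channel-ordered vector."""
    flat = np.asarray(matrix).reshape(-1)
    if mapping is None:
        return flat.copy()
    out = np.empty_like(flat)
    out[np.asarray(mapping)] = flat
    return out


def resize(matrix: np.ndarray, size: int = DEFAULT_SIZE) -> np.ndarray:
    """Bilinear upsampling of a grid to size x size; constants stay constant."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if size < max(matrix.shape[:2]):
        raise ValueError(f"target size {size} smaller than source grid {matrix.shape[:2]}")
    return _sk_resize(matrix, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def normalize_matrix(matrix: np.ndarray, mode: str = "minmax",
                     stats: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max to [0, 1] or z-score; a constant matrix maps to all zeros.

    ``stats`` supplies dataset-level (lo, hi) or (mean, sd) so the training
    split's statistics can be reused on the test split.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if mode == "minmax":
        lo, hi = stats if stats is not None else (matrix.min(), matrix.max())
        if hi - lo <= 0:
            return np.zeros_like(matrix)
        return (matrix - lo) / (hi - lo)
    if mode == "zscore":
        mu, sd = stats if stats is not None else (matrix.mean(), matrix.std())
        if sd <= 0:
            return np.zeros_like(matrix)
        return (matrix - mu) / sd
    raise ValueError(f"unknown normalization mode {mode!r}")


def augment(ms: MatrixSignal, rng: np.random.Generator,
            flip_p: float = 0.5, max_rot: float = 15.0) -> MatrixSignal:
    """Random horizontal flip and rotation; the label is never altered.

    The flip occurs with probability ``flip_p``; the rotation angle is drawn
    uniformly from [-max_rot, +max_rot] degrees and applied about the image
    center with bilinear resampling and edge padding.  Deterministic given
    the generator state.
    """
    if not 0.0 <= flip_p <= 1.0:
        raise ValueError("flip_p must lie in [0, 1]")
    pixels = ms.pixels
    if rng.random() < flip_p:
        pixels = pixels[:, ::-1, :]
    angle = rng.uniform(-max_rot, max_rot) if max_rot > 0 else 0.0
    if angle != 0.0:
        pixels = ndimage.rotate(pixels, angle, axes=(1, 0), reshape=False,
                                order=1, mode="nearest")
    return replace(ms, pixels=np.ascontiguousarray(pixels))


def electrode_patch_indices(grid_shape: tuple[int, int], image_size: int,
                            patch_size: int, electrodes) -> np.ndarray:
    """Indices of the patches whose centers fall on the given electrodes.

    Electrodes are identified by their flat row-major index on the source
    grid; patch indices are row-major over the patch grid.  Used to relate
    attention over patches back to physical electrodes.
    """
    rows, cols = grid_shape
    per_side = image_size // patch_size
    wanted = set(int(e) for e in electrodes)
    out = []
    for i in range(per_side):
        for j in range(per_side):
            cy = (i * patch_size + patch_size / 2.0) / image_size  # in [0, 1)
            cx = (j * patch_size + patch_size / 2.0) / image_size
            e = min(int(cy * rows), rows - 1) * cols + min(int(cx * cols), cols - 1)
            if e in wanted:
                out.append(i * per_side + j)
    return np.array(out, dtype=np.int64)


def build_matrix_signals(fvs: list[FeatureVector], grid_shape: tuple[int, int],
                         size: int = DEFAULT_SIZE, norm: str = "minmax",
                         mapping: np.ndarray | None = None,
                         stats: tuple[float, float] | None = None
                         ) -> list[MatrixSignal]:
    """Grid, resize and normalize a batch of feature vectors."""
    out = []
    for fv in fvs:
        m = normalize_matrix(resize(to_grid(fv, grid_shape, mapping), size),
                             mode=norm, stats=stats)
        out.append(MatrixSignal(pixels=m[:, :, None], label=fv.label,
                                subject_id=fv.subject_id,
                                source_grid=tuple(grid_shape),
                                repetition=fv.repetition))
    return out
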