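"""Difference image and the 4-D (x, y, z, d) feature space the SOM quantizes.

Each in-mask voxel contributes one vector whose first three channels are its
grid coordinates and whose fourth channel is the between-class difference
intensity at that voxel.  Coordinates and intensity live in incommensurate
units, so every channel is affinely rescaled: coordinates to [0, 1] by
dividing by (grid_dim - 1) per axis, and the difference channel min-max
scaled to [0, 1] over the mask and then multiplied by ``d_weight``, the knob
that trades spatial compactness of the ROIs against intensity homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureSpace", "difference_image", "build_feature_space", "tissue_mask"]


@dataclass
class FeatureSpace:
    """Scaled 4-D vectors with the voxel back-mapping and scaling record.

    ``vectors[p] = (raw[p] - offset) * gain`` channel-wise, with raw spatial
    channels equal to the integer voxel coordinates in ``voxel_index[p]``.
    A zero gain marks a degenerate channel (constant difference image).
    """

    vectors: np.ndarray          # (P, 4)
    voxel_index: np.ndarray      # (P, 3) 0-based integer grid coordinates
    offset: np.ndarray           # (4,)
    gain: np.ndarray             # (4,)
    mask: np.ndarray             # boolean volume
    d_weight: float
    grid_shape: tuple[int, int, int]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    def unscale_spatial(self) -> np.ndarray:
        """Invert the spatial scaling; rounds to the voxel grid exactly."""
        raw = self.vectors[:, :3] / self.gain[:3] + self.offset[:3]
        return np.rint(raw).astype(np.int64)

    def to_table(self):
        """Columnar view (x, y, z, d, voxel linear index) as a DataFrame.

        Coordinates and ``d`` are the scaled channel values; the linear
        index is row-major over the grid.
        """
        import pandas as pd

        lin = np.ravel_multi_index(tuple(self.voxel_index.T), self.grid_shape)
        return pd.DataFrame(
            {
                "x": self.vectors[:, 0],
                "y": self.vectors[:, 1],
                "z": self.vectors[:, 2],
                "d": self.vectors[:, 3],
                "voxel_index": lin,
            }
        )

    def scaling_signature(self) -> tuple:
        """Hashable record used to detect model/feature-space mismatches."""
        return (
            tuple(self.grid_shape),
            tuple(np.round(self.offset, 12)),
            tuple(np.round(self.gain, 12)),
            float(self.d_weight),
        )


def difference_image(mean_class1: np.ndarray, mean_class2: np.ndarray) -> np.ndarray:
    """Voxel-wise difference of the two class-mean volumes.

    The first argument is the reference (control) class, so positive values
    mark voxels where the second (patient) class has lost intensity.
    """
    m1 = np.asarray(mean_class1, dtype=np.float64)
    m2 = np.asarray(mean_class2, dtype=np.float64)
    if m1.shape != m2.shape:
        raise ValueError(f"grid mismatch: {m1.shape} vs {m2.shape}")
    return m1 - m2


def tissue_mask(stacks, p_min: float = 0.05) -> np.ndarray:
    """Voxels whose pooled mean tissue probability reaches ``p_min``.

    ``stacks`` is one VolumeStack or an iterable of them (pooled over all
    subjects of all classes).  Restricting the feature space to this mask
    emulates skull-stripped input.
    """
    from somroi.voxelstats import VolumeStack

    if isinstance(stacks, VolumeStack):
        stacks = [stacks]
    stacks = list(stacks)
    if not stacks:
        raise ValueError("need at least one stack")
    shape = stacks[0].grid_shape
    total = np.zeros(shape)
    n = 0
    for s in stacks:
        if s.grid_shape != shape:
            raise ValueError(f"grid mismatch: {s.grid_shape} vs {shape}")
        total += s.volumes.sum(axis=0)
        n += s.n_subjects
    return (total / n) >= p_min


def build_feature_space(
    D: np.ndarray,
    mask: np.ndarray,
    d_weight: float = 1.0,
    absolute: bool = False,
) -> FeatureSpace:
    """Assemble the scaled (x, y, z, d) vectors for every in-mask voxel.

    Parameters
    ----------
    D
        Difference image (signed by default; ``absolute=True`` uses ``|D|``).
    mask
        Boolean volume of voxels to include; must be non-empty.
    d_weight
        Positive weight applied to the min-max-scaled difference channel.

    Notes
    -----
    A constant difference image over the mask is a documented degenerate
    case: the d channel is set to 0 for every vector (gain 0).
    """
    D = np.asarray(D, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if D.shape != mask.shape:
        raise ValueError(f"grid mismatch: D {D.shape} vs mask {mask.shape}")
    if d_weight <= 0:
        raise ValueError(f"d_weight must be > 0, got {d_weight}")
    if not mask.any():
        raise ValueError("mask is empty")
    if absolute:
        D = np.abs(D)

    grid_shape = D.shape
    idx = np.argwhere(mask)                      # (P, 3), row-major order
    d_vals = D[mask]

    offset = np.zeros(4)
    gain = np.empty(4)
    for a in range(3):
        gain[a] = 1.0 / max(grid_shape[a] - 1, 1)
    d_lo, d_hi = d_vals.min(), d_vals.max()
    offset[3] = d_lo
    gain[3] = 0.0 if d_hi == d_lo else d_weight / (d_hi - d_lo)

    vectors = np.empty((idx.shape[0], 4))
    vectors[:, :3] = idx * gain[:3]
    vectors[:, 3] = (d_vals - offset[3]) * gain[3]
    return FeatureSpace(
        vectors=vectors,
        voxel_index=idx,
        offset=offset,
        gain=gain,
        mask=mask,
        d_weight=float(d_weight),
        grid_shape=tuple(grid_shape),
    )
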