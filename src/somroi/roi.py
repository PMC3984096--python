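"""Receptive-field ROIs: voxel labelling, relevance scores, reconstructions.

The receptive field of SOM unit ``i`` is the set of feature vectors (hence
voxels) for which ``i`` is the best matching unit; mapped back to the image
grid, the receptive fields partition the mask into ``M`` disjoint ROIs.
Each ROI's relevance combines an intensity volume with the voxel-wise FDR:

    r_i = sum_{v in RF_i} weight(v) * FDR(v)          (optionally / |RF_i|)

At training time ``weight`` is the between-class difference image; for
per-subject projection it is the subject's own tissue map, yielding the
M-dimensional relevance vector used as classification features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from somroi.featurespace import FeatureSpace
from somroi.som3d import SomModel, bmu_indices
from somroi.voxelstats import fdr_threshold_mask

__all__ = [
    "RoiMap",
    "receptive_fields",
    "roi_relevance",
    "reconstruct_volume",
    "restrict_to_fdr_mask",
]

SENTINEL = -1


@dataclass
class RoiMap:
    """Voxel-to-ROI assignment on the image grid.

    ``label_volume`` holds the winning unit index per in-mask voxel and
    ``SENTINEL`` (-1) outside the mask; ``sizes`` the receptive-field sizes
    (summing to the mask size); ``relevance`` the per-ROI scores, or None
    when not yet computed.  Empty receptive fields are legal — units may win
    no voxel — and keep size 0, so feature dimensionality stays fixed at M.
    """

    label_volume: np.ndarray
    sizes: np.ndarray
    n_units: int
    relevance: np.ndarray | None = None
    tissue: str | None = None

    @property
    def mask(self) -> np.ndarray:
        return self.label_volume != SENTINEL

    @property
    def n_voxels(self) -> int:
        return int(self.sizes.sum())

    def roi_centroids(self) -> np.ndarray:
        """(M, 3) voxel centroid per ROI; NaN rows for empty ROIs."""
        out = np.full((self.n_units, 3), np.nan)
        labels = self.label_volume[self.mask]
        coords = np.argwhere(self.mask).astype(np.float64)
        for axis in range(3):
            sums = np.bincount(labels, weights=coords[:, axis], minlength=self.n_units)
            with np.errstate(invalid="ignore"):
                out[:, axis] = sums / np.where(self.sizes > 0, self.sizes, np.nan)
        return out


def receptive_fields(model: SomModel, fs: FeatureSpace, tissue: str | None = None) -> RoiMap:
    """Assign every in-mask voxel to its BMU, partitioning the mask into ROIs.

    Raises if the feature space's scaling record differs from the one the
    model was trained with (prototype and vector units would disagree).
    """
    if model.scaling_signature is not None and model.scaling_signature != fs.scaling_signature():
        raise ValueError(
            "feature-space scaling does not match the scaling the model was trained with"
        )
    labels = bmu_indices(model.prototypes, fs.vectors)
    label_volume = np.full(fs.grid_shape, SENTINEL, dtype=np.int64)
    label_volume[tuple(fs.voxel_index.T)] = labels
    sizes = np.bincount(labels, minlength=model.n_units)
    return RoiMap(
        label_volume=label_volume,
        sizes=sizes,
        n_units=model.n_units,
        tissue=tissue,
    )


def roi_relevance(
    roimap: RoiMap,
    weight_volume: np.ndarray,
    fdr: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Per-ROI relevance ``r_i = sum_{v in RF_i} weight(v) * fdr(v)``.

    With ``normalize=True`` (default) each sum is divided by
    ``max(|RF_i|, 1)``, making scores comparable across unequal receptive
    field sizes.  Empty ROIs score 0.
    """
    weight_volume = np.asarray(weight_volume, dtype=np.float64)
    fdr = np.asarray(fdr, dtype=np.float64)
    if weight_volume.shape != roimap.label_volume.shape:
        raise ValueError(
            f"grid mismatch: weight {weight_volume.shape} vs labels {roimap.label_volume.shape}"
        )
    if fdr.shape != roimap.label_volume.shape:
        raise ValueError(f"grid mismatch: fdr {fdr.shape} vs labels {roimap.label_volume.shape}")
    mask = roimap.mask
    labels = roimap.label_volume[mask]
    contrib = (weight_volume * fdr)[mask]
    r = np.bincount(labels, weights=contrib, minlength=roimap.n_units)
    if normalize:
        r = r / np.maximum(roimap.sizes, 1)
    return r


def reconstruct_volume(
    roimap: RoiMap, values: np.ndarray, fill: float = 0.0
) -> np.ndarray:
    """Paint each ROI's value onto its voxels; out-of-mask voxels get ``fill``."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (roimap.n_units,):
        raise ValueError(f"need {roimap.n_units} values, got shape {values.shape}")
    out = np.full(roimap.label_volume.shape, fill)
    mask = roimap.mask
    out[mask] = values[roimap.label_volume[mask]]
    return out


def restrict_to_fdr_mask(
    roimap: RoiMap,
    fdr: np.ndarray,
    fraction: float,
    weight_volume: np.ndarray | None = None,
    normalize: bool = True,
) -> RoiMap:
    """Keep only voxels whose FDR is strictly above ``fraction * max(fdr)``.

    Failing voxels are set to the sentinel; sizes are recomputed on the
    survivors (empty ROIs keep size 0).  Relevance is recomputed on the
    survivors when ``weight_volume`` is given, otherwise dropped.
    """
    fdr = np.asarray(fdr, dtype=np.float64)
    if fdr.shape != roimap.label_volume.shape:
        raise ValueError(f"grid mismatch: fdr {fdr.shape} vs labels {roimap.label_volume.shape}")
    keep = fdr_threshold_mask(fdr, fraction)
    label_volume = np.where(keep, roimap.label_volume, SENTINEL)
    surviving = label_volume[label_volume != SENTINEL]
    sizes = np.bincount(surviving, minlength=roimap.n_units)
    restricted = replace(
        roimap, label_volume=label_volume, sizes=sizes, relevance=None
    )
    if weight_volume is not None:
        restricted.relevance = roi_relevance(
            restricted, weight_volume, fdr, normalize=normalize
        )
    return restricted
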