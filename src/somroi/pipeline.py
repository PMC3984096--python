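"""Training-fold pipeline glue: stats -> difference image -> SOM -> ROIs.

``fit_tissue_model`` runs the whole ROI-construction chain for one tissue on
training subjects only, and ``project_subjects`` turns arbitrary subjects'
volumes into M-dimensional ROI relevance vectors against that trained model.
Keeping these two steps strictly separated is what makes the
cross-validation in :mod:`somroi.classify` fold-safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somroi.featurespace import FeatureSpace, build_feature_space, difference_image, tissue_mask
from somroi.roi import RoiMap, receptive_fields, roi_relevance
from somroi.som3d import SomConfig, SomModel, train
from somroi.voxelstats import DEFAULT_FDR_EPS, StatImages, VolumeStack

__all__ = ["TissueModel", "fit_tissue_model", "project_subjects"]


@dataclass
class TissueModel:
    """All training-fold artifacts for one tissue: class statistics, the
    difference image, the in-brain mask, the feature space, the trained SOM
    and its ROI map with training-time relevance."""

    tissue: str
    stats: StatImages
    difference: np.ndarray
    mask: np.ndarray
    feature_space: FeatureSpace
    som: SomModel
    roimap: RoiMap

    @property
    def n_rois(self) -> int:
        return self.roimap.n_units


def fit_tissue_model(
    stack: VolumeStack,
    som_config: SomConfig | None = None,
    reference_class: int | None = None,
    p_min: float = 0.05,
    fdr_eps: float = DEFAULT_FDR_EPS,
    d_weight: float = 1.0,
    absolute_difference: bool = False,
    normalize_relevance: bool = True,
) -> TissueModel:
    """Fit the full ROI model for one tissue from training subjects.

    The difference image is reference-class mean minus the other class's
    mean (reference defaults to the lowest label, the control class).  The
    ROI map's relevance is the training-time score using the difference
    image as weight.
    """
    stats = StatImages.from_stack(stack, eps=fdr_eps)
    c1, c2 = stats.class_order
    if reference_class is not None:
        if reference_class == c2:
            c1, c2 = c2, c1
        elif reference_class != c1:
            raise ValueError(f"reference_class {reference_class} not in {stats.class_order}")
    D = difference_image(stats.means[c1], stats.means[c2])
    mask = tissue_mask(stack, p_min=p_min)
    fs = build_feature_space(D, mask, d_weight=d_weight, absolute=absolute_difference)
    som = train(fs, som_config)
    roimap = receptive_fields(som, fs, tissue=stack.tissue)
    roimap.relevance = roi_relevance(roimap, D, stats.fdr, normalize=normalize_relevance)
    return TissueModel(
        tissue=stack.tissue,
        stats=stats,
        difference=D,
        mask=mask,
        feature_space=fs,
        som=som,
        roimap=roimap,
    )


def project_subjects(
    model: TissueModel,
    volumes: np.ndarray,
    normalize: bool = True,
) -> np.ndarray:
    """Project subject volumes onto the trained ROI model.

    Each subject's own tissue map replaces the difference image as the
    relevance weight, against the training-fold FDR, giving an
    ``(n_subjects, M)`` feature matrix.  Linear in the subject intensities.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.ndim == 3:
        volumes = volumes[None]
    if volumes.shape[1:] != model.difference.shape:
        raise ValueError(
            f"grid mismatch: subjects {volumes.shape[1:]} vs model {model.difference.shape}"
        )
    out = np.empty((volumes.shape[0], model.n_rois))
    for i, vol in enumerate(volumes):
        out[i] = roi_relevance(model.roimap, vol, model.stats.fdr, normalize=normalize)
    return out
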