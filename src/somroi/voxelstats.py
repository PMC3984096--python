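"""Voxel-wise class statistics and the Fisher Discriminant Ratio (FDR) image.

Given a cohort of co-registered tissue probability maps with binary class
labels, this module computes per-class mean and variance volumes and the
voxel-wise two-class Fisher Discriminant Ratio

    FDR(v) = (mu_1(v) - mu_2(v))^2 / (sigma_1^2(v) + sigma_2^2(v) + eps),

a dimensionless separability score that is large where the two groups
differ consistently relative to their within-group spread.  ``FDR`` here is
the classical discriminant ratio of pattern recognition, unrelated to the
false-discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeStack",
    "StatImages",
    "class_mean_image",
    "class_variance_image",
    "fdr_image",
    "fdr_threshold_mask",
]

#: Default ridge added to the pooled variance so zero-variance voxels yield
#: large finite FDR values instead of infinities.
DEFAULT_FDR_EPS = 1e-12


@dataclass
class VolumeStack:
    """A cohort of co-registered 3-D volumes with per-subject class labels.

    Parameters
    ----------
    volumes
        Array of shape ``(n_subjects, nx, ny, nz)`` holding probability-map
        intensities in ``[0, 1]``.
    labels
        Integer class indicator per subject (binary for FDR use).
    tissue
        Tissue tag, ``"GM"`` or ``"WM"``.
    """

    volumes: np.ndarray
    labels: np.ndarray
    tissue: str = "GM"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.volumes.ndim != 4:
            raise ValueError(
                f"volumes must be (n_subjects, nx, ny, nz); got {self.volumes.shape}"
            )
        if self.labels.shape != (self.volumes.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match "
                f"{self.volumes.shape[0]} subjects"
            )
        if self.tissue not in ("GM", "WM"):
            raise ValueError(f"tissue must be 'GM' or 'WM', got {self.tissue!r}")

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, index: np.ndarray) -> "VolumeStack":
        """Return a new stack restricted to the given subject indices."""
        return VolumeStack(self.volumes[index], self.labels[index], self.tissue)


@dataclass
class StatImages:
    """Per-class mean/variance volumes and the derived FDR volume.

    ``means`` and ``variances`` map class id to a volume on the common grid;
    ``counts`` holds the per-class subject counts; ``fdr`` is the voxel-wise
    Fisher Discriminant Ratio between the two classes (ordered by class id).
    """

    means: dict[int, np.ndarray]
    variances: dict[int, np.ndarray]
    counts: dict[int, int]
    fdr: np.ndarray
    eps: float = DEFAULT_FDR_EPS
    class_order: tuple[int, int] = field(default=(0, 1))

    @classmethod
    def from_stack(
        cls,
        stack: VolumeStack,
        eps: float = DEFAULT_FDR_EPS,
        ddof: int = 0,
    ) -> "StatImages":
        """Compute class statistics and the FDR image from a labelled stack.

        The stack must contain exactly two distinct classes.  ``ddof=0``
        (population variance) is the default convention; ``ddof=1`` selects
        the sample variance.
        """
        classes = stack.classes
        if len(classes) != 2:
            raise ValueError(
                f"FDR needs exactly two classes; stack has {list(classes)}"
            )
        c1, c2 = int(classes[0]), int(classes[1])
        means = {c: class_mean_image(stack, c) for c in (c1, c2)}
        variances = {c: class_variance_image(stack, c, ddof=ddof) for c in (c1, c2)}
        counts = {c: int(np.sum(stack.labels == c)) for c in (c1, c2)}
        fdr = fdr_image(
            (means[c1], variances[c1]), (means[c2], variances[c2]), eps=eps
        )
        return cls(means, variances, counts, fdr, eps=eps, class_order=(c1, c2))


def _class_volumes(stack: VolumeStack, class_id: int) -> np.ndarray:
    sel = stack.labels == class_id
    if not np.any(sel):
        raise ValueError(f"no subjects with class {class_id}")
    return stack.volumes[sel]


def class_mean_image(stack: VolumeStack, class_id: int) -> np.ndarray:
    """Voxel-wise arithmetic mean over the subjects of one class."""
    return _class_volumes(stack, class_id).mean(axis=0)


def class_variance_image(
    stack: VolumeStack, class_id: int, ddof: int = 0
) -> np.ndarray:
    """Voxel-wise variance over the subjects of one class.

    ``ddof=0`` gives the population variance (divide by ``N_c``), the
    convention used throughout the pipeline; ``ddof=1`` gives the unbiased
    sample variance.
    """
    vols = _class_volumes(stack, class_id)
    if ddof >= vols.shape[0]:
        raise ValueError(
            f"ddof={ddof} needs more than {vols.shape[0]} subjects in class"
        )
    return vols.var(axis=0, ddof=ddof)


def fdr_image(
    stats_class1: tuple[np.ndarray, np.ndarray],
    stats_class2: tuple[np.ndarray, np.ndarray],
    eps: float = DEFAULT_FDR_EPS,
) -> np.ndarray:
    """Voxel-wise two-class Fisher Discriminant Ratio.

    Parameters
    ----------
    stats_class1, stats_class2
        ``(mean_volume, variance_volume)`` pairs for each class, all on the
        same grid.
    eps
        Non-negative ridge added to the pooled variance.  Voxels with zero
        numerator are defined to have FDR 0 even when the denominator
        vanishes.

    Returns
    -------
    ndarray
        ``(mu1 - mu2)**2 / (var1 + var2 + eps)``, non-negative, symmetric
        under swapping the class arguments.
    """
    m1, v1 = stats_class1
    m2, v2 = stats_class2
    if eps < 0:
        raise ValueError(f"eps must be >= 0, got {eps}")
    for vol in (v1, m2, v2):
        if np.shape(vol) != np.shape(m1):
            raise ValueError(
                f"grid mismatch: {np.shape(vol)} vs {np.shape(m1)}"
            )
    num = np.square(np.asarray(m1, dtype=np.float64) - m2)
    den = np.asarray(v1, dtype=np.float64) + v2 + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(num == 0.0, 0.0, num / den)
    return out


def fdr_threshold_mask(fdr: np.ndarray, fraction: float) -> np.ndarray:
    """Mask of voxels whose FDR is strictly above ``fraction * max(fdr)``.

    The strictly-greater-than convention makes ``fraction=1.0`` a
    well-defined empty mask and excludes exact ties deterministically.  An
    all-zero FDR volume yields an all-false mask.
    """
    fdr = np.asarray(fdr)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    peak = fdr.max() if fdr.size else 0.0
    if peak <= 0.0:
        return np.zeros(fdr.shape, dtype=bool)
    return fdr > fraction * peak
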