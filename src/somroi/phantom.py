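"""Synthetic two-class cohorts of GM/WM probability maps with planted atrophy.

The phantom emulates the structure the ROI pipeline assumes of segmented,
co-registered brain maps: smooth tissue probability fields in [0, 1],
spatially compact between-class differences, and independent per-subject
noise.  Class 1 ("disease") loses intensity inside each planted spherical
region of the matching tissue, so the difference image
mean(class 0) - mean(class 1) is positive there — the control-minus-patient
sign convention used throughout the pipeline.

Nothing anatomical is simulated: the baseline is a seeded low-frequency
random field, identical for both classes, rescaled to [0.2, 0.9] so tissue
masks and FDR denominators stay well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from somroi.voxelstats import VolumeStack

__all__ = ["EffectRegion", "PhantomConfig", "generate_cohort", "sphere_mask"]


@dataclass(frozen=True)
class EffectRegion:
    """A spherical planted effect: class-1 subjects lose ``effect_size``
    intensity inside the sphere, in the named tissue."""

    center: tuple[float, float, float]
    radius: float
    effect_size: float
    tissue: str = "GM"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.tissue not in ("GM", "WM"):
            raise ValueError(f"tissue must be 'GM' or 'WM', got {self.tissue!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of a synthetic cohort.

    Defaults describe the standard study condition used across the test
    suite and examples: a 32^3 grid, 40 subjects per class, one grey-matter
    sphere of radius 4 voxels losing 0.4 probability units, additive
    Gaussian noise of sd 0.05, and a baseline length scale of 4 voxels.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_per_class: int = 40
    effect_regions: tuple[EffectRegion, ...] = (
        EffectRegion(center=(16.0, 16.0, 16.0), radius=4.0, effect_size=0.4, tissue="GM"),
    )
    baseline_smoothness: float = 4.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 8, got {self.grid_shape}")
        if self.n_per_class < 2:
            raise ValueError(f"n_per_class must be >= 2, got {self.n_per_class}")
        if self.baseline_smoothness < 0:
            raise ValueError("baseline_smoothness must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for reg in self.effect_regions:
            for c, dim in zip(reg.center, self.grid_shape):
                if not 0 <= c < dim:
                    raise ValueError(
                        f"effect center {reg.center} outside grid {self.grid_shape}"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_regions"] = [asdict(r) for r in self.effect_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["effect_regions"] = tuple(
            EffectRegion(
                center=tuple(r["center"]),
                radius=r["radius"],
                effect_size=r["effect_size"],
                tissue=r.get("tissue", "GM"),
            )
            for r in d.get("effect_regions", [])
        )
        return cls(**d)


def sphere_mask(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
) -> np.ndarray:
    """Boolean volume marking voxels within ``radius`` of ``center``."""
    coords = np.indices(grid_shape, dtype=np.float64)
    d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius * radius


def _baseline_field(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int],
    smoothness: float,
    lo: float = 0.2,
    hi: float = 0.9,
) -> np.ndarray:
    """Seeded low-frequency random field rescaled to [lo, hi]."""
    noise = rng.standard_normal(grid_shape)
    if smoothness > 0:
        noise = gaussian_filter(noise, sigma=smoothness, mode="nearest")
    lo_v, hi_v = noise.min(), noise.max()
    if hi_v == lo_v:  # perfectly flat field (e.g. extreme smoothing)
        return np.full(grid_shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (noise - lo_v) / (hi_v - lo_v)


def generate_cohort(config: PhantomConfig) -> tuple[VolumeStack, VolumeStack]:
    """Generate a two-class cohort of GM and WM probability-map stacks.

    Returns ``(gm_stack, wm_stack)``, each with ``2 * n_per_class`` subjects
    labelled 0 (control) then 1 (disease), in matching subject order across
    tissues.  Class 1 subjects have each matching-tissue effect subtracted
    inside its sphere before noise; voxel values are clipped to [0, 1].
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    n = config.n_per_class

    baselines = {t: _baseline_field(rng, shape, config.baseline_smoothness) for t in ("GM", "WM")}
    effects = {t: np.zeros(shape) for t in ("GM", "WM")}
    for reg in config.effect_regions:
        effects[reg.tissue] += reg.effect_size * sphere_mask(shape, reg.center, reg.radius)

    labels = np.concatenate([np.zeros(n, dtype=np.int64), np.ones(n, dtype=np.int64)])
    stacks = {}
    for tissue in ("GM", "WM"):
        vols = np.empty((2 * n, *shape))
        for i, lab in enumerate(labels):
            vol = baselines[tissue] - (effects[tissue] if lab == 1 else 0.0)
            if config.noise_sd > 0:
                vol = vol + config.noise_sd * rng.standard_normal(shape)
            vols[i] = np.clip(vol, 0.0, 1.0)
        stacks[tissue] = VolumeStack(vols, labels.copy(), tissue)
    return stacks["GM"], stacks["WM"]
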