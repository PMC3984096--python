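"""Self-organizing map on a 3-D output lattice with two-phase online training.

The map places ``M = nx * ny * nz`` units on a 3-D lattice (flat, or
cylindrical with the first axis wrapping) and quantizes the 4-D feature
space.  Training is the classical online competitive rule: for each sample
``x`` the best matching unit (BMU) is

    c = argmin_i ||x - w_i||,

and every prototype moves by

    w_i <- w_i + alpha(t) * h(d_lattice(c, i), sigma(t)) * (x - w_i),

with Gaussian neighbourhood ``h(d, sigma) = exp(-d^2 / (2 sigma^2))`` and
reciprocally decreasing learning rate ``alpha(t) = alpha0 / (1 + t / T)``
(``T`` = total steps in the phase).  Training runs in two phases: a rough
ordering phase with a wide neighbourhood and alpha0 = 0.1, then a
fine-tuning phase with a narrow neighbourhood and a smaller learning rate.
Within each phase sigma decays linearly from its initial value to a floor.

Every update is a convex pull toward a data sample, so prototypes remain in
the axis-aligned bounding box of the initial prototypes and the data.
Training is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from somroi.featurespace import FeatureSpace

__all__ = [
    "PhaseSchedule",
    "SomConfig",
    "SomModel",
    "lattice_distance",
    "find_bmu",
    "bmu_indices",
    "neighborhood_value",
    "learning_rate",
    "train",
    "quantization_error",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """One training phase: initial learning rate and neighbourhood radius
    (``sigma0=None`` means derive from the lattice at train time), epoch
    count, and the radius floor the linear decay ends at."""

    alpha0: float
    sigma0: float | None
    epochs: int
    sigma_floor: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha0 <= 1:
            raise ValueError(f"alpha0 must be in (0, 1], got {self.alpha0}")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


@dataclass(frozen=True)
class SomConfig:
    """Lattice geometry, topology, two-phase schedule, init mode and seed.

    Defaults: a 6x6x3 cylindrical lattice (108 units / ROIs); phase 1 with
    alpha0 = 0.1 and sigma0 = max(lattice)/2 decaying to 1.0 over 10 epochs;
    phase 2 with alpha0 = 0.01 and sigma0 = max(lattice)/8 decaying to 0.5
    over 20 epochs.  ``subsample`` caps the training vectors drawn per epoch
    (seeded, without replacement); None uses the full feature space.
    """

    lattice_shape: tuple[int, int, int] = (6, 6, 3)
    topology: str = "cylindrical"
    phase1: PhaseSchedule = field(
        default_factory=lambda: PhaseSchedule(alpha0=0.1, sigma0=None, epochs=10, sigma_floor=1.0)
    )
    phase2: PhaseSchedule = field(
        default_factory=lambda: PhaseSchedule(alpha0=0.01, sigma0=None, epochs=20, sigma_floor=0.5)
    )
    init: str = "linear"
    seed: int = 0
    subsample: int | None = None

    def __post_init__(self) -> None:
        if len(self.lattice_shape) != 3 or any(s < 1 for s in self.lattice_shape):
            raise ValueError(f"lattice_shape must be 3 positive ints, got {self.lattice_shape}")
        if self.topology not in ("flat", "cylindrical"):
            raise ValueError(f"topology must be 'flat' or 'cylindrical', got {self.topology!r}")
        if self.init not in ("linear", "random"):
            raise ValueError(f"init must be 'linear' or 'random', got {self.init!r}")
        if self.subsample is not None and self.subsample < 1:
            raise ValueError(f"subsample must be >= 1, got {self.subsample}")

    @property
    def n_units(self) -> int:
        nx, ny, nz = self.lattice_shape
        return nx * ny * nz

    def resolved_phase(self, which: int) -> PhaseSchedule:
        """Phase schedule with ``sigma0=None`` replaced by its lattice default:
        max(lattice)/2 for phase 1, max(lattice)/8 for phase 2 (at least the floor)."""
        phase = self.phase1 if which == 1 else self.phase2
        if phase.sigma0 is not None:
            return phase
        div = 2.0 if which == 1 else 8.0
        sigma0 = max(max(self.lattice_shape) / div, phase.sigma_floor, 1e-6)
        return replace(phase, sigma0=sigma0)

    def to_dict(self) -> dict:
        return asdict(self)


def lattice_coordinates(lattice_shape: tuple[int, int, int]) -> np.ndarray:
    """Unit index -> lattice coordinate, row-major mixed-radix (0-based)."""
    nx, ny, nz = lattice_shape
    i = np.arange(nx * ny * nz)
    return np.stack([i // (ny * nz), (i // nz) % ny, i % nz], axis=1)


@dataclass
class SomModel:
    """A trained (or initialized) map: prototypes plus the lattice record.

    ``qe_history[0]`` is the quantization error of the initial prototypes
    over the full feature space; entry ``e >= 1`` is the error over the
    vectors presented in epoch ``e``, measured after that epoch's updates.
    """

    prototypes: np.ndarray        # (M, 4) in feature-space units
    lattice_coords: np.ndarray    # (M, 3) integer
    topology: str
    lattice_shape: tuple[int, int, int]
    config: SomConfig
    qe_history: list[float] = field(default_factory=list)
    scaling_signature: tuple | None = None

    @property
    def n_units(self) -> int:
        return self.prototypes.shape[0]


def _wrapped_deltas(
    a: np.ndarray, b: np.ndarray, lattice_shape: tuple[int, int, int], topology: str
) -> np.ndarray:
    d = np.abs(a - b)
    if topology == "cylindrical":
        nx = lattice_shape[0]
        d = d.astype(np.float64, copy=True)
        d[..., 0] = np.minimum(d[..., 0], nx - d[..., 0])
    return d


def lattice_distance(model: SomModel, i: int, j: int) -> float:
    """Euclidean distance between units ``i`` and ``j`` on the output lattice.

    For the cylindrical topology the first lattice axis wraps around:
    ``dx = min(|xi - xj|, nx - |xi - xj|)``.
    """
    m = model.n_units
    if not (0 <= i < m and 0 <= j < m):
        raise IndexError(f"unit index out of range [0, {m}): {i}, {j}")
    d = _wrapped_deltas(
        model.lattice_coords[i].astype(np.float64),
        model.lattice_coords[j].astype(np.float64),
        model.lattice_shape,
        model.topology,
    )
    return float(np.sqrt(np.sum(d * d)))


def _lattice_sq_distances(model: SomModel) -> np.ndarray:
    """Full (M, M) matrix of squared lattice distances."""
    c = model.lattice_coords.astype(np.float64)
    d = _wrapped_deltas(c[:, None, :], c[None, :, :], model.lattice_shape, model.topology)
    return np.sum(d * d, axis=-1)


def neighborhood_value(d_lattice: float, sigma: float) -> float:
    """Gaussian neighbourhood kernel ``exp(-d^2 / (2 sigma^2))``, in (0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return float(np.exp(-(d_lattice * d_lattice) / (2.0 * sigma * sigma)))


def learning_rate(alpha0: float, t: int, T: int) -> float:
    """Reciprocally decreasing learning rate ``alpha0 / (1 + t / T)``."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return alpha0 / (1.0 + t / T)


def _phase_sigma(phase: PhaseSchedule, t: int, T: int) -> float:
    """Linear decay from sigma0 to the floor across the phase's T steps."""
    if T <= 1:
        return phase.sigma_floor
    frac = t / (T - 1)
    return phase.sigma0 + (phase.sigma_floor - phase.sigma0) * min(frac, 1.0)


def find_bmu(model: SomModel, x: np.ndarray) -> int:
    """Index of the prototype nearest to ``x`` (Euclidean); ties break to the
    lowest unit index."""
    diff = model.prototypes - np.asarray(x, dtype=np.float64)
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def bmu_indices(prototypes: np.ndarray, X: np.ndarray, chunk: int = 8192) -> np.ndarray:
    """BMU index for every row of ``X`` against ``prototypes``.

    Computed by exact squared-difference expansion in chunks, so results are
    identical to an exhaustive per-query scan (same arithmetic, same
    first-minimum tie rule).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    out = np.empty(X.shape[0], dtype=np.int64)
    for lo in range(0, X.shape[0], chunk):
        block = X[lo : lo + chunk]
        diff = block[:, None, :] - prototypes[None, :, :]
        out[lo : lo + chunk] = np.argmin(np.einsum("pij,pij->pi", diff, diff), axis=1)
    return out


def _initial_prototypes(fs: FeatureSpace, config: SomConfig, rng: np.random.Generator) -> np.ndarray:
    lo = fs.vectors.min(axis=0)
    hi = fs.vectors.max(axis=0)
    m = config.n_units
    if config.init == "random":
        return lo + (hi - lo) * rng.random((m, 4))
    # linear: map lattice coordinates affinely onto the spatial bounding box;
    # the intensity channel starts at the mid-range (no lattice axis maps to it).
    coords = lattice_coordinates(config.lattice_shape).astype(np.float64)
    denom = np.maximum(np.array(config.lattice_shape, dtype=np.float64) - 1.0, 1.0)
    frac = coords / denom
    w = np.empty((m, 4))
    w[:, :3] = lo[:3] + frac * (hi[:3] - lo[:3])
    w[:, 3] = 0.5 * (lo[3] + hi[3])
    return w


def quantization_error(model: SomModel, fs: FeatureSpace | np.ndarray) -> float:
    """Mean Euclidean distance from each vector to its BMU prototype."""
    X = fs.vectors if isinstance(fs, FeatureSpace) else np.atleast_2d(np.asarray(fs, dtype=np.float64))
    if X.shape[0] == 0:
        return 0.0
    bmus = bmu_indices(model.prototypes, X)
    return float(np.mean(np.linalg.norm(X - model.prototypes[bmus], axis=1)))


def train(fs: FeatureSpace, config: SomConfig | None = None) -> SomModel:
    """Train the map on a feature space with the two-phase online schedule.

    Each phase draws samples in a seeded shuffled order each epoch
    (optionally subsampled without replacement), finds the BMU and pulls
    every prototype toward the sample weighted by the Gaussian neighbourhood
    of its lattice distance to the BMU.  Returns the trained model with its
    quantization-error history.
    """
    if config is None:
        config = SomConfig()
    if fs.n_vectors == 0:
        raise ValueError("feature space is empty")
    rng = np.random.default_rng(config.seed)
    X = np.ascontiguousarray(fs.vectors)
    P = X.shape[0]
    n_draw = P if config.subsample is None else min(config.subsample, P)

    model = SomModel(
        prototypes=_initial_prototypes(fs, config, rng),
        lattice_coords=lattice_coordinates(config.lattice_shape),
        topology=config.topology,
        lattice_shape=tuple(config.lattice_shape),
        config=config,
        scaling_signature=fs.scaling_signature(),
    )
    W = model.prototypes
    D2 = _lattice_sq_distances(model)
    model.qe_history.append(quantization_error(model, fs))

    for which in (1, 2):
        phase = config.resolved_phase(which)
        T = phase.epochs * n_draw
        t = 0
        for _ in range(phase.epochs):
            order = rng.permutation(P)[:n_draw]
            for p in order:
                x = X[p]
                diff = x - W
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                sigma = _phase_sigma(phase, t, T)
                alpha = learning_rate(phase.alpha0, t, T)
                h = np.exp(D2[bmu] * (-0.5 / (sigma * sigma)))
                W += (alpha * h)[:, None] * diff
                t += 1
            model.qe_history.append(quantization_error(model, X[order]))
    return model
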