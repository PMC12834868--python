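"""Synthetic data generators.

Three constructions exercise the whole pipeline without external data:

* :func:`generate_atom` — the two-sphere benchmark: 400 "kernel" points
  uniform inside a small ball, 400 "hull" points uniform on the surface of
  a larger concentric sphere. The classes are strictly separated in radius
  but not linearly separable, which is exactly what defeats linear models
  while distance- and tree-based classifiers separate them perfectly.
* :func:`duplicate_with_noise` — a copy of a feature perturbed by
  zero-mean Gaussian noise whose per-value standard deviation is a fixed
  fraction of the absolute value. For a standardised input and a 20%
  fraction the expected correlation with the original is
  1/sqrt(1 + 0.2**2) ~ 0.98.
* :func:`generate_planted` — two-class Gaussian tables with planted
  standardised effect sizes and optional equicorrelated feature blocks,
  emulating the statistical shape of moderate-size clinical tables
  (n ~ 100-150 cases, unit-variance features).

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "AtomSpec",
    "PlantedSpec",
    "generate_atom",
    "duplicate_with_noise",
    "generate_planted",
    "generate_xor",
]


@dataclass(frozen=True)
class AtomSpec:
    """Two concentric spherical classes in 3-D.

    Radii default to 10 (kernel ball) and 50 (hull shell): any strictly
    separated pair reproduces the linear-non-separability phenomenon; a
    wide gap makes the geometry unambiguous.
    """

    n_total: int = 800
    kernel_radius: float = 10.0
    hull_radius: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 8 or self.n_total % 2:
            raise ValueError("n_total must be an even number >= 8")
        if not 0 < self.kernel_radius < self.hull_radius:
            raise ValueError("need 0 < kernel_radius < hull_radius")


def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_atom(spec: AtomSpec = AtomSpec()) -> LabeledDataset:
    """Generate the two-sphere dataset (classes ``kernel`` and ``hull``).

    Kernel points are uniform over the ball volume (radius by inverse-CDF,
    r proportional to U**(1/3)); hull points are uniform on the sphere
    surface (normalised Gaussian directions). No rejection sampling.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.n_total // 2
    r_kernel = spec.kernel_radius * rng.random(half) ** (1.0 / 3.0)
    kernel = _unit_directions(rng, half) * r_kernel[:, None]
    hull = _unit_directions(rng, half) * spec.hull_radius
    X = np.vstack([kernel, hull])
    labels = np.array(["kernel"] * half + ["hull"] * half)
    return LabeledDataset(X, ("X1", "X2", "X3"), labels, ("hull", "kernel"))


def duplicate_with_noise(feature: np.ndarray, relative_sd: float, seed: int) -> np.ndarray:
    """Copy of ``feature`` plus N(0, (relative_sd * |value|)**2) noise.

    The closed-form correlation with the original is
    1 / sqrt(1 + relative_sd**2 * E[X**2] / Var(X)).
    """
    feature = np.asarray(feature, dtype=float)
    if relative_sd < 0:
        raise ValueError("relative_sd must be non-negative")
    rng = np.random.default_rng(seed)
    return feature + rng.normal(0.0, relative_sd * np.abs(feature))


@dataclass(frozen=True)
class PlantedSpec:
    """Two-class Gaussian feature table with planted effects.

    ``informative`` lists (feature index, standardised effect size d):
    the positive class mean is shifted by d on those unit-variance
    features. ``correlation_blocks`` lists (index tuple, pairwise r)
    groups given an equicorrelated structure via a shared latent factor.
    Defaults mirror a moderate clinical table: n=150 cases, p=20 features,
    balanced classes.
    """

    n: int = 150
    p: int = 20
    informative: tuple[tuple[int, float], ...] = ()
    correlation_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    class_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8 or self.p < 1:
            raise ValueError("need n >= 8 and p >= 1")
        if not 0 < self.class_ratio < 1:
            raise ValueError("class_ratio must lie in (0, 1)")
        for idx, d in self.informative:
            if not 0 <= idx < self.p or not np.isfinite(d):
                raise ValueError(f"invalid informative entry ({idx}, {d})")
        for block, r in self.correlation_blocks:
            if not all(0 <= j < self.p for j in block):
                raise ValueError(f"correlation block {block} out of range")
            if not -1 < r < 1:
                raise ValueError(f"block correlation must satisfy |r| < 1, got {r}")
            if r < -1.0 / max(1, len(block) - 1):
                raise ValueError(f"block correlation {r} not positive definite for size {len(block)}")


def generate_planted(spec: PlantedSpec = PlantedSpec()) -> LabeledDataset:
    """Generate a labelled Gaussian table with planted signal.

    Correlated blocks use the factor construction
    x_j = sqrt(r) * f + sqrt(1 - r) * e_j, which keeps unit variance and
    pairwise correlation exactly r; class shifts are applied afterwards
    on the standardised scale.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.class_ratio * spec.n))
    if n_pos < 2 or spec.n - n_pos < 2:
        raise ValueError("class_ratio leaves a class with fewer than 2 cases")
    y = np.array([0] * (spec.n - n_pos) + [1] * n_pos)

    X = rng.standard_normal((spec.n, spec.p))
    for block, r in spec.correlation_blocks:
        if r > 0:
            factor = rng.standard_normal(spec.n)
            for j in block:
                X[:, j] = np.sqrt(r) * factor + np.sqrt(1.0 - r) * X[:, j]
    for idx, d in spec.informative:
        X[y == 1, idx] += d

    labels = np.where(y == 1, "case", "control")
    names = tuple(f"f{j:02d}" for j in range(spec.p))
    return LabeledDataset(X, names, labels, ("control", "case"))


def generate_xor(n: int = 200, n_noise: int = 4, seed: int = 0) -> LabeledDataset:
    """Two features informative only jointly (label = sign of their product).

    Each feature alone carries no class information and no linear model can
    use the pair, but their interaction determines the label exactly; the
    construction probes interaction-only signal hidden from marginal and
    sparse-linear selection.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2 + n_noise))
    prod = X[:, 0] * X[:, 1]
    labels = np.where(prod > 0, "pos", "neg")
    if len(set(labels)) < 2:  # pathological tiny-n draw
        labels[0] = "pos" if labels[0] == "neg" else "neg"
    names = ("x1", "x2") + tuple(f"noise{j}" for j in range(n_noise))
    return LabeledDataset(X, names, labels, ("neg", "pos"))
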