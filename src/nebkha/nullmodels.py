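"""Constrained Monte Carlo null models for non-overlapping disc patterns.

Two randomization schemes provide the reference distributions against which
observed summary statistics are judged:

* **Univariate homogeneous null** — relocates the patches of one cohort to
  i.i.d. uniform positions in the window (a binomial process: the observed
  count and diameter multiset are conserved), subject to whole-disc
  containment and non-overlap both among the relocated patches and with the
  patches of *older* cohorts, which stay fixed.  Departures of the cohort's
  PCF from this null indicate within-cohort clustering or regularity.

* **Bivariate heterogeneous null** — relocates a (non-large-adult) cohort
  according to a heterogeneous Poisson intensity obtained by smoothing the
  observed cohort centroids with an isotropic Gaussian kernel (default SD
  5 m), again with fixed count, diameter multiset, containment and
  non-overlap against the conditioning (older) patches.  Because the null
  preserves the cohort's own large-scale density surface, departures of the
  cross-correlation with large adults isolate short-range attraction or
  repulsion rather than shared large-scale clustering.

Placement in both schemes is sequential from the largest disc to the
smallest (ties broken by patch id) with rejection sampling; if a disc
cannot be placed within ``max_attempts_per_patch`` proposals the whole
simulation restarts, up to ``max_restarts`` times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import PatchPattern, RectWindow

__all__ = [
    "NullModelConfig",
    "IntensitySurface",
    "PackingError",
    "estimate_intensity",
    "simulate_univariate_null",
    "simulate_bivariate_null",
]


class PackingError(RuntimeError):
    """Raised when a disc cannot be placed under the non-overlap constraint."""


@dataclass(frozen=True)
class NullModelConfig:
    """Tuning knobs shared by both null models."""

    kernel_sd: float = 5.0  # m; bivariate intensity smoothing
    lattice_step: float = 0.5  # m; intensity evaluation lattice
    max_attempts_per_patch: int = 10_000
    max_restarts: int = 100

    def __post_init__(self) -> None:
        if self.kernel_sd <= 0 or self.lattice_step <= 0:
            raise ValueError("kernel_sd and lattice_step must be > 0")
        if self.max_attempts_per_patch < 1 or self.max_restarts < 1:
            raise ValueError("attempt limits must be >= 1")


@dataclass
class IntensitySurface:
    """Gaussian kernel intensity evaluated on a regular lattice."""

    window: RectWindow
    step: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray  # (nx, ny), values[i, j] at (x_centers[i], y_centers[j])

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.step**2)


def estimate_intensity(
    centroids: np.ndarray,
    window: RectWindow,
    kernel_sd: float = 5.0,
    lattice_step: float = 0.5,
) -> IntensitySurface:
    """Sum of isotropic bivariate Gaussians centered at the given centroids.

    No renormalization is applied at the window edges: the same uncorrected
    surface drives the null-model sampling, so envelope comparisons stay
    internally consistent.  The lattice integral is therefore at most the
    number of centroids.
    """
    centroids = np.atleast_2d(np.asarray(centroids, float))
    if centroids.shape[0] < 1:
        raise ValueError("at least one centroid required")
    nx = max(1, int(np.ceil(window.width / lattice_step)))
    ny = max(1, int(np.ceil(window.height / lattice_step)))
    xc = window.x_min + (np.arange(nx) + 0.5) * window.width / nx
    yc = window.y_min + (np.arange(ny) + 0.5) * window.height / ny
    inv2s2 = 1.0 / (2.0 * kernel_sd**2)
    norm = 1.0 / (2.0 * np.pi * kernel_sd**2)
    gx = np.exp(-((xc[:, None] - centroids[None, :, 0]) ** 2) * inv2s2)
    gy = np.exp(-((yc[:, None] - centroids[None, :, 1]) ** 2) * inv2s2)
    values = norm * gx @ gy.T  # (nx, ny): separable Gaussian product summed
    return IntensitySurface(window, float(window.width / nx), xc, yc, values)


def _placement_order(pattern: PatchPattern) -> np.ndarray:
    """Strictly decreasing diameter, ties broken by ascending patch id."""
    return np.lexsort((pattern.ids, -pattern.diameter))


class _Placed:
    """Grow-only store of placed discs with vectorized overlap checks."""

    def __init__(self, capacity: int, fixed_x, fixed_y, fixed_r):
        self.x = np.empty(capacity)
        self.y = np.empty(capacity)
        self.r = np.empty(capacity)
        self.n = 0
        self.fx = np.asarray(fixed_x, float)
        self.fy = np.asarray(fixed_y, float)
        self.fr = np.asarray(fixed_r, float)

    def ok(self, x: float, y: float, r: float) -> bool:
        if self.n:
            d = np.hypot(self.x[: self.n] - x, self.y[: self.n] - y)
            if np.any(d < self.r[: self.n] + r):
                return False
        if self.fx.size:
            d = np.hypot(self.fx - x, self.fy - y)
            if np.any(d < self.fr + r):
                return False
        return True

    def add(self, x: float, y: float, r: float) -> None:
        self.x[self.n] = x
        self.y[self.n] = y
        self.r[self.n] = r
        self.n += 1


def _fixed_arrays(fixed: Sequence[PatchPattern]):
    if not fixed:
        return np.empty(0), np.empty(0), np.empty(0)
    return (
        np.concatenate([p.x for p in fixed]),
        np.concatenate([p.y for p in fixed]),
        np.concatenate([p.radius for p in fixed]),
    )


def simulate_univariate_null(
    cohort: PatchPattern,
    fixed_older: Sequence[PatchPattern],
    window: RectWindow,
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PatchPattern:
    """One homogeneous (binomial) relocation of ``cohort``.

    Conserves the count and diameter multiset; centroids uniform over the
    containment-shrunken window, rejected on overlap with already-placed
    or fixed older patches.
    """
    config = config or NullModelConfig()
    rng = rng if rng is not None else np.random.default_rng()
    order = _placement_order(cohort)
    radii = cohort.radius[order]
    fx, fy, fr = _fixed_arrays(fixed_older)
    for _ in range(config.max_restarts):
        placed = _Placed(len(cohort), fx, fy, fr)
        if _try_place_uniform(placed, radii, window, config, rng):
            return _as_pattern(cohort, order, placed, window)
    raise PackingError(
        f"could not place patch of diameter {2 * radii[placed.n]:.3f} m "
        f"after {config.max_restarts} restarts"
    )


def _try_place_uniform(placed, radii, window, config, rng) -> bool:
    for r in radii:
        lo_x, hi_x = window.x_min + r, window.x_max - r
        lo_y, hi_y = window.y_min + r, window.y_max - r
        if hi_x < lo_x or hi_y < lo_y:
            raise PackingError(f"disc of radius {r:.3f} m does not fit the window")
        for _ in range(config.max_attempts_per_patch):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if placed.ok(x, y, r):
                placed.add(x, y, r)
                break
        else:
            return False
    return True


def simulate_bivariate_null(
    cohort: PatchPattern,
    conditioning: Sequence[PatchPattern],
    window: RectWindow,
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
    intensity: IntensitySurface | None = None,
) -> PatchPattern:
    """One heterogeneous-Poisson relocation of ``cohort``.

    The sampling intensity is the Gaussian-kernel surface of the *observed*
    cohort centroids (precompute it once via ``intensity=`` when simulating
    batches).  Conditioning patches are left untouched; count and diameter
    multiset of the cohort are conserved.
    """
    if len(cohort) < 1:
        raise ValueError("cohort must contain at least one patch")
    config = config or NullModelConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if intensity is None:
        intensity = estimate_intensity(
            np.column_stack([cohort.x, cohort.y]),
            window,
            config.kernel_sd,
            config.lattice_step,
        )
    flat = intensity.values.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("intensity surface is zero everywhere")
    cdf = np.cumsum(flat) / total
    nx, ny = intensity.values.shape
    step = intensity.step
    order = _placement_order(cohort)
    radii = cohort.radius[order]
    fx, fy, fr = _fixed_arrays(conditioning)
    for _ in range(config.max_restarts):
        placed = _Placed(len(cohort), fx, fy, fr)
        complete = True
        for r in radii:
            done = False
            for _ in range(config.max_attempts_per_patch):
                # lattice-cell draw proportional to intensity + uniform jitter
                cell = int(np.searchsorted(cdf, rng.random(), side="right"))
                ci, cj = divmod(cell, ny)
                x = intensity.x_centers[ci] + (rng.random() - 0.5) * step
                y = intensity.y_centers[cj] + (rng.random() - 0.5) * step
                if not window.contains_disc(x, y, r):
                    continue
                if placed.ok(x, y, r):
                    placed.add(x, y, r)
                    done = True
                    break
            if not done:
                complete = False
                break
        if complete:
            return _as_pattern(cohort, order, placed, window)
    raise PackingError(
        f"bivariate null: could not place a disc after {config.max_restarts} restarts"
    )


def _as_pattern(cohort, order, placed, window) -> PatchPattern:
    # restore original storage order so ids line up with input
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return PatchPattern(
        window,
        placed.x[: placed.n][inv],
        placed.y[: placed.n][inv],
        cohort.diameter.copy(),
        cohort.ids.copy(),
        cohort.label,
    )
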