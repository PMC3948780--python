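"""Disc-shaped vegetation patches and the geometric primitives of the analysis.

A *patch* is the planar footprint of one shrub canopy (or of several merged
canopies), reduced to an equivalent-circle disc: the centroid of the mapped
vegetated area together with the diameter of the circle of equal area.  All
higher-level statistics in this package (grid densities, pair correlation
functions, null models) operate on collections of such discs inside a
rectangular study window, with distances measured in meters.

Patches are grouped into five diameter-defined *cohorts*, interpreted as age
classes of the shrub population:

========  =======================  ====================
label     stage                    diameter interval (m)
========  =======================  ====================
``UI``    unbranched individuals   (0, 0.25)
``J_B``   branched juveniles       [0.25, 0.50)
``A_S``   small adults             [0.50, 1.00)
``A_M``   medium adults            [1.00, 2.00)
``A_L``   large adults             [2.00, inf)
========  =======================  ====================

Boundaries are half-open ``[lower, upper)`` so that classification is total
on (0, inf); measured diameters landing exactly on a boundary are a
measure-zero event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "COHORT_BOUNDS",
    "RectWindow",
    "Patch",
    "PatchPattern",
    "classify_cohort",
    "classify_cohorts",
    "edge_distance",
    "pairwise_edge_distances",
    "cross_edge_distances",
    "is_isolated",
    "fractional_vegetation_cover",
    "validate_patterns",
]

#: Cohort labels ordered youngest -> oldest (increasing diameter class).
COHORTS: tuple[str, ...] = ("UI", "J_B", "A_S", "A_M", "A_L")

#: Upper diameter boundary (m) of each cohort except the open-ended last one.
COHORT_BOUNDS: tuple[float, ...] = (0.25, 0.50, 1.00, 2.00)


@dataclass(frozen=True)
class RectWindow:
    """Axis-aligned rectangular study window, coordinates in meters."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min},{self.x_max}]x[{self.y_min},{self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains_disc(self, x, y, radius) -> np.ndarray:
        """Whole-disc containment test, vectorized over centroids/radii."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        r = np.asarray(radius, float)
        return (
            (x - r >= self.x_min)
            & (x + r <= self.x_max)
            & (y - r >= self.y_min)
            & (y + r <= self.y_max)
        )


@dataclass(frozen=True)
class Patch:
    """A single disc-shaped vegetation patch."""

    x: float
    y: float
    diameter: float
    cohort: str | None = None
    id: int = -1

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"patch diameter must be > 0, got {self.diameter}")
        if self.cohort is not None and self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort label {self.cohort!r}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def area(self) -> float:
        return np.pi * self.radius**2


def classify_cohort(diameter: float) -> str:
    """Map an equivalent-circle diameter (m) to its cohort label.

    Half-open intervals ``[lower, upper)``; raises on non-positive input.
    """
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    idx = int(np.searchsorted(COHORT_BOUNDS, diameter, side="right"))
    return COHORTS[idx]


def classify_cohorts(diameters) -> np.ndarray:
    """Vectorized :func:`classify_cohort`."""
    d = np.asarray(diameters, float)
    if d.size and not np.all(d > 0):
        bad = np.flatnonzero(~(d > 0))[0]
        raise ValueError(f"diameter must be > 0, got {d[bad]} at index {bad}")
    idx = np.searchsorted(COHORT_BOUNDS, d, side="right")
    return np.asarray(COHORTS, object)[idx]


@dataclass
class PatchPattern:
    """All patches of one cohort (or an unclassified batch) inside a window.

    Internally columnar (numpy arrays) for the benefit of the estimators and
    simulators; :meth:`patches` gives row-wise :class:`Patch` objects.
    """

    window: RectWindow
    x: np.ndarray
    y: np.ndarray
    diameter: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, float))
        self.y = np.atleast_1d(np.asarray(self.y, float))
        self.diameter = np.atleast_1d(np.asarray(self.diameter, float))
        if self.ids is None:
            self.ids = np.arange(self.x.size)
        self.ids = np.atleast_1d(np.asarray(self.ids, int))
        n = self.x.size
        if not (self.y.size == n and self.diameter.size == n and self.ids.size == n):
            raise ValueError("x, y, diameter, ids must have equal length")
        if n and not np.all(self.diameter > 0):
            raise ValueError("all diameters must be > 0")

    @classmethod
    def empty(cls, window: RectWindow, label: str | None = None) -> "PatchPattern":
        return cls(window, np.empty(0), np.empty(0), np.empty(0), np.empty(0, int), label)

    @classmethod
    def from_patches(
        cls, window: RectWindow, patches: Iterable[Patch], label: str | None = None
    ) -> "PatchPattern":
        ps = list(patches)
        return cls(
            window,
            np.array([p.x for p in ps]),
            np.array([p.y for p in ps]),
            np.array([p.diameter for p in ps]),
            np.array([p.id if p.id >= 0 else i for i, p in enumerate(ps)], int),
            label,
        )

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def radius(self) -> np.ndarray:
        return self.diameter / 2.0

    @property
    def areas(self) -> np.ndarray:
        return np.pi * self.radius**2

    def patches(self) -> list[Patch]:
        return [
            Patch(self.x[i], self.y[i], self.diameter[i], self.label, int(self.ids[i]))
            for i in range(len(self))
        ]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "x": self.x, "y": self.y, "diameter": self.diameter}
        )
        if self.label is not None:
            df["cohort"] = self.label
        return df

    def validate(self, others: Sequence["PatchPattern"] = ()) -> None:
        """Check whole-disc containment and global (union) non-overlap.

        Raises ``ValueError`` naming the offending patches.
        """
        inside = self.window.contains_disc(self.x, self.y, self.radius)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)[0]
            raise ValueError(
                f"patch id {int(self.ids[bad])} (x={self.x[bad]:.3f}, y={self.y[bad]:.3f}, "
                f"diameter={self.diameter[bad]:.3f}) extends outside the window"
            )
        validate_patterns([self, *others])


def edge_distance(p1: Patch, p2: Patch) -> float:
    """Shortest distance between two disc boundaries (negative on overlap)."""
    # radii summed first so the result is exactly symmetric in its arguments
    return float(np.hypot(p1.x - p2.x, p1.y - p2.y) - (p1.radius + p2.radius))


def pairwise_edge_distances(pattern: PatchPattern) -> np.ndarray:
    """Condensed vector of edge distances over unordered pairs (i < j)."""
    n = len(pattern)
    if n < 2:
        return np.empty(0)
    i, j = np.triu_indices(n, k=1)
    d = np.hypot(pattern.x[i] - pattern.x[j], pattern.y[i] - pattern.y[j])
    return d - (pattern.radius[i] + pattern.radius[j])


def cross_edge_distances(a: PatchPattern, b: PatchPattern) -> np.ndarray:
    """(n_a, n_b) matrix of edge distances between two patterns."""
    dx = a.x[:, None] - b.x[None, :]
    dy = a.y[:, None] - b.y[None, :]
    return np.hypot(dx, dy) - a.radius[:, None] - b.radius[None, :]


def is_isolated(p: Patch, all_patches: Sequence[Patch]) -> bool:
    """True iff ``p``'s canopy touches no other canopy (edge distance > 0).

    ``p`` must be a member of ``all_patches`` (matched by id when set,
    else by coordinates).
    """
    found = False
    isolated = True
    for q in all_patches:
        same = (q.id == p.id and p.id >= 0) or (
            q.x == p.x and q.y == p.y and q.diameter == p.diameter
        )
        if same and not found:
            found = True
            continue
        if edge_distance(p, q) <= 0:
            isolated = False
    if not found:
        raise ValueError("patch is not a member of the supplied collection")
    return isolated


def isolated_mask(patterns: Sequence[PatchPattern]) -> list[np.ndarray]:
    """Per-pattern boolean mask of patches isolated within the union."""
    x = np.concatenate([p.x for p in patterns]) if patterns else np.empty(0)
    y = np.concatenate([p.y for p in patterns]) if patterns else np.empty(0)
    r = np.concatenate([p.radius for p in patterns]) if patterns else np.empty(0)
    n = x.size
    iso = np.ones(n, bool)
    if n > 1:
        # O(N^2) in vectorized chunks; N is at most a few thousand here.
        for start in range(0, n, 512):
            sl = slice(start, min(start + 512, n))
            d = np.hypot(x[sl, None] - x[None, :], y[sl, None] - y[None, :])
            ed = d - r[sl, None] - r[None, :]
            rows = np.arange(start, sl.stop)
            ed[np.arange(rows.size), rows] = np.inf  # self
            iso[sl] = ed.min(axis=1) > 0
    out = []
    off = 0
    for p in patterns:
        out.append(iso[off : off + len(p)])
        off += len(p)
    return out


def fractional_vegetation_cover(
    patterns: Sequence[PatchPattern] | PatchPattern, window: RectWindow
) -> float:
    """Fraction of the window covered by (disjoint) patch discs."""
    if isinstance(patterns, PatchPattern):
        patterns = [patterns]
    total = 0.0
    for p in patterns:
        if len(p) and not np.all(window.contains_disc(p.x, p.y, p.radius)):
            raise ValueError("pattern contains a patch outside the window")
        total += float(p.areas.sum())
    return total / window.area


def validate_patterns(patterns: Sequence[PatchPattern]) -> None:
    """Assert no two discs in the union of all patterns overlap."""
    x = np.concatenate([p.x for p in patterns]) if patterns else np.empty(0)
    y = np.concatenate([p.y for p in patterns]) if patterns else np.empty(0)
    r = np.concatenate([p.radius for p in patterns]) if patterns else np.empty(0)
    n = x.size
    if n < 2:
        return
    for start in range(0, n, 512):
        sl = slice(start, min(start + 512, n))
        d = np.hypot(x[sl, None] - x[None, :], y[sl, None] - y[None, :])
        ed = d - r[sl, None] - r[None, :]
        rows = np.arange(start, sl.stop)
        ed[np.arange(rows.size), rows] = np.inf
        if ed.min() < 0:
            a = int(np.argmin(ed.min(axis=1))) + start
            raise ValueError(f"overlapping discs detected (patch index {a} in union)")
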