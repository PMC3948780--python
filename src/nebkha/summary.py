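"""Second-order summary statistics on patch-edge distances.

The pair correlation function (PCF) g(r) describes, relative to complete
spatial randomness, how likely it is to find two objects of a pattern a
distance r apart; g = 1 under randomness, > 1 indicates clustering and < 1
regularity at that distance.  The cross-type variant (PCCF) g12(r) uses only
pairs drawn from two different patterns and detects attraction or repulsion
between them.

Because the objects here are canopy discs of widely varying diameter, the
abscissa is the *patch-edge distance* — the shortest distance between the
two disc boundaries (centroid distance minus both radii) — rather than the
centroid distance.  This removes the spurious regularity that finite patch
size otherwise imprints on small-scale statistics of non-overlapping
patterns.  The estimator keeps the classical normalization

    ghat(r) = A / (2 pi r N(N-1)) * sum_{i != j} k_h(r - d_ij^edge) e_ij

with an Epanechnikov kernel k_h of half-width h and translation
edge-correction weights e_ij computed from centroid displacements; any
residual first-order bias cancels in comparison with the Monte Carlo null
envelopes built from the same estimator.

Kernel sums are evaluated with prefix sums over the sorted pair distances,
which makes a single evaluation O(P log P + G) for P pairs and G grid
points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PatchPattern

__all__ = [
    "SummaryFunction",
    "default_r_grid",
    "stoyan_bandwidth",
    "pcf_edge",
    "pccf_edge",
    "pcf_histogram_oracle",
]


@dataclass
class SummaryFunction:
    """A PCF or PCCF estimate on a distance grid.

    ``reliable`` marks grid points at least one bandwidth away from the
    r = 0 singularity; values below that are reported but should not be
    interpreted (they are excluded from envelope interval detection).
    """

    r: np.ndarray
    values: np.ndarray
    kind: str  # "pcf" | "pccf"
    bandwidth: float
    n_points: int | tuple[int, int]
    edge_correction: str = "translation"
    kernel: str = "epanechnikov"
    reliable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.values = np.asarray(self.values, float)
        if self.reliable is None:
            self.reliable = (self.r >= self.bandwidth) & (self.r > 0)
        if not np.all(np.diff(self.r) > 0):
            raise ValueError("r grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "value": self.values})

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV plus a JSON sidecar holding the parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "kind": self.kind,
            "bandwidth": self.bandwidth,
            "n_points": self.n_points
            if isinstance(self.n_points, int)
            else list(self.n_points),
            "edge_correction": self.edge_correction,
            "kernel": self.kernel,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def default_r_grid(pattern: PatchPattern, n: int = 512) -> np.ndarray:
    """``n`` points from 0 to one quarter of the shorter window side."""
    w = pattern.window
    return np.linspace(0.0, min(w.width, w.height) / 4.0, n)


def stoyan_bandwidth(intensity: float) -> float:
    """Stoyan rule-of-thumb kernel half-width h = 0.15 / sqrt(intensity)."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    return 0.15 / np.sqrt(intensity)


def _kernel_sums(d, w, r, h, kernel):
    """sum_i w_i k_h(r - d_i) for each r, via prefix sums on sorted d."""
    order = np.argsort(d, kind="stable")
    d = d[order]
    w = w[order]
    s0 = np.concatenate([[0.0], np.cumsum(w)])
    lo = np.searchsorted(d, r - h, side="left")
    hi = np.searchsorted(d, r + h, side="left")
    a0 = s0[hi] - s0[lo]
    if kernel == "box":
        return 0.5 / h * a0
    if kernel == "epanechnikov":
        s1 = np.concatenate([[0.0], np.cumsum(w * d)])
        s2 = np.concatenate([[0.0], np.cumsum(w * d * d)])
        a1 = s1[hi] - s1[lo]
        a2 = s2[hi] - s2[lo]
        quad = r * r * a0 - 2.0 * r * a1 + a2
        return 0.75 / h * (a0 - quad / (h * h))
    raise ValueError(f"unknown kernel {kernel!r}")


def _translation_weights(dx, dy, window):
    wx = window.width - np.abs(dx)
    wy = window.height - np.abs(dy)
    return window.area / (wx * wy)


def pcf_edge(
    pattern: PatchPattern,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    edge_correction: str = "translation",
    kernel: str = "epanechnikov",
) -> SummaryFunction:
    """Edge-distance pair correlation function of one pattern.

    Under complete spatial randomness of vanishing-diameter discs the
    expectation is ~1 on the whole grid.  Requires at least two patches.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError("PCF needs at least 2 patches")
    if r_grid is None:
        r_grid = default_r_grid(pattern)
    r_grid = np.asarray(r_grid, float)
    window = pattern.window
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(n / window.area)
    i, j = np.triu_indices(n, k=1)
    dx = pattern.x[i] - pattern.x[j]
    dy = pattern.y[i] - pattern.y[j]
    d = np.hypot(dx, dy) - pattern.radius[i] - pattern.radius[j]
    if edge_correction == "translation":
        w = _translation_weights(dx, dy, window)
    elif edge_correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    sums = _kernel_sums(d, 2.0 * w, r_grid, bandwidth, kernel)  # ordered pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        values = window.area / (2.0 * np.pi * r_grid * n * (n - 1)) * sums
    values[r_grid <= 0] = np.nan
    return SummaryFunction(
        r_grid, values, "pcf", bandwidth, n, edge_correction, kernel
    )


def pccf_edge(
    pattern_a: PatchPattern,
    pattern_b: PatchPattern,
    r_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    edge_correction: str = "translation",
    kernel: str = "epanechnikov",
) -> SummaryFunction:
    """Edge-distance pair cross-correlation function between two patterns.

    Uses only inter-pattern edge distances; ~1 when the patterns are
    independent.  Symmetric in its two pattern arguments.
    """
    na, nb = len(pattern_a), len(pattern_b)
    if na < 1 or nb < 1:
        raise ValueError("PCCF needs at least one patch in each pattern")
    window = pattern_a.window
    if r_grid is None:
        r_grid = default_r_grid(pattern_a)
    r_grid = np.asarray(r_grid, float)
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(np.sqrt(na * nb) / window.area)
    dx = (pattern_a.x[:, None] - pattern_b.x[None, :]).ravel()
    dy = (pattern_a.y[:, None] - pattern_b.y[None, :]).ravel()
    d = np.hypot(dx, dy) - (
        pattern_a.radius[:, None] + pattern_b.radius[None, :]
    ).ravel()
    if edge_correction == "translation":
        w = _translation_weights(dx, dy, window)
    elif edge_correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    sums = _kernel_sums(d, w, r_grid, bandwidth, kernel)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = window.area / (2.0 * np.pi * r_grid * na * nb) * sums
    values[r_grid <= 0] = np.nan
    return SummaryFunction(
        r_grid, values, "pccf", bandwidth, (na, nb), edge_correction, kernel
    )


def pcf_histogram_oracle(
    pattern: PatchPattern,
    bin_edges: np.ndarray,
    edge_correction: str = "translation",
) -> SummaryFunction:
    """Un-smoothed binned PCF estimate (brute-force reference).

    Each unordered pair's edge distance is assigned to the half-open bin
    ``[edge_k, edge_{k+1})``; the kernel estimator with a box kernel of
    half-width equal to half the bin width, evaluated at bin centers,
    coincides with this estimate exactly.
    """
    n = len(pattern)
    if n < 2:
        raise ValueError("PCF needs at least 2 patches")
    bin_edges = np.asarray(bin_edges, float)
    window = pattern.window
    i, j = np.triu_indices(n, k=1)
    dx = pattern.x[i] - pattern.x[j]
    dy = pattern.y[i] - pattern.y[j]
    d = np.hypot(dx, dy) - pattern.radius[i] - pattern.radius[j]
    if edge_correction == "translation":
        w = _translation_weights(dx, dy, window)
    elif edge_correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    idx = np.searchsorted(bin_edges, d, side="right") - 1
    keep = (idx >= 0) & (idx < bin_edges.size - 1) & (d >= bin_edges[0])
    sums = np.zeros(bin_edges.size - 1)
    np.add.at(sums, idx[keep], 2.0 * w[keep])
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    widths = np.diff(bin_edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = window.area / (2.0 * np.pi * centers * n * (n - 1)) * sums / widths
    values[centers <= 0] = np.nan
    return SummaryFunction(
        centers,
        values,
        "pcf",
        float(widths.mean()) / 2.0,
        n,
        edge_correction,
        "histogram",
        reliable=centers > 0,
    )
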