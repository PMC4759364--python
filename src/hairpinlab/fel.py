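"""Autocorrelation and free-energy landscapes over (RMSD, R_g).

The landscape is the Boltzmann inversion of the sampled 2D histogram:
Delta G(x, y) = -k_B T ln(P(x, y) / P_max), so the most-populated bin sits
at Delta G = 0 and every other bin is positive.  Basins are connected
components of sub-threshold bins; the component containing the global
minimum is "the vicinity of the global minimum" (1.5 kJ/mol) or "around the
bottom" (2.5 kJ/mol), and its outer bin edges give the reported RMSD and
R_g ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "KB_KJ_PER_MOL_K",
    "ACFResult",
    "FELMap",
    "Basin",
    "autocorrelation",
    "free_energy_map",
    "basin_extract",
    "local_minima",
    "overlay_trajectory",
]

# Molar gas constant in kJ/(mol K): Boltzmann constant on a per-mole basis.
KB_KJ_PER_MOL_K = 0.0083145

DEFAULT_BIN_WIDTH_NM = 0.02


@dataclass(frozen=True)
class ACFResult:
    """Autocorrelation of a scalar time series.

    ``raw``:  C(j) = (1/(N-j)) * sum_{i=0}^{N-1-j} f_i f_{i+j}
    ``mean-subtracted-normalized``: the same on f - <f>, divided by C(0).
    """

    lags: np.ndarray     # ps (multiples of the frame interval)
    values: np.ndarray
    variant: str


def autocorrelation(
    series: np.ndarray,
    max_lag: int | None = None,
    variant: str = "mean-subtracted-normalized",
    frame_interval: float = 1.0,
) -> ACFResult:
    """Autocorrelation of a time series up to ``max_lag`` frames.

    The raw variant averages the lagged product without mean subtraction or
    normalization; for a fluctuating order parameter it decays toward the
    squared mean rather than zero.  The normalized variant subtracts the
    mean first and scales to C(0) = 1.
    """
    f = np.asarray(series, dtype=float)
    n = f.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag < n:
        raise ValueError(f"max_lag must be in [0, {n - 1}], got {max_lag}")
    if variant not in ("raw", "mean-subtracted-normalized"):
        raise ValueError(f"unknown variant {variant!r}")

    g = f if variant == "raw" else f - f.mean()
    # Full lagged-product sums in one FFT-free pass (series are short enough).
    values = np.array([
        np.dot(g[: n - j], g[j:]) / (n - j) for j in range(max_lag + 1)
    ])
    if variant == "mean-subtracted-normalized":
        c0 = values[0]
        values = values / c0 if c0 > 0 else np.zeros_like(values)
    lags = np.arange(max_lag + 1) * frame_interval
    return ACFResult(lags=lags, values=values, variant=variant)


@dataclass(frozen=True)
class FELMap:
    """Binned free-energy surface over two reaction coordinates."""

    x_edges: np.ndarray     # nm
    y_edges: np.ndarray     # nm
    counts: np.ndarray      # (nx, ny) occupancy
    delta_g: np.ma.MaskedArray  # kJ/mol; masked where counts == 0
    temperature: float      # K

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def minimum_bin(self) -> tuple[int, int]:
        """Indices of the global-minimum (most populated) bin."""
        return tuple(np.unravel_index(np.argmax(self.counts), self.counts.shape))


def free_energy_map(
    x_series: np.ndarray,
    y_series: np.ndarray,
    bins: int | tuple[int, int] | tuple[np.ndarray, np.ndarray] | None = None,
    temperature: float = 300.0,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
) -> FELMap:
    """Boltzmann-inverted 2D histogram of two reaction-coordinate series.

    Delta G = -k_B T ln(P / P_max) with the most-populated bin at zero.
    If ``bins`` is omitted, both axes are binned at ``bin_width`` over the
    data range padded by one bin on each side.  Empty bins carry a masked
    (undefined) Delta G, not a capped value.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("series must be equal-length and non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    if bins is None:
        def edges(v: np.ndarray) -> np.ndarray:
            lo = np.floor(v.min() / bin_width) * bin_width - bin_width
            hi = np.ceil(v.max() / bin_width) * bin_width + bin_width
            n = max(2, int(round((hi - lo) / bin_width)))
            return lo + bin_width * np.arange(n + 1)

        bins = (edges(x), edges(y))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    if x_edges.size < 3 or y_edges.size < 3:
        raise ValueError("need at least 2 bins per axis")
    if x_edges[0] == x_edges[-1] or y_edges[0] == y_edges[-1]:
        raise ValueError("zero-width axis range")

    p_max = counts.max()
    if p_max == 0:
        raise ValueError("no samples fell inside the bin range")
    with np.errstate(divide="ignore"):
        dg = -KB_KJ_PER_MOL_K * temperature * np.log(counts / p_max)
    delta_g = np.ma.masked_array(dg, mask=(counts == 0))
    return FELMap(x_edges=x_edges, y_edges=y_edges, counts=counts,
                  delta_g=delta_g, temperature=temperature)


@dataclass(frozen=True)
class Basin:
    """One connected sub-threshold region of a free-energy landscape."""

    member_bins: frozenset[tuple[int, int]]
    threshold: float          # kJ/mol
    min_delta_g: float        # kJ/mol, lowest Delta G inside
    rmsd_range: tuple[float, float]  # nm, outer bin edges along x
    rg_range: tuple[float, float]    # nm, outer bin edges along y

    @property
    def rmsd_width(self) -> float:
        return self.rmsd_range[1] - self.rmsd_range[0]

    @property
    def rg_width(self) -> float:
        return self.rg_range[1] - self.rg_range[0]


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def _components(fel: FELMap, threshold: float) -> tuple[np.ndarray, int]:
    below = (~fel.delta_g.mask) & (fel.delta_g.filled(np.inf) <= threshold)
    return ndimage.label(below, structure=_EIGHT_CONNECTED)


def _basin_from_labels(fel: FELMap, labels: np.ndarray, which: int,
                       threshold: float) -> Basin:
    members = np.argwhere(labels == which)
    xs, ys = members[:, 0], members[:, 1]
    return Basin(
        member_bins=frozenset((int(i), int(j)) for i, j in members),
        threshold=threshold,
        min_delta_g=float(fel.delta_g[xs, ys].min()),
        rmsd_range=(float(fel.x_edges[xs.min()]), float(fel.x_edges[xs.max() + 1])),
        rg_range=(float(fel.y_edges[ys.min()]), float(fel.y_edges[ys.max() + 1])),
    )


def basin_extract(fel: FELMap, threshold: float) -> Basin:
    """The sub-threshold region around the global minimum.

    8-connected component of bins with Delta G <= threshold that contains
    the global-minimum bin; its outer bin edges give the reported RMSD and
    R_g ranges.
    """
    labels, _ = _components(fel, threshold)
    gmin = fel.minimum_bin
    which = labels[gmin]
    if which == 0:
        raise ValueError("global minimum not below threshold (threshold < 0?)")
    return _basin_from_labels(fel, labels, which, threshold)


def local_minima(fel: FELMap, threshold: float) -> list[Basin]:
    """All maximal sub-threshold components, sorted by their minimum Delta G."""
    labels, n = _components(fel, threshold)
    basins = [_basin_from_labels(fel, labels, k, threshold) for k in range(1, n + 1)]
    return sorted(basins, key=lambda b: b.min_delta_g)


def overlay_trajectory(
    fel: FELMap,
    x_series: np.ndarray,
    y_series: np.ndarray,
    basin: Basin | None = None,
) -> tuple[np.ndarray, float, int]:
    """Map an independent trajectory onto an existing landscape.

    Returns a boolean per-bin visitation mask, the fraction of in-range
    samples falling inside ``basin`` (or inside any defined bin when no
    basin is given), and the number of out-of-range samples.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    ix = np.digitize(x, fel.x_edges) - 1
    iy = np.digitize(y, fel.y_edges) - 1
    nx, ny = fel.counts.shape
    in_range = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    n_out = int((~in_range).sum())

    visited = np.zeros_like(fel.counts, dtype=bool)
    visited[ix[in_range], iy[in_range]] = True

    if x.size == n_out:
        return visited, 0.0, n_out
    if basin is None:
        target = ~fel.delta_g.mask
    else:
        target = np.zeros_like(visited)
        for i, j in basin.member_bins:
            target[i, j] = True
    inside = target[ix[in_range], iy[in_range]]
    return visited, float(inside.mean()), n_out
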