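"""Pairwise dependence measures between two time series.

Three edge-definition measures for functional connectivity graphs:

``lc``
    Linear (Pearson) correlation — the ubiquitous linear measure.
``mi``
    Mutual information in bits, estimated from an equal-width joint
    histogram of the two series.
``bcfd``
    Box-counting fractal dimension of the *pair image*: the two series
    are plotted one against the other on an M x M amplitude grid, the
    occupancy of each cell becomes a gray level, and the fractal
    dimension of the resulting gray-level surface (differential box
    counting) or of the occupied point set (binary box counting) is
    estimated by a least-squares log-log fit of box counts against
    scale.

All measures are symmetric in their arguments and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIN_SERIES_LENGTH",
    "pearson_correlation",
    "JointHistogram",
    "joint_histogram",
    "mutual_information",
    "mutual_information_from_counts",
    "PairImage",
    "build_pair_image",
    "dbc_box_count",
    "binary_box_count",
    "BoxCountTable",
    "default_scales",
    "box_count_table",
    "FractalFit",
    "fit_fractal_dimension",
    "bcfd",
    "MEASURES",
    "get_measure",
]

#: shortest series for which any measure is defined
MIN_SERIES_LENGTH = 4


def _as_series(x, name: str = "series") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < MIN_SERIES_LENGTH:
        raise ValueError(
            f"{name} must have at least {MIN_SERIES_LENGTH} samples, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: x has {xa.size} samples, y has {ya.size}")
    return xa, ya


# ---------------------------------------------------------------------------
# Linear correlation
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient r of two equal-length series.

    Raises
    ------
    ValueError
        If the lengths differ or either series is constant (zero
        variance makes r undefined).
    """
    xa, ya = _check_pair(x, y)
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0:
        raise ValueError("x has zero variance; correlation is undefined")
    if ssy == 0.0:
        raise ValueError("y has zero variance; correlation is undefined")
    r = float(dx @ dy) / np.sqrt(ssx * ssy)
    # guard against rounding outside [-1, 1]
    return float(min(1.0, max(-1.0, r)))


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointHistogram:
    """Two-dimensional occupancy histogram of a pair of series.

    ``counts[i, j]`` is the number of samples falling in the i-th
    amplitude bin of x and the j-th bin of y.  Bins are equal-width
    over each series' [min, max] range with the last bin right-closed.
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def joint_p(self) -> np.ndarray:
        return self.counts / self.total

    @property
    def marginal_x(self) -> np.ndarray:
        return self.joint_p.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.joint_p.sum(axis=0)


def joint_histogram(x, y, n_bins_x: int, n_bins_y: int) -> JointHistogram:
    """Equal-width 2-D histogram spanning each series' own range."""
    xa, ya = _check_pair(x, y)
    if n_bins_x < 2 or n_bins_y < 2:
        raise ValueError("need at least 2 bins on each axis")

    def _range(a, name):
        lo, hi = float(a.min()), float(a.max())
        if lo == hi:
            warnings.warn(
                f"{name} is constant; all mass falls in a single bin",
                stacklevel=3,
            )
            lo, hi = lo - 0.5, hi + 0.5
        return lo, hi

    counts, xe, ye = np.histogram2d(
        xa, ya, bins=[n_bins_x, n_bins_y], range=[_range(xa, "x"), _range(ya, "y")]
    )
    return JointHistogram(counts.astype(np.int64), xe, ye)


def mutual_information_from_counts(counts) -> float:
    """Mutual information in bits of a joint count table.

    Cells with zero probability contribute nothing (0 log 0 := 0).
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty joint histogram")
    p = c / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    return max(0.0, mi)


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Histogram mutual information I(X, Y) in bits.

    ``n_bins`` applies to both axes; the default is ceil(sqrt(N)),
    a common histogram-MI rule when nothing is known about the data.
    """
    xa, ya = _check_pair(x, y)
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(xa.size)))
    h = joint_histogram(xa, ya, n_bins, n_bins)
    return mutual_information_from_counts(h.counts)


# ---------------------------------------------------------------------------
# Pair image and box counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairImage:
    """M x M gray-level image built from one pair of time series.

    ``counts`` holds the raw occupancy of each amplitude cell (how many
    time points fell there); ``grid`` holds the gray level in [1..G]
    obtained by affine rescaling of the counts, with empty cells mapped
    to gray level 1.  The grid is the substrate of differential box
    counting; the occupancy is the substrate of the binary variant.
    """

    grid: np.ndarray
    counts: np.ndarray
    m: int
    g: int

    def __post_init__(self):
        if self.m < 4:
            raise ValueError(f"image side M must be >= 4, got {self.m}")
        if not (2 <= self.g <= self.m):
            raise ValueError(f"gray levels G must satisfy 2 <= G <= M, got G={self.g}")
        if self.grid.shape != (self.m, self.m):
            raise ValueError("grid shape does not match M")
        if self.grid.min() < 1 or self.grid.max() > self.g:
            raise ValueError("gray levels must lie in [1..G]")


def build_pair_image(x, y, m: int | None = None, g: int = 64) -> PairImage:
    """Rasterize the joint phase portrait of (x, y) into a gray image.

    Cell (i, j) covers the i-th amplitude bin of x and the j-th of y
    (equal-width over each series' min-max range).  The gray level is
    the cell's point count rescaled to integers in [1..G].

    ``m`` defaults to the series length; ``g`` defaults to 64.
    """
    xa, ya = _check_pair(x, y)
    if float(np.ptp(xa)) == 0.0:
        raise ValueError("x is constant; the pair image collapses to a line")
    if float(np.ptp(ya)) == 0.0:
        raise ValueError("y is constant; the pair image collapses to a line")
    if m is None:
        m = xa.size
    g = int(g)
    m = int(m)
    if m < 4:
        raise ValueError(f"image side M must be >= 4, got {m}")
    if not (2 <= g <= m):
        raise ValueError(f"gray levels G must satisfy 2 <= G <= M, got G={g}")
    # equal-width min-max binning; the top edge closes the last bin
    ix = np.minimum((m * (xa - xa.min()) / np.ptp(xa)).astype(np.int64), m - 1)
    iy = np.minimum((m * (ya - ya.min()) / np.ptp(ya)).astype(np.int64), m - 1)
    counts = np.bincount(ix * m + iy, minlength=m * m).reshape(m, m)
    cmax = counts.max()
    grid = 1 + np.rint((g - 1) * counts / cmax).astype(np.int64)
    return PairImage(grid=grid, counts=counts, m=m, g=g)


def _check_scale(m: int, s: int) -> None:
    if not (1 < s <= m / 2):
        raise ValueError(f"scale s must satisfy 1 < s <= M/2 (M={m}), got s={s}")


def _block_reduce(a: np.ndarray, s: int, pad_value, op) -> np.ndarray:
    """Reduce an image over an s x s block partition, padding partial
    edge blocks with a neutral value so only real pixels count."""
    m = a.shape[0]
    b = -(-m // s)  # ceil
    if b * s != m:
        padded = np.full((b * s, b * s), pad_value, dtype=a.dtype)
        padded[:m, :m] = a
        a = padded
    return op(a.reshape(b, s, b, s), axis=(1, 3))


def dbc_box_count(img: PairImage, s: int) -> int:
    """Differential box count N_r at scale s.

    The image plane is partitioned into s x s blocks (partial edge
    blocks included).  Boxes stacked over each block have gray-level
    height s' = ceil(s * G / M), so that the number of boxes per column
    matches the number of blocks per side.  A block whose gray levels
    span [g_min, g_max] is covered by n = l - k + 1 boxes where
    k = ceil(g_min / s') and l = ceil(g_max / s'); N_r sums n over all
    blocks.
    """
    _check_scale(img.m, s)
    s = int(s)
    sp = max(1, -(-s * img.g // img.m))  # ceil(s*G/M)
    gmax = _block_reduce(img.grid, s, 0, np.max)
    gmin = _block_reduce(img.grid, s, img.g + 1, np.min)
    k = -(-gmin // sp)
    l = -(-gmax // sp)
    return int((l - k + 1).sum())


def binary_box_count(img: PairImage, s: int) -> int:
    """Number of s x s blocks containing at least one occupied cell."""
    _check_scale(img.m, s)
    occupied = img.counts > 0
    any_block = _block_reduce(occupied, int(s), False, np.max)
    return int(any_block.sum())


@dataclass(frozen=True)
class BoxCountTable:
    """Box counts N_r over a set of scales s, with r = s / M."""

    scales: np.ndarray
    r: np.ndarray
    n_boxes: np.ndarray

    def __post_init__(self):
        if len(self.scales) != len(self.n_boxes):
            raise ValueError("scales and counts must align")


def default_scales(m: int) -> np.ndarray:
    """Powers of two in (1, M/2] — the default scale ladder."""
    scales = []
    s = 2
    while s <= m / 2:
        scales.append(s)
        s *= 2
    if not scales:
        raise ValueError(f"image side {m} admits no valid scale")
    return np.asarray(scales, dtype=int)


def _is_doubling_ladder(scales: np.ndarray) -> bool:
    return scales[0] == 2 and np.all(scales[1:] == 2 * scales[:-1])


def _pad_even(a: np.ndarray, pad_value):
    b = a.shape[0]
    if b % 2 == 0:
        return a
    padded = np.full((b + 1, b + 1), pad_value, dtype=a.dtype)
    padded[:b, :b] = a
    return padded


def _pyramid_counts(img: PairImage, scales: np.ndarray, variant: str) -> np.ndarray:
    """Box counts over a doubling scale ladder via a min/max pyramid.

    Each level's per-block extrema are reduced from the previous
    level's, which matches the direct per-scale computation exactly
    because ceil-partitioned blocks at scale 2s are unions of the
    (padded) blocks at scale s.
    """
    def _halve(a, pad_value, op):
        a = _pad_even(a, pad_value)
        return op(
            op(a[0::2, 0::2], a[0::2, 1::2]), op(a[1::2, 0::2], a[1::2, 1::2])
        )

    out = np.empty(len(scales), dtype=np.int64)
    if variant == "binary":
        cur = img.counts > 0
        for i, s in enumerate(scales):
            cur = _halve(cur, False, np.logical_or)
            out[i] = int(cur.sum())
        return out
    big = img.g + 1
    cur_max = img.grid.astype(np.int32)
    cur_min = cur_max
    for i, s in enumerate(scales):
        cur_max = _halve(cur_max, 0, np.maximum)
        cur_min = _halve(cur_min, big, np.minimum)
        sp = max(1, -(-int(s) * img.g // img.m))
        k = -(-cur_min // sp)
        l = -(-cur_max // sp)
        out[i] = int((l - k + 1).sum())
    return out


def box_count_table(
    img: PairImage, scales=None, variant: str = "dbc"
) -> BoxCountTable:
    """Count boxes at every scale with the chosen counting variant."""
    if variant not in ("dbc", "binary"):
        raise ValueError(f"unknown box-counting variant {variant!r}")
    if scales is None:
        scales = default_scales(img.m)
    scales = np.asarray(scales, dtype=int)
    for s in scales:
        _check_scale(img.m, int(s))
    if len(scales) and _is_doubling_ladder(scales):
        n = _pyramid_counts(img, scales, variant)
    else:
        counter = dbc_box_count if variant == "dbc" else binary_box_count
        n = np.asarray([counter(img, int(s)) for s in scales], dtype=np.int64)
    return BoxCountTable(scales=scales, r=scales / img.m, n_boxes=n)


@dataclass(frozen=True)
class FractalFit:
    """Least-squares fit of log N_r against log(1/r)."""

    dimension: float
    intercept: float
    residuals: np.ndarray = field(repr=False)


def fit_fractal_dimension(table: BoxCountTable) -> FractalFit:
    """Estimate D as the OLS slope of log N_r versus log(1/r)."""
    if len(np.unique(table.scales)) < 2:
        raise ValueError("at least 2 distinct scales are required for the fit")
    if np.any(table.n_boxes <= 0):
        raise ValueError("box counts must be positive for the log-log fit")
    xs = np.log(1.0 / table.r)
    ys = np.log(table.n_boxes.astype(float))
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    return FractalFit(dimension=float(slope), intercept=float(intercept), residuals=resid)


def bcfd(
    x,
    y,
    m: int | None = None,
    g: int = 64,
    scales=None,
    variant: str = "dbc",
) -> float:
    """Box-counting fractal dimension of the pair image of (x, y).

    ``variant="dbc"`` (default) applies differential box counting to
    the gray-level surface (dimension in [2, 3] on ideal surfaces);
    ``variant="binary"`` counts blocks containing any occupied cell
    (dimension in [0, 2] for point sets).
    """
    img = build_pair_image(x, y, m=m, g=g)
    table = box_count_table(img, scales=scales, variant=variant)
    return fit_fractal_dimension(table).dimension


# ---------------------------------------------------------------------------
# Measure registry
# ---------------------------------------------------------------------------

def _lc(x, y, **params):
    return pearson_correlation(x, y)


def _mi(x, y, n_bins=None, **params):
    return mutual_information(x, y, n_bins=n_bins)


def _bcfd(x, y, m=None, g=64, scales=None, variant="dbc", **params):
    return bcfd(x, y, m=m, g=g, scales=scales, variant=variant)


MEASURES = {"lc": _lc, "mi": _mi, "bcfd": _bcfd}


def get_measure(name: str, **params):
    """Return a two-argument callable for a measure addressed by name."""
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; choose from {sorted(MEASURES)}"
        ) from None
    if params:
        return lambda x, y: fn(x, y, **params)
    return fn
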