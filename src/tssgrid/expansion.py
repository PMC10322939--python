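"""Multi-landmark coordinate expansion and rectangular region averages.

A genomic position ``z`` near an oriented landmark pair (upstream ``z_U``,
downstream ``z_D``) maps to relative coordinates ``x = z − z_U`` and
``y = z − z_D``, so each pair contributes signal along the line
``y = x − d`` where ``d`` is the oriented pair distance.  Averaging the
expanded signal over a rectangle ``[(x0,y0),(x1,y1)]`` across a set of
pairs gives the region average

    R_V = (1/N) Σ_pairs Σ_{x=max(x0, y0+d)}^{min(x1, y1+d)} g(x + z_U),

with N the total number of contributing (pair, base) terms.  The double
sum with the Kronecker constraint collapses to a single x-interval per
pair, which is what makes genome-scale 2D sweeps cheap; the literal
double-sum twin :func:`region_average_bruteforce` exists as the testing
oracle.  Signal densities G(x,y) evaluate R_V in moving rectangular
windows whose half-widths grow with distance from the landmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import LandmarkPair

#: Relative-coordinate analysis domain: x in [-500, 20000], y in [-20000, 1000].
ANALYSIS_DOMAIN = {"x": (-500, 20_000), "y": (-20_000, 1_000)}


@dataclass(frozen=True)
class RegionSpec:
    """Inclusive rectangle [(x0,y0),(x1,y1)] in relative-coordinate space."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str = ""

    def __post_init__(self):
        if self.x0 > self.x1 or self.y0 > self.y1:
            raise ValueError(f"invalid region {self.label!r}: need x0<=x1 and y0<=y1")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0 + 1) * (self.y1 - self.y0 + 1)


@dataclass(frozen=True)
class RegionAverage:
    """Mean signal over a region across a pair set; undefined when no
    (pair, base) term falls inside the region (count 0)."""

    value: float
    count: int
    defined: bool

    @staticmethod
    def undefined() -> "RegionAverage":
        return RegionAverage(float("nan"), 0, False)


def _pair_interval(region: RegionSpec, distance: int) -> tuple[int, int]:
    """The x-interval a pair at oriented distance d contributes to a region."""
    lo = max(region.x0, region.y0 + distance)
    hi = min(region.x1, region.y1 + distance)
    return lo, hi


def align_1d(signal, anchors: Sequence[tuple[str, str, int]], x_lo: int, x_hi: int) -> np.ndarray:
    """Classic 1D metagene: mean oriented signal over anchors at offsets
    ``x_lo..x_hi`` inclusive.  ``anchors`` are (chrom, strand, position)."""
    if len(anchors) == 0:
        raise ValueError("align_1d requires at least one anchor")
    acc = np.zeros(x_hi - x_lo + 1)
    for chrom, strand, pos in anchors:
        acc += signal.oriented_slice(chrom, strand, pos, x_lo, x_hi)
    return acc / len(anchors)


def region_average(signal, pairs: Iterable[LandmarkPair], region: RegionSpec) -> RegionAverage:
    """Efficient R_V over a pair set: one contiguous signal slice per pair."""
    total = 0.0
    count = 0
    for p in pairs:
        lo, hi = _pair_interval(region, p.distance)
        if lo > hi:
            continue
        total += float(signal.oriented_slice(p.chrom, p.strand, p.z_U, lo, hi).sum())
        count += hi - lo + 1
    if count == 0:
        return RegionAverage.undefined()
    return RegionAverage(total / count, count, True)


def region_average_bruteforce(
    signal, pairs: Iterable[LandmarkPair], region: RegionSpec, max_area: int = 2_000_000
) -> RegionAverage:
    """Literal double sum over the rectangle with the Kronecker constraint
    y = x − d.  O(|pairs| · area); refuses large regions — this is the
    small-instance testing oracle, not the production path."""
    if region.area > max_area:
        raise ValueError(f"region area {region.area} exceeds oracle cap {max_area}")
    total = 0.0
    count = 0
    for p in pairs:
        d = p.distance
        for x in range(region.x0, region.x1 + 1):
            for y in range(region.y0, region.y1 + 1):
                if y == x - d:
                    total += signal.oriented_value(p.chrom, p.strand, p.z_U, x)
                    count += 1
    if count == 0:
        return RegionAverage.undefined()
    return RegionAverage(total / count, count, True)


def region_defined(pairs: Iterable[LandmarkPair], region: RegionSpec) -> bool:
    """Definedness condition: some pair satisfies y0−x1 ≤ −d ≤ y1−x0."""
    return any(
        region.y0 - region.x1 <= -p.distance <= region.y1 - region.x0 for p in pairs
    )


# -- adaptive windows and density grids --------------------------------------

def window_halfwidths(x: int, y: int) -> tuple[int, int]:
    """Moving-window half-widths (n_X, n_Y) at an evaluation point.

    n_X = 99 for −500 ≤ x ≤ 1000 and ⌊x/4⌋ for 1000 < x ≤ 20000;
    n_Y = 99 for −1000 ≤ y ≤ 1000 and ⌊−y/4⌋ for −20000 ≤ y < −1000.
    Points outside the analysis domain raise.
    """
    (x_lo, x_hi), (y_lo, y_hi) = ANALYSIS_DOMAIN["x"], ANALYSIS_DOMAIN["y"]
    if not (x_lo <= x <= x_hi) or not (y_lo <= y <= y_hi):
        raise ValueError(f"({x}, {y}) outside analysis domain x∈{ANALYSIS_DOMAIN['x']}, "
                         f"y∈{ANALYSIS_DOMAIN['y']}")
    n_x = 99 if x <= 1000 else x // 4
    n_y = 99 if y >= -1000 else (-y) // 4
    return n_x, n_y


def _axis_points(dense_lo: int, dense_hi: int, far: int, spacing: int, halfwidth) -> np.ndarray:
    """Dense evaluation points between dense_lo..dense_hi, then geometric
    thinning toward ``far`` with step = half-width/2."""
    pts = list(range(dense_lo, dense_hi + 1, spacing))
    step_sign = 1 if far > dense_hi else -1
    p = pts[-1] if step_sign == 1 else pts[0]
    out = pts if step_sign == 1 else pts[::-1]
    while (p < far) if step_sign == 1 else (p > far):
        p = p + step_sign * max(spacing, round(halfwidth(p) / 2))
        p = min(p, far) if step_sign == 1 else max(p, far)
        out.append(p)
    return np.array(sorted(out), dtype=int)


@dataclass
class GridConfig:
    """Evaluation points of a density grid (defaults resolve the 99 bp
    windows near the TSSs and thin out where windows widen)."""

    x_points: np.ndarray
    y_points: np.ndarray

    @classmethod
    def default(cls, spacing: int = 25) -> "GridConfig":
        x = _axis_points(-500, 1000, 20_000, spacing, lambda p: p // 4)
        y = _axis_points(-1000, 1000, -20_000, spacing, lambda p: (-p) // 4)
        return cls(x_points=x, y_points=y)

    @classmethod
    def rectangle(cls, x_lo, x_hi, y_lo, y_hi, spacing: int = 25) -> "GridConfig":
        return cls(
            x_points=np.arange(x_lo, x_hi + 1, spacing),
            y_points=np.arange(y_lo, y_hi + 1, spacing),
        )


@dataclass
class DensityGrid:
    """G(x,y) and N(x,y) on a grid; cells with no contributing terms are NaN."""

    x_points: np.ndarray
    y_points: np.ndarray
    halfwidth_x: np.ndarray
    halfwidth_y: np.ndarray
    values: np.ndarray  # shape (len(y_points), len(x_points))
    counts: np.ndarray

    def value_at(self, x: int, y: int) -> float:
        i = int(np.nonzero(self.x_points == x)[0][0])
        j = int(np.nonzero(self.y_points == y)[0][0])
        return float(self.values[j, i])


def density_grid(
    signal, pairs: Sequence[LandmarkPair], grid: GridConfig | None = None, min_count: int = 1
) -> DensityGrid:
    """Windowed 2D signal density: each cell is the region average over the
    rectangle centered at (x,y) with half-widths from
    :func:`window_halfwidths`.

    Per-pair prefix sums over the needed offset range make each cell an
    O(|pairs|) lookup.  Cells whose count is below ``min_count`` are NaN
    (the default keeps the literal definition: only count-0 cells masked).
    """
    if grid is None:
        grid = GridConfig.default()
    xs = np.asarray(grid.x_points, dtype=int)
    ys = np.asarray(grid.y_points, dtype=int)
    n_x = np.array([window_halfwidths(int(x), int(ys[0]))[0] for x in xs])
    n_y = np.array([window_halfwidths(int(xs[0]), int(y))[1] for y in ys])
    values = np.full((len(ys), len(xs)), np.nan)
    counts = np.zeros((len(ys), len(xs)), dtype=np.int64)
    pairs = list(pairs)
    if not pairs:
        warnings.warn("density_grid: empty pair set; all cells masked")
        return DensityGrid(xs, ys, n_x, n_y, values, counts)

    off_lo = int((xs - n_x).min())
    off_hi = int((xs + n_x).max())
    length = off_hi - off_lo + 1
    prefix = np.zeros((len(pairs), length + 1))
    dist = np.empty(len(pairs), dtype=np.int64)
    for k, p in enumerate(pairs):
        sl = signal.oriented_slice(p.chrom, p.strand, p.z_U, off_lo, off_hi)
        np.cumsum(sl, out=prefix[k, 1:])
        dist[k] = p.distance

    min_count = max(1, min_count)
    for j, y in enumerate(ys):
        win_lo = int(y) - n_y[j] + dist
        win_hi = int(y) + n_y[j] + dist
        for i, x in enumerate(xs):
            lo = np.maximum(int(x) - n_x[i], win_lo)
            hi = np.minimum(int(x) + n_x[i], win_hi)
            sel = lo <= hi
            if not sel.any():
                continue
            lo_s, hi_s = lo[sel], hi[sel]
            n = int((hi_s - lo_s + 1).sum())
            counts[j, i] = n
            if n >= min_count:
                idx = np.flatnonzero(sel)
                total = float((prefix[idx, hi_s - off_lo + 1] - prefix[idx, lo_s - off_lo]).sum())
                values[j, i] = total / n
    return DensityGrid(xs, ys, n_x, n_y, values, counts)


# -- three-landmark extension ------------------------------------------------

@dataclass(frozen=True)
class LandmarkTriple:
    """Three oriented landmarks z_U < z_D < z_F (oriented frame) of one gene."""

    gene_id: str
    chrom: str
    strand: str
    z_U: int
    z_D: int
    z_F: int

    def __post_init__(self):
        if not (0 < self.d1 < self.d2):
            raise ValueError(f"{self.gene_id}: landmarks must be oriented z_U < z_D < z_F")

    @property
    def d1(self) -> int:
        return (self.z_D - self.z_U) if self.strand == "+" else (self.z_U - self.z_D)

    @property
    def d2(self) -> int:
        return (self.z_F - self.z_U) if self.strand == "+" else (self.z_U - self.z_F)


@dataclass(frozen=True)
class BoxSpec:
    """Inclusive 3D box in (x, y, v) relative-coordinate space."""

    x0: int
    y0: int
    v0: int
    x1: int
    y1: int
    v1: int

    def __post_init__(self):
        if self.x0 > self.x1 or self.y0 > self.y1 or self.v0 > self.v1:
            raise ValueError("invalid box bounds")


def region_average_3d(
    signal, triples: Iterable[LandmarkTriple], box: BoxSpec, max_width: int = 2_000_000
) -> RegionAverage:
    """Box average of the 3D-aligned signal g(x+z_U)·δ_{y,x−d1}·δ_{v,x−d2}.

    Direct enumeration over x with the two delta constraints checked per
    base; intended for exploratory triple analyses at modest box sizes.
    """
    if box.x1 - box.x0 + 1 > max_width:
        raise ValueError("box x-width exceeds cap")
    total = 0.0
    count = 0
    for t in triples:
        for x in range(box.x0, box.x1 + 1):
            y = x - t.d1
            v = x - t.d2
            if box.y0 <= y <= box.y1 and box.v0 <= v <= box.v1:
                total += signal.oriented_value(t.chrom, t.strand, t.z_U, x)
                count += 1
    if count == 0:
        return RegionAverage.undefined()
    return RegionAverage(total / count, count, True)
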