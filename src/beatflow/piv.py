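"""Two-pass block-matching optical flow for grayscale image pairs.

The first image is divided into overlapping square tiles.  For each tile
an equally sized window is shifted pixel-by-pixel over a search area of
the second image and the integer shift maximizing the cross-correlation
(the pixel-wise sum of brightness products) is taken as the tile's
displacement.  A thin-plate spline fit of the coarse vectors provides a
denoised prediction around which a second, finer pass searches with
smaller tiles and a much smaller search radius.

Coordinate convention: origin at the top-left pixel, ``x`` rightward
(columns), ``y`` downward (rows), 0-based indices.  A displacement
``(ux, uy)`` means the tile content moved by that many pixels from the
first to the second frame.  Displacements are integer pixels; there is
deliberately no sub-pixel peak refinement, which keeps the estimator
exactly equivalent to brute-force scoring of every shift in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import RBFInterpolator

from .errors import (
    FrameSizeError,
    InputError,
    InsufficientSupportError,
    TileShapeError,
)

__all__ = [
    "PIVConfig",
    "FlowGrid",
    "cross_correlation_score",
    "best_match_displacement",
    "thin_plate_spline_fit",
    "two_pass_flow",
]

#: Default thin-plate smoothing weight.  Node coordinates are measured
#: in grid-spacing units inside the fit, so this value is independent of
#: the lattice pitch; it is calibrated so that a single 8-px outlier
#: node in an otherwise uniform 8x8 field is attenuated below 2 px.
DEFAULT_SPLINE_SMOOTHING = 10.0

# Relative score tolerance used to detect ties between correlation
# maxima.  Exact ties computed through an FFT differ by rounding noise
# of this order; genuinely distinct scores on textured images differ by
# far more.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PIVConfig:
    """Tile and search geometry of the two passes.

    Defaults follow the standard setup: 64-px coarse tiles searched over
    +/-32 px, then 32-px tiles searched over +/-4 px around the coarse
    prediction.  ``tile_overlap`` is the fractional overlap between
    neighbouring tiles of a pass (0.5 means tile centers are spaced half
    a tile apart).
    """

    coarse_tile: int = 64
    coarse_search: int = 32
    fine_tile: int = 32
    fine_search: int = 4
    tile_overlap: float = 0.5
    spline_smoothing: float = DEFAULT_SPLINE_SMOOTHING
    mean_subtract: bool = True

    def __post_init__(self) -> None:
        for name in ("coarse_tile", "coarse_search", "fine_tile", "fine_search"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise InputError(f"{name} must be a positive integer, got {v!r}")
        if self.fine_tile >= self.coarse_tile:
            raise InputError("fine_tile must be smaller than coarse_tile")
        if self.fine_search >= self.coarse_search:
            raise InputError("fine_search must be smaller than coarse_search")
        if not 0.0 <= self.tile_overlap < 1.0:
            raise InputError("tile_overlap must lie in [0, 1)")
        if self.spline_smoothing < 0:
            raise InputError("spline_smoothing must be nonnegative")

    @property
    def coarse_spacing(self) -> int:
        return max(1, int(round(self.coarse_tile * (1.0 - self.tile_overlap))))

    @property
    def fine_spacing(self) -> int:
        return max(1, int(round(self.fine_tile * (1.0 - self.tile_overlap))))


@dataclass
class FlowGrid:
    """Displacement vectors on a regular lattice of image positions.

    ``vectors[j, i]`` holds ``(ux, uy)`` for the node whose pixel
    position is ``(origin[0] + i * spacing, origin[1] + j * spacing)``.
    Nodes whose tile or search window left the frame (or had no
    contrast) are masked out via ``valid`` and carry NaN vectors.
    """

    vectors: np.ndarray  # (ny, nx, 2) float64, [ux, uy]
    spacing: float
    origin: tuple[float, float]  # (x0, y0) in pixels
    valid: np.ndarray = field(default=None)  # (ny, nx) bool

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[-1] != 2:
            raise InputError("vectors must have shape (ny, nx, 2)")
        if self.spacing <= 0:
            raise InputError("grid spacing must be positive")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.vectors), axis=-1)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        self.vectors[~self.valid] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.vectors.shape[:2]

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates ``(X, Y)`` of every node, each (ny, nx)."""
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    def magnitudes(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])

    def copy(self) -> "FlowGrid":
        return FlowGrid(
            self.vectors.copy(), self.spacing, self.origin, self.valid.copy()
        )


def cross_correlation_score(tile_a: np.ndarray, tile_b: np.ndarray) -> float:
    """Pixel-by-pixel sum of brightness products of two same-shape tiles."""
    tile_a = np.asarray(tile_a, dtype=float)
    tile_b = np.asarray(tile_b, dtype=float)
    if tile_a.shape != tile_b.shape:
        raise TileShapeError(
            f"incompatible tiles: {tile_a.shape} vs {tile_b.shape}"
        )
    return float(np.sum(tile_a * tile_b))


def _tile_bounds(center: tuple[int, int], tile_size: int) -> tuple[int, int, int, int]:
    """Row/col bounds (r0, r1, c0, c1) of a tile centered on a pixel."""
    cx, cy = int(center[0]), int(center[1])
    half = tile_size // 2
    r0 = cy - half
    c0 = cx - half
    return r0, r0 + tile_size, c0, c0 + tile_size


def best_match_displacement(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    center: tuple[int, int],
    tile_size: int,
    search_radius: int,
    predicted: tuple[int, int] = (0, 0),
    mean_subtract: bool = True,
) -> np.ndarray | None:
    """Integer shift within ``predicted +/- search_radius`` maximizing the
    cross-correlation of the tile around ``center``.

    Returns ``None`` (a masked node) when the tile or the full search
    window does not fit inside the frames, or when the tile has zero
    contrast.  Ties are broken by the smallest Euclidean shift
    magnitude, then by row-major scan order of the search window.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    px, py = int(round(predicted[0])), int(round(predicted[1]))
    r0, r1, c0, c1 = _tile_bounds(center, tile_size)
    if r0 < 0 or c0 < 0 or r1 > frame_a.shape[0] or c1 > frame_a.shape[1]:
        return None
    wr0, wr1 = r0 + py - search_radius, r1 + py + search_radius
    wc0, wc1 = c0 + px - search_radius, c1 + px + search_radius
    if wr0 < 0 or wc0 < 0 or wr1 > frame_b.shape[0] or wc1 > frame_b.shape[1]:
        return None

    tile = frame_a[r0:r1, c0:c1]
    if np.ptp(tile) == 0:
        return None  # zero contrast: every shift scores alike
    if mean_subtract:
        # Subtracting the template mean makes the score identical to the
        # fully zero-mean cross-correlation (the window-mean term cancels).
        tile = tile - tile.mean()
    window = frame_b[wr0:wr1, wc0:wc1]

    # correlate(window, tile, 'valid')[i, j] is the product-sum with the
    # tile placed at window offset (i, j).  Small windows go through the
    # direct method so that integer-valued inputs score exactly.
    method = "direct" if window.size * (2 * search_radius + 1) ** 2 < 2_000_000 else "fft"
    scores = signal.correlate(window, tile, mode="valid", method=method)

    smax = scores.max()
    tol = _TIE_RTOL * max(1.0, abs(smax))
    ties = np.argwhere(scores >= smax - tol)
    dy = ties[:, 0] - search_radius + py
    dx = ties[:, 1] - search_radius + px
    best = np.lexsort((ties[:, 1], ties[:, 0], dx * dx + dy * dy))[0]
    return np.array([dx[best], dy[best]], dtype=float)


def _valid_points(flow: FlowGrid) -> tuple[np.ndarray, np.ndarray]:
    X, Y = flow.node_positions()
    m = flow.valid
    pts = np.column_stack([X[m], Y[m]])
    vals = flow.vectors[m]
    return pts, vals


def _check_support(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise InsufficientSupportError(
            f"thin-plate spline needs >= 3 valid nodes, got {len(pts)}"
        )
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise InsufficientSupportError("valid flow nodes are collinear")


def tps_interpolator(flow: FlowGrid, smoothing: float | None = None):
    """Thin-plate-spline interpolant of the valid nodes of ``flow``.

    Returns a callable mapping an (n, 2) array of pixel positions to an
    (n, 2) array of displacement vectors.  ``smoothing`` 0 interpolates
    the nodes exactly; positive values trade fidelity for smoothness.
    """
    pts, vals = _valid_points(flow)
    _check_support(pts)
    s = DEFAULT_SPLINE_SMOOTHING if smoothing is None else float(smoothing)
    # coordinates in grid-spacing units: smoothing then has the same
    # meaning regardless of the lattice pitch
    scale = float(flow.spacing)
    rbf = RBFInterpolator(
        pts / scale, vals, kernel="thin_plate_spline", smoothing=s, degree=1
    )

    def evaluate(points: np.ndarray) -> np.ndarray:
        return rbf(np.atleast_2d(np.asarray(points, dtype=float)) / scale)

    return evaluate


def thin_plate_spline_fit(
    sparse_flow: FlowGrid, smoothing: float | None = None
) -> FlowGrid:
    """Interpolate/denoise a flow field with a thin-plate spline.

    The smooth field is evaluated on the same lattice; every node of the
    result is valid.  Affine fields (uniform and linear displacement)
    are reproduced exactly for any smoothing weight.
    """
    evaluate = tps_interpolator(sparse_flow, smoothing)
    X, Y = sparse_flow.node_positions()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    fitted = evaluate(pts).reshape(sparse_flow.shape + (2,))
    return FlowGrid(
        fitted,
        sparse_flow.spacing,
        sparse_flow.origin,
        np.ones(sparse_flow.shape, dtype=bool),
    )


def _node_centers(extent: int, tile: int, spacing: int) -> np.ndarray:
    half = tile // 2
    last = extent - (tile - half)  # largest center with the tile inside
    if last < half:
        return np.array([], dtype=int)
    return np.arange(half, last + 1, spacing)


def _single_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    tile: int,
    search: int,
    spacing: int,
    predictor=None,
    mean_subtract: bool = True,
) -> FlowGrid:
    h, w = frame_a.shape
    xs = _node_centers(w, tile, spacing)
    ys = _node_centers(h, tile, spacing)
    vectors = np.full((len(ys), len(xs), 2), np.nan)
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    if predictor is not None:
        X, Y = np.meshgrid(xs, ys)
        pred = predictor(np.column_stack([X.ravel(), Y.ravel()]))
        pred = np.rint(pred).astype(int).reshape(len(ys), len(xs), 2)
    else:
        pred = np.zeros((len(ys), len(xs), 2), dtype=int)
    for j, cy in enumerate(ys):
        for i, cx in enumerate(xs):
            d = best_match_displacement(
                frame_a,
                frame_b,
                (cx, cy),
                tile,
                search,
                predicted=tuple(pred[j, i]),
                mean_subtract=mean_subtract,
            )
            if d is not None:
                vectors[j, i] = d
                valid[j, i] = True
    return FlowGrid(vectors, float(spacing), (float(xs[0]) if len(xs) else 0.0,
                                              float(ys[0]) if len(ys) else 0.0), valid)


def two_pass_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, config: PIVConfig | None = None
) -> FlowGrid:
    """Dense displacement field from ``frame_a`` to ``frame_b``.

    Pass 1 matches coarse tiles over the full search radius and is
    denoised by a thin-plate spline; pass 2 matches fine tiles within a
    small search radius around the spline prediction.  The returned grid
    has the fine-pass lattice; vector components never exceed
    ``coarse_search + fine_search`` in magnitude.
    """
    config = config or PIVConfig()
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise FrameSizeError(
            f"frames differ in shape: {frame_a.shape} vs {frame_b.shape}"
        )
    if frame_a.ndim != 2:
        raise FrameSizeError("frames must be single-channel 2-D images")
    need = config.coarse_tile + 2 * config.coarse_search
    if min(frame_a.shape) <= need:
        raise FrameSizeError(
            f"frame {frame_a.shape} too small: both dimensions must exceed "
            f"coarse_tile + 2*coarse_search = {need}"
        )

    coarse = _single_pass(
        frame_a,
        frame_b,
        config.coarse_tile,
        config.coarse_search,
        config.coarse_spacing,
        mean_subtract=config.mean_subtract,
    )
    evaluate = tps_interpolator(coarse, config.spline_smoothing)

    def predictor(points: np.ndarray) -> np.ndarray:
        p = evaluate(points)
        # keep predictions within the coarse search range so total
        # displacements stay bounded by coarse_search + fine_search
        return np.clip(p, -config.coarse_search, config.coarse_search)

    return _single_pass(
        frame_a,
        frame_b,
        config.fine_tile,
        config.fine_search,
        config.fine_spacing,
        predictor=predictor,
        mean_subtract=config.mean_subtract,
    )
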