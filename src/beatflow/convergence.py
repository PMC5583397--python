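"""Convergence and contractility maps from displacement fields.

Convergence C = -div(u) is estimated by central differences on the flow
lattice; it is positive where the tissue locally contracts.  Because a
numerical derivative of tracked displacements is noisy, three filters
are applied before thresholding into the contractility estimate s*:
a spatial median filter, a recursive temporal high-pass filter, and a
weighting by local image contrast that suppresses cell-free areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError, ProcessingError, StageError
from .piv import FlowGrid, PIVConfig

__all__ = [
    "ScalarMap",
    "finite_difference_convergence",
    "median_filter",
    "high_pass_filter",
    "local_contrast",
    "contrast_weight",
    "threshold_contractility",
    "contractility_pipeline",
    "tile_aggregate",
    "radial_profile",
]


@dataclass
class ScalarMap:
    """Scalar field on the lattice of a parent flow grid."""

    values: np.ndarray  # (ny, nx)
    spacing: float
    origin: tuple[float, float]
    kind: str = "generic"  # convergence | contractility | weight | generic
    border: np.ndarray = field(default=None)  # True where one-sided differences

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("ScalarMap values must be 2-D")
        if self.border is None:
            self.border = np.zeros(self.values.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    def same_lattice(self, other: "ScalarMap") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )


def finite_difference_convergence(flow: FlowGrid) -> ScalarMap:
    """C = -div(u) by central differences with the grid spacing d.

    Border nodes use one-sided differences and are flagged in the
    ``border`` mask so downstream statistics can exclude them.
    """
    ny, nx = flow.shape
    if ny < 3 or nx < 3:
        raise InputError(
            f"need at least 3x3 flow nodes for central differences, got {ny}x{nx}"
        )
    ux = flow.vectors[..., 0]
    uy = flow.vectors[..., 1]
    d = flow.spacing
    dux_dx = np.gradient(ux, d, axis=1)
    duy_dy = np.gradient(uy, d, axis=0)
    C = -(dux_dx + duy_dy)
    border = np.zeros((ny, nx), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return ScalarMap(C, flow.spacing, flow.origin, kind="convergence", border=border)


def median_filter(smap: ScalarMap, radius: int = 1) -> ScalarMap:
    """Replace each node by the median over its (2r+1)^2 neighbourhood.

    The neighbourhood is truncated at the map border (no padding values
    are invented) and NaN nodes are ignored, which preserves step edges
    exactly.
    """
    if radius < 1:
        raise InputError("median filter radius must be >= 1")
    padded = np.pad(smap.values, radius, constant_values=np.nan)
    windows = sliding_window_view(padded, (2 * radius + 1, 2 * radius + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = np.nanmedian(windows, axis=(2, 3))
    return ScalarMap(out, smap.spacing, smap.origin, smap.kind, smap.border.copy())


def high_pass_filter(series: np.ndarray, q: float) -> np.ndarray:
    """Recursive temporal high-pass filter of a per-node time series.

    ``series`` has time as its first axis.  With forgetting factor
    0 < q < 1, each step adds the raw increment to the filtered value
    and relaxes toward the temporal mean M of the unfiltered sequence:

        C'(t) = q * [C'(t-1) + C(t) - C(t-1)] + (1 - q) * M

    The mean of a stationary sequence is preserved exactly.  The filter
    is initialized at C'(0) = M, which makes a constant series a fixed
    point from the first step.
    """
    if not 0.0 < q < 1.0:
        raise InputError(f"q must lie strictly between 0 and 1, got {q}")
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise InputError("series must contain at least 2 time points")
    M = series.mean(axis=0)
    out = np.empty_like(series)
    out[0] = M
    for t in range(1, series.shape[0]):
        out[t] = q * (out[t - 1] + series[t] - series[t - 1]) + (1.0 - q) * M
    return out


def _box_std(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel standard deviation over a window truncated at borders."""
    img = np.asarray(image, dtype=float)
    ones = np.ones_like(img)

    def boxsum(a: np.ndarray) -> np.ndarray:
        # integral-image box sum of the window centered on each pixel,
        # clipped to the image bounds
        ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
        ii[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
        h, w = a.shape
        lo = window // 2
        hi = window - lo
        r = np.arange(h)
        c = np.arange(w)
        r0 = np.clip(r - lo, 0, h)[:, None]
        r1 = np.clip(r + hi, 0, h)[:, None]
        c0 = np.clip(c - lo, 0, w)[None, :]
        c1 = np.clip(c + hi, 0, w)[None, :]
        return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]

    n = boxsum(ones)
    mean = boxsum(img) / n
    meansq = boxsum(img * img) / n
    return np.sqrt(np.maximum(meansq - mean * mean, 0.0))


def local_contrast(
    frame: np.ndarray,
    window: int = 16,
    grid: FlowGrid | ScalarMap | None = None,
    normalize: float | bool = True,
) -> ScalarMap:
    """Local standard deviation of image brightness around each node.

    Computed within a ``window`` x ``window`` pixel area centered on the
    node's pixel position.  ``normalize=True`` rescales by the frame's
    maximum local SD so the weight lies in [0, 1]; a float rescales by
    that fixed saturation value instead (use the stack-wide maximum for
    consistent weighting across frames).
    """
    if window < 2:
        raise InputError("contrast window must be >= 2 pixels")
    frame = np.asarray(frame, dtype=float)
    sd = _box_std(frame, window)
    if grid is None:
        values = sd
        spacing, origin = 1.0, (0.0, 0.0)
    else:
        X, Y = grid.node_positions()
        rows = np.clip(np.rint(Y).astype(int), 0, frame.shape[0] - 1)
        cols = np.clip(np.rint(X).astype(int), 0, frame.shape[1] - 1)
        values = sd[rows, cols]
        spacing, origin = grid.spacing, grid.origin
    if normalize is True:
        peak = values.max()
        values = values / peak if peak > 0 else np.zeros_like(values)
    elif normalize:
        values = np.clip(values / float(normalize), 0.0, 1.0)
    return ScalarMap(values, spacing, origin, kind="weight")


def contrast_weight(smap: ScalarMap, weight: ScalarMap) -> ScalarMap:
    """Pointwise product of a map with a contrast weight in [0, 1]."""
    if not smap.same_lattice(weight):
        raise InputError("map and weight are on different lattices")
    return ScalarMap(
        smap.values * weight.values,
        smap.spacing,
        smap.origin,
        smap.kind,
        smap.border | weight.border,
    )


def threshold_contractility(C: ScalarMap) -> ScalarMap:
    """s* = C where C > 0, else 0."""
    values = np.where(C.values > 0, C.values, 0.0)
    return ScalarMap(values, C.spacing, C.origin, kind="contractility",
                     border=C.border.copy())


def contractility_pipeline(
    stack,
    config: PIVConfig | None = None,
    q: float = 0.9,
    median_radius: int = 1,
    contrast_window: int = 16,
    reference_flows: list[FlowGrid] | None = None,
    reference_index: int | None = None,
    frame_interval: float = 0.1,
) -> list[ScalarMap]:
    """Per-frame contractility maps s* from an image stack.

    Stages, in order: reference-frame optical flow -> convergence ->
    spatial median filter -> temporal high-pass -> contrast weighting ->
    thresholding.  Precomputed ``reference_flows`` (displacements
    against a relaxed reference frame) can be supplied to avoid
    recomputing the optical flow.
    """
    from . import kinetics  # local import to avoid a cycle

    frames = kinetics._as_frames(stack)
    if len(frames) < 2:
        raise InputError("need at least 2 frames")
    config = config or PIVConfig()

    if reference_flows is None:
        try:
            if reference_index is None:
                pair_flows = [
                    kinetics.two_pass_flow(frames[t], frames[t + 1], config)
                    for t in range(len(frames) - 1)
                ]
                V = kinetics.velocity_trace(pair_flows, frame_interval)
                reference_index = int(np.nanargmin(V.values))
            reference_flows, _ = kinetics.reference_displacement(
                stack, reference_index, config, frame_interval
            )
        except Exception as exc:  # noqa: BLE001 - annotate with stage
            raise StageError("optical flow", str(exc)) from exc

    try:
        conv = [finite_difference_convergence(f) for f in reference_flows]
    except Exception as exc:
        raise StageError("convergence", str(exc)) from exc
    try:
        conv = [median_filter(c, median_radius) for c in conv]
    except Exception as exc:
        raise StageError("median filter", str(exc)) from exc
    try:
        filtered = high_pass_filter(np.stack([c.values for c in conv]), q)
    except Exception as exc:
        raise StageError("high-pass filter", str(exc)) from exc

    try:
        grid = reference_flows[0]
        raw_weights = [
            local_contrast(frame, contrast_window, grid, normalize=False)
            for frame in frames
        ]
        peak = max(w.values.max() for w in raw_weights)
        scale = peak if peak > 0 else 1.0
    except Exception as exc:
        raise StageError("local contrast", str(exc)) from exc

    maps = []
    for t, c in enumerate(conv):
        weighted = ScalarMap(
            filtered[t] * (raw_weights[t].values / scale),
            c.spacing,
            c.origin,
            kind="convergence",
            border=c.border,
        )
        maps.append(threshold_contractility(weighted))
    return maps


def tile_aggregate(
    map_a: ScalarMap | np.ndarray, map_b: np.ndarray, tile: int
) -> np.ndarray:
    """Paired per-tile totals of a map and a pixel image.

    The field of view (the shape of ``map_b``) is split into
    non-overlapping ``tile`` x ``tile`` pixel squares (remainder rows and
    columns are dropped).  Returns an (n_tiles, 2) array of
    (sum of map_a, sum of map_b) suitable for a correlation readout.
    ``map_a`` may be a pixel-resolved array or a ScalarMap whose nodes
    are assigned to tiles by pixel position.
    """
    map_b = np.asarray(map_b, dtype=float)
    h, w = map_b.shape
    if tile > min(h, w):
        raise InputError(f"tile size {tile} exceeds the field of view {h}x{w}")
    n_ty, n_tx = h // tile, w // tile

    sums_b = (
        map_b[: n_ty * tile, : n_tx * tile]
        .reshape(n_ty, tile, n_tx, tile)
        .sum(axis=(1, 3))
    )

    if isinstance(map_a, ScalarMap):
        sums_a = np.zeros((n_ty, n_tx))
        X, Y = map_a.node_positions()
        tx = (X / tile).astype(int)
        ty = (Y / tile).astype(int)
        inside = (tx < n_tx) & (ty < n_ty) & np.isfinite(map_a.values)
        np.add.at(sums_a, (ty[inside], tx[inside]), map_a.values[inside])
    else:
        arr = np.asarray(map_a, dtype=float)
        if arr.shape != map_b.shape:
            raise InputError("pixel map_a must match map_b's shape")
        sums_a = (
            arr[: n_ty * tile, : n_tx * tile]
            .reshape(n_ty, tile, n_tx, tile)
            .sum(axis=(1, 3))
        )
    return np.column_stack([sums_a.ravel(), sums_b.ravel()])


def radial_profile(
    smap: ScalarMap, center: tuple[float, float], bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radial average of a map around a center, in annuli of fixed width.

    Returns (bin_center_radii, mean_values); empty annuli yield NaN.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    X, Y = smap.node_positions()
    r = np.hypot(X - center[0], Y - center[1])
    finite = np.isfinite(smap.values)
    idx = (r[finite] / bin_width).astype(int)
    vals = smap.values[finite]
    nbins = idx.max() + 1 if idx.size else 0
    counts = np.bincount(idx, minlength=nbins)
    totals = np.bincount(idx, weights=vals, minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    radii = (np.arange(nbins) + 0.5) * bin_width
    return radii, means
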