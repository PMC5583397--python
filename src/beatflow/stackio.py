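"""Readers, writers and run configuration.

All numeric outputs are plain CSV with full ``repr`` precision so a
write/read round trip reproduces every value exactly.  Image stacks are
read from multi-page TIFFs or from directories of same-shape
single-channel images sorted lexicographically; integer bit depths are
normalized to [0, 1] with the original scale recorded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .kinetics import BeatPattern, ExtremaSequence
from .convergence import ScalarMap
from .piv import FlowGrid

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_flow_csv",
    "read_flow_csv",
    "write_scalar_maps_csv",
    "read_scalar_maps_csv",
    "write_beat_csv",
    "write_extrema_csv",
]

_FLOAT_FMT = "%.17g"  # lossless for float64


@dataclass
class ImageStack:
    """Ordered single-channel frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W) float64 in [0, 1]
    fps: float = 10.0
    source_dtype: str = "float64"
    source_max: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("stack must have shape (frames, height, width)")
        if self.fps <= 0:
            raise InputError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.fps


def _normalize(frames: np.ndarray, fps: float) -> ImageStack:
    dtype = frames.dtype
    if np.issubdtype(dtype, np.integer):
        scale = float(np.iinfo(dtype).max)
    else:
        scale = float(frames.max()) or 1.0
        if scale <= 1.0:
            scale = 1.0
    return ImageStack(
        frames.astype(float) / scale,
        fps=fps,
        source_dtype=str(dtype),
        source_max=scale,
    )


def read_stack(path: str | Path, fps: float = 10.0) -> ImageStack:
    """Load a multi-page TIFF or a directory of single-channel images."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise InputError(f"no image files found in {path}")
        frames = []
        shape = None
        for p in files:
            img = _read_single(p)
            if img.ndim != 2:
                raise InputError(f"{p.name}: expected a single-channel image")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise InputError(
                    f"{p.name}: shape {img.shape} differs from first frame {shape}"
                )
            frames.append(img)
        stacked = np.stack(frames)
    elif path.exists():
        import tifffile

        stacked = tifffile.imread(path)
        if stacked.ndim == 2:
            stacked = stacked[None]
        if stacked.ndim != 3:
            raise InputError(
                f"{path.name}: expected grayscale pages, got shape {stacked.shape}"
            )
    else:
        raise InputError(f"no such file or directory: {path}")
    if stacked.shape[0] == 0:
        raise InputError(f"{path}: contains zero frames")
    return _normalize(stacked, fps)


def _read_single(p: Path) -> np.ndarray:
    if p.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(p)
    import imageio.v3 as iio

    return np.asarray(iio.imread(p))


def write_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write frames as a 16-bit multi-page TIFF."""
    import tifffile

    frames = getattr(stack, "frames", stack)
    data = np.clip(np.asarray(frames, dtype=float), 0.0, 1.0)
    tifffile.imwrite(
        Path(path), (data * 65535).astype(np.uint16), photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# CSV formats


def write_flow_csv(
    flows: list[FlowGrid] | FlowGrid, path: str | Path
) -> None:
    if isinstance(flows, FlowGrid):
        flows = [flows]
    rows = []
    for t, flow in enumerate(flows):
        X, Y = flow.node_positions()
        ny, nx = flow.shape
        for j in range(ny):
            for i in range(nx):
                rows.append(
                    (
                        t,
                        i,
                        j,
                        X[j, i],
                        Y[j, i],
                        flow.vectors[j, i, 0],
                        flow.vectors[j, i, 1],
                        int(flow.valid[j, i]),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "node_x",
            "node_y",
            "pixel_x",
            "pixel_y",
            "ux",
            "uy",
            "valid",
        ],
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_flow_csv(path: str | Path) -> list[FlowGrid]:
    df = pd.read_csv(path, float_precision="round_trip")
    flows = []
    for _, grp in df.groupby("frame", sort=True):
        nx = int(grp["node_x"].max()) + 1
        ny = int(grp["node_y"].max()) + 1
        vectors = np.full((ny, nx, 2), np.nan)
        valid = np.zeros((ny, nx), dtype=bool)
        i = grp["node_x"].to_numpy()
        j = grp["node_y"].to_numpy()
        vectors[j, i, 0] = grp["ux"].to_numpy()
        vectors[j, i, 1] = grp["uy"].to_numpy()
        valid[j, i] = grp["valid"].to_numpy().astype(bool)
        px = grp["pixel_x"].to_numpy()
        py = grp["pixel_y"].to_numpy()
        if nx > 1:
            spacing = float(np.diff(np.unique(px)).min())
        elif ny > 1:
            spacing = float(np.diff(np.unique(py)).min())
        else:
            spacing = 1.0
        flows.append(
            FlowGrid(vectors, spacing, (float(px.min()), float(py.min())), valid)
        )
    return flows


def write_scalar_maps_csv(
    maps: list[ScalarMap] | ScalarMap, path: str | Path
) -> None:
    if isinstance(maps, ScalarMap):
        maps = [maps]
    rows = []
    for t, m in enumerate(maps):
        ny, nx = m.shape
        for j in range(ny):
            for i in range(nx):
                rows.append((t, i, j, m.values[j, i]))
    pd.DataFrame(rows, columns=["frame", "node_x", "node_y", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_scalar_maps_csv(
    path: str | Path, spacing: float = 1.0, origin: tuple[float, float] = (0.0, 0.0)
) -> list[ScalarMap]:
    df = pd.read_csv(path, float_precision="round_trip")
    maps = []
    for _, grp in df.groupby("frame", sort=True):
        nx = int(grp["node_x"].max()) + 1
        ny = int(grp["node_y"].max()) + 1
        values = np.full((ny, nx), np.nan)
        values[grp["node_y"].to_numpy(), grp["node_x"].to_numpy()] = grp[
            "value"
        ].to_numpy()
        maps.append(ScalarMap(values, spacing, origin))
    return maps


def write_beat_csv(pattern: BeatPattern, path: str | Path) -> None:
    pd.DataFrame({"time_s": pattern.times, "value": pattern.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_extrema_csv(
    ext: ExtremaSequence, signal: np.ndarray, path: str | Path
) -> None:
    rows = [("min", int(t), signal[t]) for t in ext.minima]
    rows += [("max", int(t), signal[t]) for t in ext.maxima]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["kind", "frame", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every knob of the end-to-end pipeline, JSON round-trippable."""

    coarse_tile: int = 64
    coarse_search: int = 32
    fine_tile: int = 32
    fine_search: int = 4
    tile_overlap: float = 0.5
    spline_smoothing: float = 50.0
    mean_subtract: bool = True
    delta: float | None = None  # None: 20% of the interdecile range
    q: float = 0.9
    median_radius: int = 1
    contrast_window: int = 16
    fps: float = 10.0
    seed: int = 0
    exact_rereference: bool = True
    max_exact_flows: int | None = None

    def piv(self):
        from .piv import PIVConfig

        return PIVConfig(
            coarse_tile=self.coarse_tile,
            coarse_search=self.coarse_search,
            fine_tile=self.fine_tile,
            fine_search=self.fine_search,
            tile_overlap=self.tile_overlap,
            spline_smoothing=self.spline_smoothing,
            mean_subtract=self.mean_subtract,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
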