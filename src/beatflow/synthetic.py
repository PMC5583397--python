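"""Ground-truth-annotated synthetic beating-monolayer movies.

A band-limited random texture stands in for a confluent cell layer.
One or more radially symmetric contractile centers deform it with the
elastic-sheet displacement field, modulated in time by a waveform with a
swift linear contraction and an exponential relaxation.  Frames are
produced by inverse-mapping (pull-back) warping, optionally degraded by
read noise and by drifting debris blobs inside designated cell-free
regions, and are returned together with the exact displacement and
convergence fields used to generate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import InputError
from .mechanics import SheetParams, solve_uniform_core

__all__ = [
    "BeatWaveform",
    "ContractileCenter",
    "SceneSpec",
    "GroundTruth",
    "generate_texture",
    "waveform_value",
    "warp_frame",
    "generate_movie",
]

#: Maximum allowed peak displacement (pixels); keeps the deformation in
#: the small-displacement regime where superposing centers is fair.
MAX_PEAK_DISPLACEMENT = 8.0


@dataclass(frozen=True)
class BeatWaveform:
    """Periodic activation: linear rise, then exponential relaxation."""

    period: float  # seconds
    contraction_rise: float  # seconds, short
    relaxation_tau: float  # seconds, exponential decay constant
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.contraction_rise < self.relaxation_tau < self.period:
            raise InputError(
                "need 0 < contraction_rise < relaxation_tau < period"
            )
        if self.amplitude <= 0:
            raise InputError("amplitude must be positive")


def waveform_value(w: BeatWaveform, t: float | np.ndarray) -> np.ndarray:
    """Activation in [0, 1]: 0 at cycle start, 1 at the end of the rise,
    exp(-(t - rise)/tau) during relaxation."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be nonnegative")
    phase = np.mod(t, w.period)
    rising = phase < w.contraction_rise
    out = np.where(
        rising,
        phase / w.contraction_rise,
        np.exp(-(phase - w.contraction_rise) / w.relaxation_tau),
    )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class ContractileCenter:
    """One beating focus: position, mechanics, waveform and phase.

    ``profile`` selects the active-stress distribution: a sharp uniform
    core of radius r0 (convergence peaks toward the core edge when the
    substrate drag is strong) or a radially symmetric Gaussian of width
    r0/2 (convergence peaks at the center; requires k > 0).
    """

    position: tuple[float, float]  # (x, y) pixels
    params: SheetParams  # lengths in pixels
    waveform: BeatWaveform
    phase: float = 0.0  # seconds, added to t before the waveform
    peak_displacement: float = 4.0  # max |u| in pixels at full activation
    profile: str = "uniform"  # "uniform" | "gaussian"

    def __post_init__(self) -> None:
        if not 0 < self.peak_displacement <= MAX_PEAK_DISPLACEMENT:
            raise InputError(
                f"peak_displacement must lie in (0, {MAX_PEAK_DISPLACEMENT}]"
            )
        if self.profile not in ("uniform", "gaussian"):
            raise InputError(f"unknown profile {self.profile!r}")
        if self.profile == "gaussian" and self.params.k == 0:
            raise InputError("gaussian profile needs substrate drag (k > 0)")


@dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    size: tuple[int, int]  # (height, width) pixels
    centers: list[ContractileCenter]
    texture_seed: int = 0
    noise_sigma: float = 0.0  # additive Gaussian read noise (intensity units)
    blank_regions: list[tuple[int, int, int, int]] = dc_field(default_factory=list)
    # (row0, col0, row1, col1) rectangles devoid of cells
    debris: bool = False  # drifting blobs inside blank regions
    fps: float = 10.0
    texture_correlation_length: float = 2.0

    def __post_init__(self) -> None:
        h, w = self.size
        if self.fps <= 0:
            raise InputError("fps must be positive")
        for c in self.centers:
            x, y = c.position
            if not (0 <= x < w and 0 <= y < h):
                raise InputError(f"center {c.position} outside the {h}x{w} frame")


@dataclass
class GroundTruth:
    """Exact per-frame deformation used to synthesize the movie."""

    activations: np.ndarray  # (n_frames, n_centers)
    center_displacements: list[np.ndarray]  # static (H, W, 2) per center
    center_convergences: list[np.ndarray]  # static (H, W) per center
    sigma_star_maps: list[np.ndarray]  # static (H, W) per center
    beat_times: list[np.ndarray]  # per center, seconds of activation peaks
    fps: float

    def displacement(self, t: int) -> np.ndarray:
        """Total (H, W, 2) displacement field of frame t."""
        out = np.zeros_like(self.center_displacements[0])
        for a, u in zip(self.activations[t], self.center_displacements):
            out += a * u
        return out

    def convergence(self, t: int) -> np.ndarray:
        out = np.zeros_like(self.center_convergences[0])
        for a, c in zip(self.activations[t], self.center_convergences):
            out += a * c
        return out


def generate_texture(
    seed: int, size: tuple[int, int] | int, correlation_length: float = 2.0
) -> np.ndarray:
    """Reproducible band-limited random texture in [0, 1].

    Mixes a smoothed random field with a fine-grained one so block
    matching finds unique correlation peaks at every scale.
    """
    if np.isscalar(size):
        size = (int(size), int(size))
    if min(size) < 64:
        raise InputError("texture must be at least 64 pixels on a side")
    rng = np.random.default_rng(seed)
    coarse = ndimage.gaussian_filter(rng.standard_normal(size), correlation_length)
    fine = rng.standard_normal(size)

    def norm(a: np.ndarray) -> np.ndarray:
        return (a - a.mean()) / a.std()

    tex = 0.8 * norm(coarse) + 0.2 * norm(fine)
    return np.clip(0.5 + 0.15 * tex, 0.0, 1.0)


def warp_frame(texture: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Pull-back warp: output pixel x samples the texture at x - u(x).

    ``u`` is an (H, W, 2) field of (ux, uy) in pixels.  Bilinear
    interpolation; a zero field reproduces the input exactly and integer
    uniform shifts are exact pixel shifts.
    """
    texture = np.asarray(texture, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape != texture.shape + (2,):
        raise InputError("displacement field must be (H, W, 2)")
    if np.hypot(u[..., 0], u[..., 1]).max() > 0.25 * min(texture.shape):
        raise InputError("displacement exceeds a quarter of the frame size")
    rows, cols = np.mgrid[0 : texture.shape[0], 0 : texture.shape[1]].astype(float)
    return ndimage.map_coordinates(
        texture, [rows - u[..., 1], cols - u[..., 0]], order=1, mode="nearest"
    )


def _center_fields(
    center: ContractileCenter, size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static displacement, convergence and sigma* maps of one center."""
    h, w = size
    cx, cy = center.position
    if center.profile == "gaussian":
        from .mechanics import (
            ContractilityField,
            convergence_from_contractility,
            displacement_from_contractility,
        )

        x = np.arange(w, dtype=float)
        y = np.arange(h, dtype=float)
        X, Y = np.meshgrid(x, y)
        width = center.params.r0 / 2.0
        sstar = center.params.sigma_star * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2)
        )
        field = ContractilityField(sstar, 1.0, (0.0, 0.0))
        u = displacement_from_contractility(field, center.params)
        C = convergence_from_contractility(field, center.params)
        scale = center.peak_displacement / np.hypot(u[..., 0], u[..., 1]).max()
        return scale * u, scale * C, sstar

    sol = solve_uniform_core(center.params)
    Y, X = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    r_safe = np.where(r > 1e-9, r, 1e-9)
    ur = sol.u(r_safe)
    scale = center.peak_displacement / abs(sol.u(np.array([center.params.r0]))[0])
    ux = scale * ur * dx / r_safe
    uy = scale * ur * dy / r_safe
    ux[r < 1e-9] = 0.0
    uy[r < 1e-9] = 0.0
    C = scale * sol.convergence(r_safe)
    sstar = np.where(r <= center.params.r0, center.params.sigma_star, 0.0)
    return np.stack([ux, uy], axis=-1), C, sstar


def _beat_times(w: BeatWaveform, phase: float, duration: float) -> np.ndarray:
    """Times (s) at which the activation peaks within [0, duration)."""
    # activation peaks when (t + phase) mod period == contraction_rise
    first = np.mod(w.contraction_rise - phase, w.period)
    return np.arange(first, duration, w.period)


def generate_movie(
    spec: SceneSpec, n_frames: int, seed: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a movie and its exact ground truth.

    Returns ``(frames, truth)`` with ``frames`` an (n_frames, H, W)
    float array in [0, 1].  All randomness (texture, noise, debris)
    derives from a single generator seeded with ``seed`` combined with
    the spec's texture seed, so identical inputs give identical movies.
    """
    if n_frames < 1:
        raise InputError("need at least one frame")
    h, w = spec.size
    rng = np.random.default_rng([seed, spec.texture_seed])
    texture = generate_texture(
        spec.texture_seed, spec.size, spec.texture_correlation_length
    )
    blank_value = float(texture.mean())
    for r0_, c0_, r1_, c1_ in spec.blank_regions:
        texture[r0_:r1_, c0_:c1_] = blank_value

    fields = [_center_fields(c, spec.size) for c in spec.centers]
    disps = [f[0] for f in fields]
    convs = [f[1] for f in fields]
    sstars = [f[2] for f in fields]

    times = np.arange(n_frames) / spec.fps
    acts = np.zeros((n_frames, len(spec.centers)))
    for i, c in enumerate(spec.centers):
        acts[:, i] = c.waveform.amplitude * waveform_value(
            c.waveform, np.mod(times + c.phase, c.waveform.period)
        )

    n_debris = 3 * len(spec.blank_regions) if spec.debris else 0
    debris_state = []
    for _ in range(n_debris):
        region = spec.blank_regions[rng.integers(len(spec.blank_regions))]
        r0_, c0_, r1_, c1_ = region
        debris_state.append(
            {
                "pos": np.array(
                    [rng.uniform(r0_, r1_), rng.uniform(c0_, c1_)]
                ),
                "vel": rng.uniform(-2.0, 2.0, size=2),  # px/frame, convective
                "region": region,
                "size": rng.uniform(2.0, 4.0),
            }
        )

    frames = np.empty((n_frames, h, w))
    Y, X = np.mgrid[0:h, 0:w].astype(float)
    for t in range(n_frames):
        u = np.zeros((h, w, 2))
        for a, d in zip(acts[t], disps):
            u += a * d
        frame = warp_frame(texture, u)
        for blob in debris_state:
            r0_, c0_, r1_, c1_ = blob["region"]
            p = blob["pos"] + t * blob["vel"]
            # wrap within the blank region so debris keeps drifting
            p[0] = r0_ + np.mod(p[0] - r0_, max(r1_ - r0_, 1))
            p[1] = c0_ + np.mod(p[1] - c0_, max(c1_ - c0_, 1))
            bump = 0.3 * np.exp(
                -((Y - p[0]) ** 2 + (X - p[1]) ** 2) / (2 * blob["size"] ** 2)
            )
            inside = np.zeros((h, w), dtype=bool)
            inside[r0_:r1_, c0_:c1_] = True
            frame = np.where(inside, np.clip(frame - bump, 0, 1), frame)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)

    duration = n_frames / spec.fps
    truth = GroundTruth(
        activations=acts,
        center_displacements=disps,
        center_convergences=convs,
        sigma_star_maps=sstars,
        beat_times=[
            _beat_times(c.waveform, c.phase, duration) for c in spec.centers
        ],
        fps=spec.fps,
    )
    return frames, truth
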