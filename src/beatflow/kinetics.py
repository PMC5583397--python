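"""Beat-pattern extraction from per-frame flow fields.

The average motility V(t) is the spatial mean of the speed magnitudes of
the frame-pair flow.  Displacements relative to a relaxed reference
frame (a minimum of V) give the per-frame mean displacement U(t); the
final beat pattern is synthesized as the pointwise minimum over the
candidate reference frames found as minima of the working displacement
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ProcessingError
from .piv import FlowGrid, PIVConfig, two_pass_flow

__all__ = [
    "BeatPattern",
    "ExtremaSequence",
    "BeatFrequency",
    "velocity_trace",
    "find_extrema",
    "reference_displacement",
    "approximate_reference_switch",
    "synthesize_beat_pattern",
    "beat_analysis",
    "beat_frequency",
    "default_delta",
]


@dataclass
class BeatPattern:
    """Per-frame scalar trace (mean speed or mean displacement)."""

    values: np.ndarray
    frame_interval: float  # seconds between consecutive samples
    kind: str = "velocity"  # "velocity" | "displacement"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ExtremaSequence:
    """Alternating minima/maxima frame indices of a scalar signal.

    The sequence starts with a minimum; each retained maximum is the
    absolute maximum between its flanking minima and exceeds them by at
    least ``delta`` (and symmetrically for minima).
    """

    minima: np.ndarray
    maxima: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=int)
        self.maxima = np.asarray(self.maxima, dtype=int)
        merged = self.interleaved()
        if np.any(np.diff(merged) <= 0):
            raise ProcessingError("extrema are not strictly alternating")

    def interleaved(self) -> np.ndarray:
        """Indices in temporal order: min, max, min, ..."""
        out = []
        for k in range(len(self.minima)):
            out.append(self.minima[k])
            if k < len(self.maxima):
                out.append(self.maxima[k])
        return np.asarray(out, dtype=int)


@dataclass
class BeatFrequency:
    bpm: float
    unreliable: bool
    n_maxima: int
    extrema: ExtremaSequence


def default_delta(values: np.ndarray, fraction: float = 0.2) -> float:
    """Default prominence threshold: a fraction of the interdecile range."""
    lo, hi = np.nanpercentile(np.asarray(values, dtype=float), [10, 90])
    spread = hi - lo
    return float(fraction * spread) if spread > 0 else np.finfo(float).tiny


def _interpolate_missing(values: np.ndarray) -> np.ndarray:
    """Fill NaN entries of a scalar trace by linear interpolation."""
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    good = ~bad
    if not good.any():
        raise ProcessingError("every frame of the trace is missing")
    idx = np.arange(len(values))
    out = values.copy()
    out[bad] = np.interp(idx[bad], idx[good], values[good])
    return out


def velocity_trace(
    flows: list[FlowGrid], frame_interval: float = 0.1
) -> BeatPattern:
    """V(t): spatial mean of speed magnitudes over the valid nodes.

    Frames with no valid node are flagged missing and filled by linear
    interpolation between their neighbours.
    """
    vals = np.full(len(flows), np.nan)
    for t, flow in enumerate(flows):
        if flow.valid.any():
            vals[t] = np.nanmean(flow.magnitudes()[flow.valid])
    return BeatPattern(_interpolate_missing(vals), frame_interval, kind="velocity")


def find_extrema(signal: np.ndarray, delta: float) -> ExtremaSequence:
    """Alternating Δ-prominent minima and maxima of a noisy signal.

    A minimum is retained once the signal has risen at least ``delta``
    above it; a maximum once the signal has dropped at least ``delta``
    below it.  Retained extrema are the absolute extremum of their
    interval; the earliest frame of an equal-valued plateau is reported.
    A trailing minimum is kept when the signal ends at least ``delta``
    below the last maximum.
    """
    a = np.asarray(signal, dtype=float)
    if delta <= 0:
        raise InputError("delta must be positive")
    if len(a) < 3:
        raise InputError("signal must contain at least 3 samples")

    minima: list[int] = []
    maxima: list[int] = []
    mn, mnpos = np.inf, -1
    mx, mxpos = -np.inf, -1
    looking_for_max = False  # start by confirming the leading minimum
    for t, v in enumerate(a):
        if v > mx:
            mx, mxpos = v, t
        if v < mn:
            mn, mnpos = v, t
        if not looking_for_max:
            if v > mn + delta:
                minima.append(mnpos)
                looking_for_max = True
                mx, mxpos = v, t
        else:
            if v < mx - delta:
                maxima.append(mxpos)
                looking_for_max = False
                mn, mnpos = v, t
    if not looking_for_max and maxima and mnpos > maxima[-1]:
        # trailing minimum already confirmed by the delta-drop from the
        # last maximum
        minima.append(mnpos)
    if not maxima:
        # a lone rise-confirmed minimum without any prominent maximum
        # (e.g. a monotone ramp) is not a beat
        minima = []
    return ExtremaSequence(np.array(minima), np.array(maxima), delta)


def reference_displacement(
    stack,
    reference_index: int,
    config: PIVConfig | None = None,
    frame_interval: float = 0.1,
) -> tuple[list[FlowGrid], BeatPattern]:
    """Flow of every frame against a fixed reference frame.

    Returns the per-frame displacement fields u_ref(t, x) and the trace
    of their spatial mean magnitudes; the trace is 0 at the reference
    frame by construction.
    """
    frames = _as_frames(stack)
    if not 0 <= reference_index < len(frames):
        raise InputError(
            f"reference index {reference_index} outside stack of {len(frames)} frames"
        )
    config = config or PIVConfig()
    ref = frames[reference_index]
    flows = [two_pass_flow(ref, frame, config) for frame in frames]
    trace = velocity_trace(flows, frame_interval)
    return flows, BeatPattern(trace.values, frame_interval, kind="displacement")


def approximate_reference_switch(
    flow_t: FlowGrid, flow_T: FlowGrid
) -> FlowGrid:
    """Re-reference a displacement field by vector subtraction.

    Both fields must be flows against the same reference; the result
    approximates the flow of frame t against frame T.  Nodes invalid in
    either operand are invalid in the result.
    """
    if flow_t.shape != flow_T.shape or flow_t.spacing != flow_T.spacing:
        raise InputError("flow grids do not share a lattice")
    valid = flow_t.valid & flow_T.valid
    vectors = np.where(valid[..., None], flow_t.vectors - flow_T.vectors, np.nan)
    return FlowGrid(vectors, flow_t.spacing, flow_t.origin, valid)


def _as_frames(stack) -> np.ndarray:
    frames = getattr(stack, "frames", stack)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise InputError("image stack must be a (frames, height, width) array")
    return frames


def _mean_magnitude_trace(
    flows: list[FlowGrid], frame_interval: float
) -> BeatPattern:
    trace = velocity_trace(flows, frame_interval)
    return BeatPattern(trace.values, frame_interval, kind="displacement")


@dataclass
class BeatAnalysis:
    """Everything derived while synthesizing the beat pattern."""

    velocity: BeatPattern  # V(t)
    t_star: int  # primary reference frame (a minimum of V)
    reference_flows: list[FlowGrid]  # u_{t*}(t, x)
    displacement: BeatPattern  # U_{t*}(t)
    references: np.ndarray  # frames t_k^min used in the synthesis
    pattern: BeatPattern  # U(t), pointwise min over references


def beat_analysis(
    stack,
    config: PIVConfig | None = None,
    delta: float | None = None,
    frame_interval: float = 0.1,
    exact: bool = True,
    max_exact_flows: int | None = None,
) -> BeatAnalysis:
    """Full bootstrap: V(t) -> t* -> U_{t*}(t) -> minima -> U(t).

    ``exact`` re-references by fresh optical flow against every
    candidate reference; otherwise (or when the number of flows needed
    would exceed ``max_exact_flows``) the cheap vector-difference
    approximation is used.
    """
    frames = _as_frames(stack)
    config = config or PIVConfig()
    pair_flows = [
        two_pass_flow(frames[t], frames[t + 1], config)
        for t in range(len(frames) - 1)
    ]
    V = velocity_trace(pair_flows, frame_interval)
    t_star = int(np.nanargmin(V.values))

    ref_flows, U_ref = reference_displacement(
        stack, t_star, config, frame_interval
    )
    if delta is None:
        delta = default_delta(U_ref.values)
    ext = find_extrema(U_ref.values, delta)
    if len(ext.minima) == 0:
        if np.nanmax(U_ref.values) - np.nanmin(U_ref.values) < delta:
            # essentially flat recording (e.g. a static stack): the
            # bootstrap reference is the only sensible one
            references = np.array([t_star])
        else:
            raise ProcessingError(
                "no displacement minima found; record a longer sequence or "
                "reduce delta"
            )
    else:
        references = ext.minima

    n = len(frames)
    if max_exact_flows is not None and len(references) * n > max_exact_flows:
        exact = False

    candidates = []
    for T in references:
        if T == t_star:
            candidates.append(U_ref.values)
        elif exact:
            _, U_T = reference_displacement(stack, int(T), config, frame_interval)
            candidates.append(U_T.values)
        else:
            diffs = [
                approximate_reference_switch(ref_flows[t], ref_flows[int(T)])
                for t in range(n)
            ]
            candidates.append(_mean_magnitude_trace(diffs, frame_interval).values)
    U = np.min(np.vstack(candidates), axis=0)
    return BeatAnalysis(
        velocity=V,
        t_star=t_star,
        reference_flows=ref_flows,
        displacement=U_ref,
        references=np.asarray(references, dtype=int),
        pattern=BeatPattern(U, frame_interval, kind="displacement"),
    )


def synthesize_beat_pattern(
    stack,
    config: PIVConfig | None = None,
    delta: float | None = None,
    frame_interval: float = 0.1,
    exact: bool = True,
    max_exact_flows: int | None = None,
) -> BeatPattern:
    """Beat pattern U(t) synthesized over the optimal reference frames."""
    return beat_analysis(
        stack, config, delta, frame_interval, exact, max_exact_flows
    ).pattern


def beat_frequency(pattern: BeatPattern, delta: float | None = None) -> BeatFrequency:
    """Beats per minute from the mean period between consecutive maxima.

    Flags the result unreliable when the frequency reaches the sampling
    limit (120 bpm at 10 frames/s, i.e. periods under 5 frames).
    """
    if delta is None:
        delta = default_delta(pattern.values)
    ext = find_extrema(pattern.values, delta)
    if len(ext.maxima) < 2:
        raise ProcessingError(
            f"need at least 2 maxima to estimate a period, found {len(ext.maxima)}"
        )
    period = float(np.mean(np.diff(ext.maxima))) * pattern.frame_interval
    bpm = 60.0 / period
    fps = 1.0 / pattern.frame_interval
    unreliable = bpm >= 12.0 * fps
    return BeatFrequency(bpm, unreliable, len(ext.maxima), ext)
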