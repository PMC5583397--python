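"""End-to-end orchestration: stack in, beat pattern and s* maps out."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__, convergence, kinetics
from .errors import ProcessingError, StageError
from .stackio import (
    ImageStack,
    RunConfig,
    write_beat_csv,
    write_extrema_csv,
    write_flow_csv,
    write_scalar_maps_csv,
)

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("beatflow")


@dataclass
class PipelineResult:
    analysis: kinetics.BeatAnalysis
    frequency: kinetics.BeatFrequency | None
    sstar: list[convergence.ScalarMap]
    config: RunConfig


def run_pipeline(
    stack: ImageStack,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    overlays: bool = False,
) -> PipelineResult:
    """Run optical flow, beat analysis and contractility mapping.

    Deterministic given (stack, config).  When ``outdir`` is given, the
    flows, traces, extrema, s* maps and a JSON manifest are written
    there; ``overlays`` additionally renders s* heat overlays as PNGs.
    """
    config = config or RunConfig()
    piv_cfg = config.piv()
    dt = stack.frame_interval

    log.info("stage=flow frames=%d", len(stack))
    analysis = kinetics.beat_analysis(
        stack,
        piv_cfg,
        delta=config.delta,
        frame_interval=dt,
        exact=config.exact_rereference,
        max_exact_flows=config.max_exact_flows,
    )

    frequency = None
    try:
        frequency = kinetics.beat_frequency(analysis.pattern, config.delta)
        log.info(
            "stage=beats bpm=%.2f unreliable=%s",
            frequency.bpm,
            frequency.unreliable,
        )
    except ProcessingError as exc:
        log.info("stage=beats no frequency: %s", exc)

    log.info("stage=convergence q=%.3f", config.q)
    sstar = convergence.contractility_pipeline(
        stack,
        piv_cfg,
        q=config.q,
        median_radius=config.median_radius,
        contrast_window=config.contrast_window,
        reference_flows=analysis.reference_flows,
        frame_interval=dt,
    )

    result = PipelineResult(analysis, frequency, sstar, config)
    if outdir is not None:
        _write_bundle(result, stack, Path(outdir), overlays)
    return result


def _write_bundle(
    result: PipelineResult, stack: ImageStack, outdir: Path, overlays: bool
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    a = result.analysis
    write_flow_csv(a.reference_flows, outdir / "reference_flow.csv")
    write_beat_csv(a.velocity, outdir / "velocity.csv")
    write_beat_csv(a.pattern, outdir / "beat_pattern.csv")
    delta = result.config.delta or kinetics.default_delta(a.pattern.values)
    try:
        ext = kinetics.find_extrema(a.pattern.values, delta)
        write_extrema_csv(ext, a.pattern.values, outdir / "extrema.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("extrema", str(exc)) from exc
    write_scalar_maps_csv(result.sstar, outdir / "sstar.csv")
    manifest = {
        "beatflow_version": __version__,
        "config": dataclasses.asdict(result.config),
        "n_frames": len(stack),
        "reference_frame": int(a.t_star),
        "references": [int(t) for t in a.references],
        "beats_per_minute": (
            None if result.frequency is None else result.frequency.bpm
        ),
        "frequency_unreliable": (
            None if result.frequency is None else result.frequency.unreliable
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if overlays:
        _render_overlays(result, stack, outdir)


def _render_overlays(
    result: PipelineResult, stack: ImageStack, outdir: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(float(np.nanmax(m.values)) for m in result.sstar) or 1.0
    for t, smap in enumerate(result.sstar):
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(stack[t], cmap="gray", interpolation="nearest")
        X, Y = smap.node_positions()
        masked = np.ma.masked_less_equal(smap.values, 0)
        ax.pcolormesh(
            X, Y, masked, cmap="hot", alpha=0.6, vmin=0, vmax=vmax, shading="nearest"
        )
        ax.set_axis_off()
        fig.savefig(outdir / f"sstar_{t:04d}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
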