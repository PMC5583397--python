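"""Shared fixtures: textures, synthetic movies and their analyses.

The expensive optical-flow analyses are session-scoped so each movie is
processed once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from beatflow import convergence, kinetics, mechanics, synthetic
from beatflow.piv import PIVConfig
from beatflow.stackio import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture256():
    return synthetic.generate_texture(1, (256, 256))


@pytest.fixture(scope="session")
def beating_movie():
    """Small single-center beating movie with full ground truth."""
    center = synthetic.ContractileCenter(
        position=(80, 80),
        params=mechanics.SheetParams(k=0.005, r0=36),
        waveform=synthetic.BeatWaveform(
            period=1.0, contraction_rise=0.1, relaxation_tau=0.12
        ),
        peak_displacement=4.0,
        profile="gaussian",
    )
    spec = synthetic.SceneSpec(
        size=(160, 160),
        centers=[center],
        texture_seed=3,
        noise_sigma=0.01,
        fps=10.0,
    )
    frames, truth = synthetic.generate_movie(spec, 80, seed=3)
    return ImageStack(frames, fps=10.0), truth, spec


@pytest.fixture(scope="session")
def beating_analysis(beating_movie):
    stack, _, _ = beating_movie
    return kinetics.beat_analysis(
        stack, PIVConfig(), frame_interval=0.1, exact=False, max_exact_flows=0
    )


@pytest.fixture(scope="session")
def beating_sstar(beating_movie, beating_analysis):
    stack, _, _ = beating_movie
    return convergence.contractility_pipeline(
        stack, reference_flows=beating_analysis.reference_flows
    )


@pytest.fixture(scope="session")
def static_stack():
    tex = synthetic.generate_texture(7, (160, 160))
    return ImageStack(np.repeat(tex[None], 6, axis=0), fps=10.0)
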