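"""Shared fixtures: synthetic sessions at several scales.

Everything is generated programmatically at test time from fixed seeds; the
expensive benchmark-scale fixtures are session-scoped so they are built once
per run.
"""

import numpy as np
import pytest

import ecogpipe as ep
from ecogpipe.synthetic import NoiseModel, TuningMap, synthesize_session


def make_planted_session(n_rows, n_cols, tuned_channels, duration_s=100.0,
                         seed=0, gain=3.0, fs=1000.0, noise=None):
    """Session where exactly ``tuned_channels`` carry kinematic drive.

    Channel i in the list is coupled to axis ``i % 3`` with a fixed gain;
    every other channel has zero gain (noise only).  Returns
    (session, kin, tuning).
    """
    layout = ep.build_layout(n_rows, n_cols, 1250.0, 850.0)
    gains = np.zeros((layout.n_channels, 3))
    for i, ch in enumerate(tuned_channels):
        gains[ch, i % 3] = gain
    tuning = TuningMap(gains=gains, source_centers=np.zeros((0, 2)),
                       source_axes=np.zeros(0, dtype=int), spatial_scale_mm=1.0,
                       baseline_hg=np.full(layout.n_channels, 0.2))
    kin = ep.make_kinematics(duration_s, 100.0, "gait", seed=seed + 1)
    noise = noise if noise is not None else NoiseModel(
        one_over_f_scale=5.0, line_amp=5.0, common_mode_amp=8.0,
        white_rms=0.5, shared_hg_amp=0.4)
    session = synthesize_session(layout, tuning, kin, noise, fs=fs, seed=seed + 2)
    return session, kin, tuning


@pytest.fixture(scope="session")
def benchmark_data():
    """The packaged benchmark preset at full scale (seed 1, 300 s, 16x16)."""
    session, kin, tuning = ep.make_benchmark_session(seed=1)
    fm, al = ep.assemble_dataset(session, kin, ep.benchmark_config())
    return {"session": session, "kin": kin, "tuning": tuning, "fm": fm, "al": al}


@pytest.fixture(scope="session")
def small_data():
    """Benchmark-like conditions on an 8x8 grid, 120 s (fast variant)."""
    session, kin, tuning = ep.make_benchmark_session(
        seed=7, n_rows=8, n_cols=8, duration_s=120.0, n_sources=6)
    fm, al = ep.assemble_dataset(session, kin, ep.benchmark_config())
    return {"session": session, "kin": kin, "tuning": tuning, "fm": fm, "al": al}


@pytest.fixture(scope="session")
def planted_data():
    """8x8 session where exactly 8 known channels carry the kinematic drive."""
    tuned = [0, 9, 18, 27, 36, 45, 54, 63]  # grid diagonal
    session, kin, tuning = make_planted_session(8, 8, tuned, seed=11)
    fm, al = ep.assemble_dataset(session, kin, ep.RunConfig())
    return {"session": session, "kin": kin, "tuning": tuning, "fm": fm,
            "al": al, "tuned": tuned}
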