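"""Synthetic micro-ECoG sessions with known ground truth.

Real grid recordings of this kind are not publicly deposited, so every
downstream stage is exercised against generated sessions in which the
movement-related structure is known exactly.  The generator emulates the
statistical structure the analysis assumes, not cortical biophysics:

* a spatial tuning map — Gaussian "source" bumps on the array plane, each
  coupled to one kinematic axis, so high-gamma amplitude at a site is
  baseline plus the gain-weighted kinematic drive;
* kinematics — a quasi-periodic gait-like trajectory (largest amplitude on
  the Y axis, mirroring primary knee-flexion kinematics) or piecewise
  minimum-jerk centre-out reaches;
* layered noise — 1/f background, 50 Hz line plus harmonics, a shared
  common-mode process (removed by common average referencing) and white
  sensor noise;
* bad channels — impedance above the 1 MOhm exclusion threshold with the
  signal replaced by high-amplitude noise.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import ElectrodeArrayLayout, KinematicTrace, SessionRecording
from .errors import AliasingError, InvalidArgumentError

HG_BAND = (70.0, 150.0)  # Hz, high-gamma carrier band


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class TuningMap:
    """Per-channel coupling of each kinematic axis to high-gamma amplitude."""

    gains: np.ndarray            # (n_channels, 3), >= 0
    source_centers: np.ndarray   # (n_sources, 2) mm
    source_axes: np.ndarray      # (n_sources,) axis index each source drives
    spatial_scale_mm: float
    baseline_hg: np.ndarray      # (n_channels,) resting HG amplitude, uV


@dataclass
class NoiseModel:
    """Amplitudes (uV) of the layered noise processes."""

    one_over_f_scale: float = 10.0   # RMS of the 1/f background
    line_hz: float = 50.0
    line_amp: float = 5.0            # amplitude of the fundamental
    n_harmonics: int = 4
    common_mode_amp: float = 10.0    # RMS of the shared common-mode process
    white_rms: float = 2.0
    shared_hg_amp: float = 0.4       # RMS of the diffuse synchronous HG background
    shared_hg_scale_mm: float = 8.0  # spatial scale of its weight profile

    def __post_init__(self):
        for name in ("one_over_f_scale", "line_amp", "common_mode_amp",
                     "white_rms", "shared_hg_amp"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")


@dataclass
class TrialSpec:
    """One cursor-task trial: reach the target within the time limit and hold."""

    task: str                    # "center_out" | "webgrids"
    target_id: int
    target_xy: np.ndarray        # normalized screen coordinates in [-1, 1]^2
    max_duration: float = 4.0    # s
    hold_ms: float = 200.0

    def __post_init__(self):
        n_targets = {"center_out": 8, "webgrids": 255}.get(self.task)
        if n_targets is None:
            raise InvalidArgumentError(f"unknown task {self.task!r}")
        if not (0 <= self.target_id < n_targets):
            raise InvalidArgumentError(
                f"{self.task} target_id must be in [0, {n_targets})")
        if self.max_duration <= 0:
            raise InvalidArgumentError("max_duration must be positive")
        self.target_xy = np.asarray(self.target_xy, dtype=float)


# ---------------------------------------------------------------------------
# Tuning maps
# ---------------------------------------------------------------------------

def make_tuning_maps(layout: ElectrodeArrayLayout, n_sources: int,
                     spatial_scale_mm: float, seed: int,
                     source_amp_range: tuple = (0.5, 1.0),
                     baseline_hg: float = 1.0) -> TuningMap:
    """Place Gaussian source bumps on the array and sum them into channel gains.

    Each source sits at a uniform random location within the array footprint,
    drives exactly one kinematic axis (cycling X, Y, Z so all axes are covered
    once ``n_sources >= 3``), and contributes
    ``amp * exp(-d^2 / (2 * scale^2))`` to the gain of every site at planar
    distance ``d``.
    """
    if n_sources < 1:
        raise InvalidArgumentError("n_sources must be >= 1")
    if spatial_scale_mm <= 0:
        raise InvalidArgumentError("spatial_scale_mm must be positive")
    rng = np.random.default_rng(seed)
    xy = layout.site_xy
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    centers = rng.uniform(lo, hi, size=(n_sources, 2))
    amps = rng.uniform(*source_amp_range, size=n_sources)
    axes = np.arange(n_sources) % 3
    gains = np.zeros((layout.n_channels, 3))
    for c, a, ax in zip(centers, amps, axes):
        d2 = np.sum((xy - c) ** 2, axis=1)
        gains[:, ax] += a * np.exp(-d2 / (2.0 * spatial_scale_mm ** 2))
    return TuningMap(
        gains=gains, source_centers=centers, source_axes=axes,
        spatial_scale_mm=float(spatial_scale_mm),
        baseline_hg=np.full(layout.n_channels, float(baseline_hg)),
    )


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

#: Gait oscillation amplitude per axis (arbitrary length units). Y largest,
#: mirroring primary knee-flexion kinematics dominating that direction.
GAIT_AMPLITUDES = (0.6, 1.0, 0.4)
GAIT_F0_HZ = 1.4  # stride frequency


def _smooth_noise(n: int, fs: float, cutoff_hz: float, rng) -> np.ndarray:
    """Unit-RMS low-pass-filtered white noise (slow random modulation)."""
    x = rng.standard_normal(n)
    if n > 30:
        sos = sps.butter(2, cutoff_hz, fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def make_kinematics(duration_s: float, fs_kin: float, profile: str,
                    seed: int) -> KinematicTrace:
    """Generate a 3-D kinematic trace.

    ``gait`` — smooth quasi-periodic oscillation per axis: a stride-frequency
    sinusoid plus a weaker second harmonic, slowly amplitude-modulated, riding
    on a positive offset (a joint angle does not cross zero).  Amplitudes
    differ per axis with Y largest.  ``center_out_reach`` — piecewise
    minimum-jerk point-to-point moves between random workspace targets, with
    zero speed at segment boundaries.
    """
    if duration_s <= 0 or fs_kin <= 0:
        raise InvalidArgumentError("duration_s and fs_kin must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_kin))
    if n < 2:
        raise InvalidArgumentError("duration too short for the sampling rate")
    t = np.arange(n) / fs_kin

    if profile == "gait":
        pos = np.empty((n, 3))
        phase0 = rng.uniform(0, 2 * np.pi, size=3)
        phase2 = rng.uniform(0, 2 * np.pi, size=3)
        for ax, amp in enumerate(GAIT_AMPLITUDES):
            mod = 1.0 + 0.15 * _smooth_noise(n, fs_kin, 0.2, rng)
            osc = (np.sin(2 * np.pi * GAIT_F0_HZ * t + phase0[ax])
                   + 0.3 * np.sin(2 * np.pi * 2 * GAIT_F0_HZ * t + phase2[ax]))
            pos[:, ax] = amp * (1.2 + mod * osc)  # offset keeps the trace positive
    elif profile == "center_out_reach":
        move_s, hold_s = 0.8, 0.2
        pos = np.empty((n, 3))
        current = rng.uniform(-0.5, 0.5, size=3)
        i = 0
        while i < n:
            target = rng.uniform(-1.0, 1.0, size=3)
            n_move = int(round(move_s * fs_kin))
            n_hold = int(round(hold_s * fs_kin))
            tau = np.arange(min(n_move, n - i)) / n_move
            seg = current + np.outer(_min_jerk(tau), target - current)
            pos[i:i + len(seg)] = seg
            i += len(seg)
            if i < n:
                n_h = min(n_hold, n - i)
                pos[i:i + n_h] = target
                i += n_h
            current = target
    else:
        raise InvalidArgumentError(f"unknown kinematic profile {profile!r}")

    speed = np.gradient(pos, t, axis=0)
    return KinematicTrace(timestamps=t, position=pos, speed=speed,
                          effector_label=profile)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _one_over_f(n: int, n_channels: int, rms: float, rng,
                exponent: float = 1.0) -> np.ndarray:
    """Noise with 1/f^exponent magnitude spectrum, per-channel independent."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)  # amplitude ~ f^(-exp/2) => PSD ~ 1/f^exp
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    cur = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def kinematic_drive(kin: KinematicTrace, t: np.ndarray) -> np.ndarray:
    """Per-axis kinematic drive resampled to ``t`` and normalized to unit RMS.

    Normalizing each axis keeps the signal-to-noise presets comparable across
    kinematic profiles with different amplitude conventions.
    """
    drive = np.column_stack([
        np.interp(t, kin.timestamps, kin.position[:, a]) for a in range(3)]).T
    rms = np.sqrt(np.mean(drive ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return drive / rms


def synthesize_session(layout: ElectrodeArrayLayout, tuning: TuningMap,
                       kin: KinematicTrace, noise: NoiseModel, fs: float,
                       seed: int, band: tuple = HG_BAND,
                       dtype=np.float32) -> SessionRecording:
    """Render a multichannel voltage session from tuning map + kinematics.

    Per channel the movement-related component is a band-limited (70-150 Hz)
    unit-RMS noise carrier amplitude-modulated by
    ``baseline + sum_axis gain * |drive_axis|`` where the drive is the
    unit-RMS-normalized kinematics.  On top of that: 1/f background, a line
    sinusoid at 50 Hz and harmonics (shared phase across channels), a shared
    common-mode process, and independent white noise.
    """
    margin = 50.0
    if fs < 2 * (band[1] + margin):
        raise AliasingError(
            f"fs={fs} Hz too low for HG band top {band[1]} Hz (need >= {2*(band[1]+margin)})")
    if kin.t_end <= kin.t_start:
        raise InvalidArgumentError("kinematic trace is empty")
    rng = np.random.default_rng(seed)
    duration = kin.t_end - kin.t_start
    n = int(np.floor(duration * fs))
    t = np.arange(n) / fs + kin.t_start
    n_ch = layout.n_channels

    drive = kinematic_drive(kin, t)                      # (3, n)
    envelope = tuning.baseline_hg[:, None] + tuning.gains @ np.abs(drive)

    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    carrier /= np.sqrt(np.mean(carrier ** 2, axis=1, keepdims=True))
    x = envelope * carrier

    if noise.one_over_f_scale > 0:
        x += _one_over_f(n, n_ch, noise.one_over_f_scale, rng)
    if noise.line_amp > 0:
        line = np.zeros(n)
        for h in range(1, noise.n_harmonics + 1):
            f_h = noise.line_hz * h
            if f_h >= fs / 2:
                break
            line += (noise.line_amp / h) * np.sin(
                2 * np.pi * f_h * t + rng.uniform(0, 2 * np.pi))
        x += line[None, :]
    if noise.common_mode_amp > 0:
        cm = _one_over_f(n, 1, noise.common_mode_amp, rng)[0]
        x += cm[None, :]
    if noise.shared_hg_amp > 0:
        # Diffuse synchronous in-band background: one shared carrier with a
        # broad Gaussian weight profile.  Because the weights vary across the
        # array it is not fully removed by common average referencing, so
        # channels without local tuning remain mutually correlated in-band —
        # the signature of non-specific activity in low-contribution regions.
        shared = sps.sosfiltfilt(sos, rng.standard_normal(n))
        shared /= np.sqrt(np.mean(shared ** 2))
        center = layout.site_xy[rng.integers(layout.n_channels)]
        d2 = np.sum((layout.site_xy - center) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * noise.shared_hg_scale_mm ** 2))
        x += noise.shared_hg_amp * w[:, None] * shared[None, :]
    if noise.white_rms > 0:
        x += noise.white_rms * rng.standard_normal((n_ch, n))

    impedances = rng.uniform(0.2, 0.8, size=n_ch)  # healthy, below 1 MOhm
    return SessionRecording(signals=x.astype(dtype), fs=float(fs), t0=0.0,
                            impedances=impedances, layout=layout)


def inject_bad_channels(session: SessionRecording, fraction: float,
                        seed: int, bad_noise_rms: float = 300.0) -> SessionRecording:
    """Return a copy with ``round(fraction * n_channels)`` broken channels.

    Broken channels get an impedance above the 1 MOhm exclusion threshold and
    their signal replaced by high-amplitude white noise; the selection is
    uniform without replacement and reproducible from the seed.
    """
    if not (0 <= fraction < 1):
        raise InvalidArgumentError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = SessionRecording(
        signals=session.signals.copy(), fs=session.fs, t0=session.t0,
        impedances=session.impedances.copy(), layout=session.layout,
        channel_mask=session.channel_mask.copy(),
    )
    n_bad = int(round(fraction * session.n_channels))
    if n_bad == 0:
        return out
    bad = rng.choice(session.n_channels, size=n_bad, replace=False)
    out.impedances[bad] = rng.uniform(1.1, 3.0, size=n_bad)
    out.signals[bad] = (bad_noise_rms *
                        rng.standard_normal((n_bad, session.n_samples))
                        ).astype(session.signals.dtype)
    return out


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

CENTER_OUT_RADIUS = 0.7       # normalized screen units
WEBGRIDS_SHAPE = (15, 17)     # 255 cells


def _center_out_targets() -> np.ndarray:
    ang = 2 * np.pi * np.arange(8) / 8
    return CENTER_OUT_RADIUS * np.column_stack([np.cos(ang), np.sin(ang)])


def _webgrids_targets() -> np.ndarray:
    r, c = WEBGRIDS_SHAPE
    ys = np.linspace(-1, 1, r + 1)
    xs = np.linspace(-1, 1, c + 1)
    cy = (ys[:-1] + ys[1:]) / 2
    cx = (xs[:-1] + xs[1:]) / 2
    gx, gy = np.meshgrid(cx, cy)
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_trial_sequence(task: str, n_trials: int, seed: int) -> list:
    """Generate a trial sequence with the standard 4 s limit and 200 ms hold.

    Center-out draws targets in shuffled blocks of all 8 directions (every
    block balanced); webgrids draws uniformly from the 255 cells.
    """
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if task == "center_out":
        targets = _center_out_targets()
        order = []
        while len(order) < n_trials:
            order.extend(rng.permutation(8))
        ids = np.array(order[:n_trials])
    elif task == "webgrids":
        targets = _webgrids_targets()
        ids = rng.integers(0, 255, size=n_trials)
    else:
        raise InvalidArgumentError(f"unknown task {task!r}")
    return [TrialSpec(task=task, target_id=int(i), target_xy=targets[i])
            for i in ids]
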