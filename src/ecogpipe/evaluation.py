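"""Decoding metrics, closed-loop cursor tasks and statistical comparisons.

Metrics: per-axis Pearson CC between predicted and actual trajectories,
sliding-window in-session accuracy curves, the peak-to-peak/RMS signal-to-
noise ratio in decibels, and the target-selection bit rate

    BR = log2(N) * max(S - F, 0) / T

with N selectable targets, S successes, F failures and T the total task time
(timed-out trials count as failed and their full duration enters T).

The closed-loop simulator runs Center-out / Webgrids cursor trials at the
100-ms feature tick with "flexible fixturing" assistance: the commanded
velocity blends the decoded velocity with an attractor toward the target,
weighted by the assistance level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core_io import KinematicTrace
from .errors import InvalidArgumentError
from .synthetic import TrialSpec

TARGET_RADIUS = 0.12          # normalized screen units
ASSIST_GAIN = 1.5             # attractor speed, screen units / s
TICK_S = 0.1                  # one feature bin


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------

@dataclass
class CCResult:
    """Per-axis Pearson CC with an explicit undefined flag per axis.

    A constant trace on either side leaves that axis undefined (flag False,
    value NaN) rather than propagating a 0/0.
    """

    values: np.ndarray
    defined: np.ndarray

    def mean(self) -> float:
        if not self.defined.any():
            return float("nan")
        return float(np.mean(self.values[self.defined]))


def _trace_values(x) -> np.ndarray:
    if isinstance(x, KinematicTrace):
        return x.position
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def pearson_cc(pred, real) -> CCResult:
    """Per-axis Pearson correlation between predicted and actual trajectories."""
    p, r = _trace_values(pred), _trace_values(real)
    if p.shape != r.shape:
        raise InvalidArgumentError(f"shape mismatch {p.shape} vs {r.shape}")
    if len(p) < 3:
        raise InvalidArgumentError("need at least 3 samples")
    k = p.shape[1]
    values = np.full(k, np.nan)
    defined = np.zeros(k, dtype=bool)
    for j in range(k):
        if p[:, j].std() > 0 and r[:, j].std() > 0:
            values[j] = stats.pearsonr(p[:, j], r[:, j]).statistic
            defined[j] = True
    return CCResult(values=values, defined=defined)


def sliding_cc(pred, real, times: np.ndarray, window_s: float,
               step_s: float = None) -> tuple:
    """In-session accuracy curve: CC in half-open sliding windows.

    Returns ``(centers, ccs)`` with window-centre timestamps and per-axis CC
    per window (undefined axes NaN).
    """
    p, r = _trace_values(pred), _trace_values(real)
    times = np.asarray(times, dtype=float)
    if step_s is None:
        step_s = window_s / 3
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    duration = len(times) * dt   # each sample represents one bin of width dt
    if window_s > duration:
        raise InvalidArgumentError(
            f"window {window_s} s longer than trace duration {duration:.3f} s")
    n_win = int(np.floor((duration - window_s) / step_s + 1e-9)) + 1
    centers = np.empty(n_win)
    ccs = np.full((n_win, p.shape[1]), np.nan)
    for i in range(n_win):
        t0 = times[0] + i * step_s
        m = (times >= t0) & (times < t0 + window_s)
        centers[i] = t0 + window_s / 2
        if m.sum() >= 3:
            res = pearson_cc(p[m], r[m])
            ccs[i] = res.values
    return centers, ccs


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def snr_db(signals: np.ndarray, fs: float, envelope_cutoff_hz: float = 10.0,
           sustain_s: float = 0.1) -> np.ndarray:
    """Per-channel SNR: peak-to-peak of high-activity states over RMS of low.

    States are segmented from a rectified, low-pass (10 Hz) envelope: high =
    envelope above median + 2*MAD sustained for at least 100 ms, low =
    envelope below the median.  SNR = 20*log10(pp_high / rms_low) in dB;
    channels without both states come back NaN (undefined).
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    sos = sps.butter(4, envelope_cutoff_hz, fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(x), axis=1)
    out = np.full(x.shape[0], np.nan)
    # classify whole frames (the sustain duration) so the low-state RMS is
    # computed over complete oscillation cycles, not phase-selected samples
    frame = max(int(round(sustain_s * fs)), 1)
    n_frames = x.shape[1] // frame
    if n_frames < 2:
        return out
    for ch in range(x.shape[0]):
        e = env[ch, : n_frames * frame].reshape(n_frames, frame).mean(axis=1)
        med = np.median(e)
        mad = np.median(np.abs(e - med))
        high = e > med + 2 * mad
        low = e < med
        if not high.any() or not low.any():
            continue
        xf = x[ch, : n_frames * frame].reshape(n_frames, frame)
        pp_high = xf[high].max() - xf[high].min()
        rms_low = np.sqrt(np.mean(xf[low] ** 2))
        if rms_low > 0 and pp_high > 0:
            out[ch] = 20.0 * np.log10(pp_high / rms_low)
    return out


# ---------------------------------------------------------------------------
# Bit rate and trial adjudication
# ---------------------------------------------------------------------------

def bit_rate(n_targets: int, successes: int, failures: int,
             total_time_s: float) -> float:
    """Target-selection throughput: log2(N) * max(S - F, 0) / T, bits/s."""
    if n_targets < 1:
        raise InvalidArgumentError("n_targets must be >= 1")
    if successes < 0 or failures < 0:
        raise InvalidArgumentError("trial counts must be non-negative")
    if total_time_s <= 0:
        raise InvalidArgumentError("total_time_s must be positive")
    return np.log2(n_targets) * max(successes - failures, 0) / total_time_s


@dataclass
class TrialRecord:
    """Outcome of one cursor-task trial."""

    spec: TrialSpec
    t_start: float
    t_end: float
    success: bool
    cursor_path: np.ndarray      # (ticks, 2)
    time_to_target: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def adjudicate(trials: list, n_targets: int) -> tuple:
    """Tally (S, F, T, bit_rate) over a trial list.

    Timed-out trials are failures and their full duration counts in T.
    """
    if not trials:
        raise InvalidArgumentError("empty trial list")
    s = sum(1 for t in trials if t.success)
    f = len(trials) - s
    total = sum(t.duration for t in trials)
    return s, f, total, bit_rate(n_targets, s, f, total)


@dataclass
class MetricsReport:
    """Session-level decoding scorecard."""

    cc_per_axis: np.ndarray
    sliding_cc_times: np.ndarray = None
    sliding_cc_values: np.ndarray = None
    snr_db: np.ndarray = None
    bit_rate: float = None
    cv_norm: np.ndarray = None

    def to_dict(self) -> dict:
        def _conv(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        return {k: _conv(v) for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# Closed-loop cursor task
# ---------------------------------------------------------------------------

def toward_target_source(speed: float = 0.5, angle_sd: float = 0.6):
    """Synthetic user: velocity toward the target with Gaussian angular noise."""
    def source(cursor, target, rng):
        delta = target - cursor
        dist = np.linalg.norm(delta)
        if dist < 1e-12:
            return np.zeros(2)
        theta = np.arctan2(delta[1], delta[0]) + rng.normal(0, angle_sd)
        return speed * np.array([np.cos(theta), np.sin(theta)])
    return source


def random_walk_source(speed: float = 0.5):
    """Chance baseline: uniformly random heading each tick."""
    def source(cursor, target, rng):
        theta = rng.uniform(0, 2 * np.pi)
        return speed * np.array([np.cos(theta), np.sin(theta)])
    return source


def run_closed_loop(velocity_source, trials: list, alpha: float,
                    seed: int = 0, assist_gain: float = ASSIST_GAIN,
                    target_radius: float = TARGET_RADIUS,
                    tick_s: float = TICK_S) -> list:
    """Simulate cursor trials with flexible-fixturing assistance.

    Per tick the commanded velocity is ``(1 - alpha) * decoded +
    alpha * g * unit(target - cursor)``; the attractor speed is capped so a
    fully assisted cursor lands on the target instead of orbiting it.  A
    trial succeeds on a continuous 200-ms in-target dwell before the 4-s
    limit; otherwise it fails with the full limit charged to its duration.
    """
    if not (0 <= alpha <= 1):
        raise InvalidArgumentError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    t_clock = 0.0
    for spec in trials:
        target = np.asarray(spec.target_xy, dtype=float)
        cursor = np.zeros(2)
        path = [cursor.copy()]
        hold_ticks_needed = max(int(round(spec.hold_ms / 1000.0 / tick_s)), 1)
        max_ticks = int(round(spec.max_duration / tick_s))
        dwell = 0
        success = False
        time_to_target = None
        elapsed = spec.max_duration
        for k in range(max_ticks):
            decoded = np.asarray(velocity_source(cursor, target, rng), dtype=float)
            delta = target - cursor
            dist = np.linalg.norm(delta)
            if dist > 1e-12:
                assist_speed = min(assist_gain, dist / tick_s)
                assist = assist_speed * delta / dist
            else:
                assist = np.zeros(2)
            v = (1 - alpha) * decoded + alpha * assist
            cursor = np.clip(cursor + v * tick_s, -1.0, 1.0)
            path.append(cursor.copy())
            if np.linalg.norm(target - cursor) <= target_radius:
                if dwell == 0:
                    time_to_target = (k + 1) * tick_s
                dwell += 1
                if dwell >= hold_ticks_needed:
                    success = True
                    elapsed = (k + 1) * tick_s
                    break
            else:
                dwell = 0
                time_to_target = None
        records.append(TrialRecord(
            spec=spec, t_start=t_clock, t_end=t_clock + elapsed, success=success,
            cursor_path=np.asarray(path),
            time_to_target=time_to_target if success else None))
        t_clock += elapsed
    return records


# ---------------------------------------------------------------------------
# Statistical comparison
# ---------------------------------------------------------------------------

@dataclass
class PairedTestReport:
    test_name: str
    statistic: float
    pvalue: float
    normal_a: bool
    normal_b: bool
    equal_variance: bool


def paired_compare(group_a, group_b, alpha: float = 0.05) -> PairedTestReport:
    """Normality-gated paired comparison.

    Both groups are checked with Shapiro-Wilk and for variance homogeneity
    (Levene); the paired t-test is used only if all checks pass, otherwise
    the Wilcoxon signed-rank test (the rank-based test appropriate for
    paired samples).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("paired groups must have equal length")
    if len(a) < 5:
        raise InvalidArgumentError("need at least 5 pairs")
    norm_a = stats.shapiro(a).pvalue > alpha
    norm_b = stats.shapiro(b).pvalue > alpha
    eq_var = stats.levene(a, b).pvalue > alpha
    if np.allclose(a, b):
        # identical groups: no evidence of a difference under either test
        name = "paired t-test" if (norm_a and norm_b and eq_var) \
            else "wilcoxon signed-rank"
        return PairedTestReport(name, 0.0, 1.0, norm_a, norm_b, eq_var)
    if norm_a and norm_b and eq_var:
        res = stats.ttest_rel(a, b)
        name = "paired t-test"
    else:
        res = stats.wilcoxon(a, b)
        name = "wilcoxon signed-rank"
    return PairedTestReport(name, float(res.statistic), float(res.pvalue),
                            norm_a, norm_b, eq_var)


def normalized_cv(means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Coefficient of variation per condition, scaled to its maximum."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    cv = np.where(np.abs(means) > 0, sds / np.abs(means), np.nan)
    top = np.nanmax(cv)
    return cv / top if top and np.isfinite(top) and top > 0 else cv
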