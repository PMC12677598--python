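"""Spatial structure of motor encoding on the electrode grid.

Covers the array-level experiments: electrode-density subsets (stride
subsampling of the grid emulates coarser pitch over the same extent),
coverage subsets (centred k x k blocks emulate shrinking cortical coverage),
the two-stage channel-contribution algorithm (random-forest Gini importance
followed by a greedy accuracy curve), cross-session contribution maps,
pairwise high-gamma cross-correlation, and the high- versus low-contribution
4 x 4 subset comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.ensemble import RandomForestClassifier

from .core_io import ElectrodeArrayLayout
from .decoders import (KalmanDecoder, _as_state_array, decode_cc,
                       train_test_split_bins, STATE_DIM)
from .errors import DegenerateLabelsError, InvalidArgumentError
from .evaluation import normalized_cv, paired_compare
from .preprocessing import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Subset geometry
# ---------------------------------------------------------------------------

@dataclass
class SubsetSpec:
    """A resolved subset of grid channels."""

    kind: str                       # density_stride | centered_grid | explicit
    channel_indices: np.ndarray     # unique layout channel indices
    stride: int | None = None
    grid_size: int | None = None

    def __post_init__(self):
        self.channel_indices = np.asarray(self.channel_indices, dtype=int)
        if len(np.unique(self.channel_indices)) != len(self.channel_indices):
            raise InvalidArgumentError("subset channel indices must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_indices)

    def label(self) -> str:
        if self.kind == "density_stride":
            return f"stride-{self.stride}"
        if self.kind == "centered_grid":
            return f"grid-{self.grid_size}x{self.grid_size}"
        return f"explicit-{self.n_channels}ch"


def density_subsets(layout: ElectrodeArrayLayout,
                    strides=(8, 4, 2, 1)) -> list:
    """Stride subsampling anchored at the top-left site: same extent, lower density.

    On the 16x16 grid strides {8, 4, 2, 1} give densities {1, 4, 16, 64}
    channels/cm^2 over the same 2 cm x 2 cm area.
    """
    if layout.n_rows != layout.n_cols:
        raise InvalidArgumentError("density subsets require a square grid")
    out = []
    for s in strides:
        if not (1 <= s <= layout.n_rows):
            raise InvalidArgumentError(f"stride {s} outside grid of {layout.n_rows}")
        rows = np.arange(0, layout.n_rows, s)
        cols = np.arange(0, layout.n_cols, s)
        idx = (rows[:, None] * layout.n_cols + cols[None, :]).ravel()
        out.append(SubsetSpec(kind="density_stride", channel_indices=idx, stride=int(s)))
    return out


def centered_grid_subsets(layout: ElectrodeArrayLayout, sizes) -> list:
    """k x k blocks closest to the array centroid (ties shift toward top-left)."""
    out = []
    for k in sizes:
        if not (1 <= k <= min(layout.n_rows, layout.n_cols)):
            raise InvalidArgumentError(f"grid size {k} outside layout")
        r0 = (layout.n_rows - k) // 2
        c0 = (layout.n_cols - k) // 2
        rows = np.arange(r0, r0 + k)
        cols = np.arange(c0, c0 + k)
        idx = (rows[:, None] * layout.n_cols + cols[None, :]).ravel()
        out.append(SubsetSpec(kind="centered_grid", channel_indices=idx, grid_size=int(k)))
    return out


def _resolve_columns(features: FeatureMatrix, subset: SubsetSpec) -> np.ndarray:
    """Positions of the subset's channels among the feature columns."""
    pos = {int(cid): i for i, cid in enumerate(features.channel_ids)}
    cols = [pos[int(c)] for c in subset.channel_indices if int(c) in pos]
    return np.asarray(cols, dtype=int)


# ---------------------------------------------------------------------------
# Subsampling performance
# ---------------------------------------------------------------------------

@dataclass
class SubsamplePerformance:
    subsets: list
    mean_cc: np.ndarray          # (k,) mean-over-axes position CC
    sd_cc: np.ndarray
    cc_axes: np.ndarray          # (k, 3)
    cv_norm: np.ndarray          # CV scaled to its maximum across subsets
    undefined: np.ndarray        # subsets with too few channels to decode


def subsample_performance(features: FeatureMatrix, states, subsets,
                          n_repeats: int = 1, seed: int = 0,
                          split_ratio: float = 0.7,
                          session_factory=None) -> SubsamplePerformance:
    """Decoding accuracy and variability per channel subset.

    Per subset the features are column-restricted (the common-average
    reference was computed once over the full retained array, mirroring
    analysis of subsets of a single recorded session), the Kalman decoder is
    trained on the chronological 7:3 split and scored on the held-out bins.
    ``session_factory(seed) -> (features, states)`` regenerates the session
    with fresh noise per repeat; without it the evaluation is deterministic
    and repeats collapse to one.
    """
    subsets = list(subsets)
    k = len(subsets)
    reps = n_repeats if session_factory is not None else 1
    cc_rep = np.full((k, reps, 3), np.nan)
    undefined = np.zeros(k, dtype=bool)
    for r in range(reps):
        if session_factory is not None:
            fm, st = session_factory(seed + r)
        else:
            fm, st = features, states
        X = _as_state_array(st)
        tr, te = train_test_split_bins(fm.n_bins, split_ratio)
        for i, sub in enumerate(subsets):
            cols = _resolve_columns(fm, sub)
            if len(cols) < STATE_DIM:
                undefined[i] = True
                logger.warning("subset %s has %d channels (< state dim %d); undefined",
                               sub.label(), len(cols), STATE_DIM)
                continue
            fsub = fm.values[:, cols]
            res = KalmanDecoder(fsub[tr], (X[tr, 0:3], X[tr, 3:6]),
                                dt=fm.bin_ms / 1000.0).fit()
            cc_rep[i, r] = decode_cc(res, fsub[te], (X[te, 0:3], X[te, 3:6]))
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        cc_axes = np.nanmean(cc_rep, axis=1)
        mean_cc = np.nanmean(cc_axes, axis=1)
        per_rep_mean = np.nanmean(cc_rep, axis=2)      # (k, reps)
        sd_cc = np.nanstd(per_rep_mean, axis=1)
        cv = normalized_cv(mean_cc, sd_cc)
    mean_cc[undefined] = np.nan
    return SubsamplePerformance(subsets=subsets, mean_cc=mean_cc, sd_cc=sd_cc,
                                cc_axes=cc_axes, cv_norm=cv, undefined=undefined)


# ---------------------------------------------------------------------------
# Two-stage contribution algorithm
# ---------------------------------------------------------------------------

@dataclass
class ContributionResult:
    """Per-channel importance, accuracy curve and the optimal channel subset."""

    importance_per_axis: np.ndarray   # (3, n_channels), each row sums to 1
    importance_mean: np.ndarray       # (n_channels,)
    channel_ids: np.ndarray
    curve_sizes: np.ndarray = None    # subset sizes along the accuracy curve
    curve_cc: np.ndarray = None
    optimal_subset: np.ndarray = None  # channel ids at the curve peak


def rf_importance(features: FeatureMatrix, states, n_trees: int = 500,
                  n_classes: int = 3, seed: int = 0) -> ContributionResult:
    """Stage 1: normalized Gini importance of each channel, per kinematic axis.

    Gini impurity needs classes, so each continuous kinematic axis is
    discretized into tertiles (``n_classes`` quantile bins) and one
    classification forest is grown per axis.  Importances are the mean
    decrease in Gini impurity, normalized to sum to one per axis; the mean
    across axes is reported alongside.
    """
    X = _as_state_array(states)[:, 0:3]
    Z = features.values
    if len(Z) < 200:
        logger.warning("rf_importance on %d bins; recommend >= 200", len(Z))
    n_ch = Z.shape[1]
    per_axis = np.zeros((3, n_ch))
    for ax in range(3):
        qs = np.quantile(X[:, ax], np.linspace(0, 1, n_classes + 1)[1:-1])
        labels = np.digitize(X[:, ax], qs)
        if len(np.unique(labels)) < 2:
            raise DegenerateLabelsError(
                f"axis {ax} kinematics collapse to a single class")
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed + ax,
                                        n_jobs=1)
        forest.fit(Z, labels)
        imp = forest.feature_importances_
        total = imp.sum()
        per_axis[ax] = imp / total if total > 0 else np.full(n_ch, 1.0 / n_ch)
    return ContributionResult(importance_per_axis=per_axis,
                              importance_mean=per_axis.mean(axis=0),
                              channel_ids=np.asarray(features.channel_ids))


def optimal_subset(features: FeatureMatrix, states, importance: np.ndarray,
                   start_k: int = 5, split_ratio: float = 0.7,
                   dt: float | None = None) -> ContributionResult:
    """Stage 2: greedy accuracy curve over channels in descending importance.

    Starting from the ``start_k`` most important channels, channels are added
    one at a time in descending importance; decoding CC is recorded at each
    size and the optimal subset is the one at the curve's global peak (the
    smallest subset on ties).
    """
    if start_k < 1:
        raise InvalidArgumentError("start_k must be >= 1")
    importance = np.asarray(importance, dtype=float)
    Z = features.values
    n_ch = Z.shape[1]
    if importance.shape != (n_ch,):
        raise InvalidArgumentError("importance must have one value per feature channel")
    order = np.argsort(-importance, kind="stable")
    X = _as_state_array(states)
    tr, te = train_test_split_bins(len(Z), split_ratio)
    dt = dt if dt is not None else features.bin_ms / 1000.0
    sizes = np.arange(min(start_k, n_ch), n_ch + 1)
    curve = np.empty(len(sizes))
    for i, k in enumerate(sizes):
        cols = order[:k]
        res = KalmanDecoder(Z[tr][:, cols], (X[tr, 0:3], X[tr, 3:6]), dt=dt).fit()
        cc = decode_cc(res, Z[te][:, cols], (X[te, 0:3], X[te, 3:6]))
        curve[i] = np.nanmean(cc)
    peak = _first_peak(curve)             # first peak = smallest subset on ties
    best_cols = order[:sizes[peak]]
    return ContributionResult(
        importance_per_axis=None, importance_mean=importance,
        channel_ids=np.asarray(features.channel_ids),
        curve_sizes=sizes, curve_cc=curve,
        optimal_subset=np.asarray(features.channel_ids)[best_cols])


def _first_peak(curve: np.ndarray) -> int:
    """Index of the curve's global peak; the first (smallest subset) on ties.

    An all-undefined curve (e.g. pure-noise features where CC is undefined)
    falls back to index 0, i.e. the starting subset.
    """
    finite = np.isfinite(curve)
    if not finite.any():
        return 0
    best = np.nanmax(curve)
    return int(np.nonzero(np.isclose(curve, best) & finite)[0][0])


def contribution_map(results: list, n_channels: int) -> np.ndarray:
    """Cross-session contribution: optimal-subset frequency, max-normalized.

    Frequency = appearances in the per-session optimal subsets divided by the
    number of sessions, then scaled so the most frequent channel maps to 1.
    """
    if not results:
        raise InvalidArgumentError("need at least one session result")
    counts = np.zeros(n_channels)
    for res in results:
        counts[np.asarray(res.optimal_subset, dtype=int)] += 1
    freq = counts / len(results)
    top = freq.max()
    return freq / top if top > 0 else freq


# ---------------------------------------------------------------------------
# Inter-electrode high-gamma correlation
# ---------------------------------------------------------------------------

def hg_correlation(signals: np.ndarray, fs: float, band=(70.0, 150.0),
                   bin_s: float = 2.0, max_lag_s: float = 0.1) -> tuple:
    """Pairwise peak cross-correlation of band-passed signals in 2-s bins.

    Per bin and channel pair, the peak of the absolute normalized
    cross-correlation over lags within +/-100 ms is recorded.  Returns
    ``(peak_matrix, similarity, n_skipped)``: the bin-averaged pairwise peak
    matrix, per-channel similarity curves (mean peak against all paired
    channels per bin, z-scored per channel to remove amplitude effects), and
    the number of pair-bins skipped because a signal was flat.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n = x.shape
    if n_ch < 2:
        raise InvalidArgumentError("need at least 2 channels")
    L = int(round(bin_s * fs))
    if n < L:
        raise InvalidArgumentError("signal shorter than one bin")
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x, axis=1)
    n_bins = n // L
    max_lag = int(round(max_lag_s * fs))
    peaks = np.full((n_bins, n_ch, n_ch), np.nan)
    skipped = 0
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    sd_floor = 1e-10 * max(xb.std(), 1e-300)   # numerically flat after filtering
    for b in range(n_bins):
        seg = xb[:, b * L:(b + 1) * L]
        sd = seg.std(axis=1)
        sd[sd < sd_floor] = 0.0
        segz = (seg - seg.mean(axis=1, keepdims=True))
        segz[sd > 0] /= sd[sd > 0, None]
        F = np.fft.rfft(segz, n=nfft, axis=1)
        for i in range(n_ch):
            peaks[b, i, i] = 1.0
        for i, j in itertools.combinations(range(n_ch), 2):
            if sd[i] == 0 or sd[j] == 0:
                skipped += 1
                continue
            cc = np.fft.irfft(F[i] * np.conj(F[j]), n=nfft) / L
            window = np.concatenate([cc[-max_lag:], cc[:max_lag + 1]])
            peak = window[np.argmax(np.abs(window))]
            peaks[b, i, j] = peaks[b, j, i] = peak
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        peak_matrix = np.nanmean(peaks, axis=0)
        off = ~np.eye(n_ch, dtype=bool)
        sim = np.array([[np.nanmean(np.abs(peaks[b, i, off[i]]))
                         for b in range(n_bins)] for i in range(n_ch)])
        mu = np.nanmean(sim, axis=1, keepdims=True)
        sd_sim = np.nanstd(sim, axis=1, keepdims=True)
    sd_sim[sd_sim == 0] = 1.0
    similarity = (sim - mu) / sd_sim
    return peak_matrix, similarity, skipped


# ---------------------------------------------------------------------------
# High- vs low-contribution subset comparison
# ---------------------------------------------------------------------------

@dataclass
class SubsetComparison:
    high_subset: SubsetSpec
    low_subset: SubsetSpec
    high_mean_contribution: float
    low_mean_contribution: float
    high_hg_corr: float              # mean off-diagonal peak correlation
    low_hg_corr: float
    high_cc: np.ndarray              # per-repeat mean position CC
    low_cc: np.ndarray
    test_report: object


def _block_channels(layout, r0, c0, k):
    rows = np.arange(r0, r0 + k)
    cols = np.arange(c0, c0 + k)
    return (rows[:, None] * layout.n_cols + cols[None, :]).ravel()


def compare_contribution_subsets(contrib: np.ndarray, layout: ElectrodeArrayLayout,
                                 features: FeatureMatrix, states,
                                 signals: np.ndarray, fs: float,
                                 subset_size: int = 4, n_repeats: int = 5,
                                 seed: int = 0, band=(70.0, 150.0)) -> SubsetComparison:
    """Select the top-contribution k x k block and a lower-contribution neighbour.

    The high subset is the contiguous block with maximal mean contribution
    (row-major first block on ties, logged); the low subset is the adjacent
    non-overlapping block (shifted by the block size up/down/left/right) with
    the lowest mean contribution.  Reports the mean inter-electrode HG peak
    correlation within each subset, decoding CC per subset over repeated
    chronological splits, and the paired comparison across those splits.
    """
    contrib = np.asarray(contrib, dtype=float)
    grid = contrib.reshape(layout.n_rows, layout.n_cols)
    k = subset_size
    nr, nc = layout.n_rows - k + 1, layout.n_cols - k + 1
    if nr < 1 or nc < 1:
        raise InvalidArgumentError("subset size exceeds grid")
    means = np.array([[grid[r:r + k, c:c + k].mean() for c in range(nc)]
                      for r in range(nr)])
    flat_best = int(np.argmax(means))
    r_hi, c_hi = divmod(flat_best, nc)
    if np.count_nonzero(np.isclose(means, means.max())) > 1:
        logger.info("contribution block tie; picking the top-left block (%d, %d)",
                    r_hi, c_hi)
    neighbours = []
    for dr, dc in ((-k, 0), (k, 0), (0, -k), (0, k)):
        r2, c2 = r_hi + dr, c_hi + dc
        if 0 <= r2 <= layout.n_rows - k and 0 <= c2 <= layout.n_cols - k:
            m = grid[r2:r2 + k, c2:c2 + k].mean()
            if m < means[r_hi, c_hi] or np.isclose(m, means[r_hi, c_hi]):
                neighbours.append((m, r2, c2))
    if not neighbours:
        raise InvalidArgumentError(
            "no non-overlapping neighbouring block with lower contribution")
    m_lo, r_lo, c_lo = min(neighbours)
    high = SubsetSpec("explicit", _block_channels(layout, r_hi, c_hi, k))
    low = SubsetSpec("explicit", _block_channels(layout, r_lo, c_lo, k))

    def _mean_offdiag_corr(subset):
        chans = subset.channel_indices
        mat, _, _ = hg_correlation(signals[chans], fs, band=band)
        off = ~np.eye(len(chans), dtype=bool)
        return float(np.nanmean(np.abs(mat[off])))

    X = _as_state_array(states)
    ratios = np.linspace(0.6, 0.8, n_repeats)

    def _cc_over_splits(subset):
        cols = _resolve_columns(features, subset)
        out = np.empty(len(ratios))
        for i, ratio in enumerate(ratios):
            tr, te = train_test_split_bins(features.n_bins, ratio)
            res = KalmanDecoder(features.values[tr][:, cols],
                                (X[tr, 0:3], X[tr, 3:6]),
                                dt=features.bin_ms / 1000.0).fit()
            cc = decode_cc(res, features.values[te][:, cols],
                           (X[te, 0:3], X[te, 3:6]))
            out[i] = np.nanmean(cc)
        return out

    high_cc = _cc_over_splits(high)
    low_cc = _cc_over_splits(low)
    return SubsetComparison(
        high_subset=high, low_subset=low,
        high_mean_contribution=float(means[r_hi, c_hi]),
        low_mean_contribution=float(m_lo),
        high_hg_corr=_mean_offdiag_corr(high), low_hg_corr=_mean_offdiag_corr(low),
        high_cc=high_cc, low_cc=low_cc,
        test_report=paired_compare(high_cc, low_cc),
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_contribution_map(layout: ElectrodeArrayLayout, values: np.ndarray,
                          ax=None, cmap: str = "viridis"):
    """Heat map of a per-channel quantity on the physical grid layout."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    grid = np.asarray(values, dtype=float).reshape(layout.n_rows, layout.n_cols)
    extent_x = layout.pitch_mm * layout.n_cols / 2
    extent_y = layout.pitch_mm * layout.n_rows / 2
    im = ax.imshow(grid, cmap=cmap,
                   extent=[-extent_x, extent_x, -extent_y, extent_y])
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
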