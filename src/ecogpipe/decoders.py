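"""Kinematic decoders: position-velocity Kalman filter and optional LSTM.

The Kalman decoder follows the modelling-object convention: build a
:class:`KalmanDecoder` from a feature matrix and aligned kinematics, call
``fit()`` to obtain a :class:`KalmanResults` holding the closed-form
parameter estimates, then ``results.predict(features)`` to decode and
``results.summary()`` for a diagnostic table.  ``fit_kalman`` and
``kalman_decode`` are thin functional wrappers over the same objects.

Model
-----
State ``x = [px, py, pz, vx, vy, vz, 1]``: 3-D position, 3-D velocity and a
constant bias that absorbs feature offsets (z-scored features have zero mean
only on the training segment).  The transition encodes
``p_{t+1} = p_t + dt * v_t`` exactly; the velocity block and its process
noise are least-squares estimates from successive state pairs.  The
observation model is generative, ``z = H x + q`` with ``H`` and the noise
covariance ``Q`` fit by least squares of features on states — the standard
formulation for neural cursor filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import AlignedStreams, KinematicTrace
from .errors import DivergenceError, InvalidArgumentError, SingularFitError
from .preprocessing import FeatureMatrix

logger = logging.getLogger(__name__)

STATE_DIM = 7
_STATE_NAMES = ("px", "py", "pz", "vx", "vy", "vz", "bias")


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.atleast_2d(np.asarray(features, dtype=float))


def _as_state_array(states) -> np.ndarray:
    """Stack position, velocity and the constant bias column."""
    if isinstance(states, AlignedStreams):
        pos, vel = states.position, states.speed
    elif isinstance(states, KinematicTrace):
        pos, vel = states.position, states.speed
    else:
        pos, vel = states
    pos = np.asarray(pos, dtype=float)
    vel = np.asarray(vel, dtype=float)
    if pos.shape != vel.shape or pos.ndim != 2 or pos.shape[1] != 3:
        raise InvalidArgumentError("states must provide (n, 3) position and velocity")
    return np.column_stack([pos, vel, np.ones(len(pos))])


def _cc_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        sa, sb = a[:, j].std(), b[:, j].std()
        if sa > 0 and sb > 0:
            out[j] = np.corrcoef(a[:, j], b[:, j])[0, 1]
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class KalmanDecoder:
    """Position-velocity Kalman filter decoder (model object).

    Parameters
    ----------
    features : FeatureMatrix or (n_bins, n_features) array
        Z-scored neural features, one row per bin.
    states : AlignedStreams, KinematicTrace or (position, velocity) pair
        Kinematics aligned to the feature bins.
    dt : float
        Bin duration in seconds (default 0.1, the 100-ms feature bin).
    """

    def __init__(self, features, states, dt: float = 0.1):
        self.features = _as_feature_array(features)
        self.states = _as_state_array(states)
        if len(self.features) != len(self.states):
            raise InvalidArgumentError(
                f"{len(self.features)} feature bins vs {len(self.states)} state bins")
        if dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        self.dt = float(dt)
        self.n_features = self.features.shape[1]

    @classmethod
    def from_aligned(cls, features: FeatureMatrix,
                     aligned: AlignedStreams) -> "KalmanDecoder":
        """Build from a feature matrix and an alignment, intersecting bins."""
        idx = aligned.bin_index
        idx = idx[idx < features.n_bins]
        return cls(features.values[idx],
                   (aligned.position[:len(idx)], aligned.speed[:len(idx)]),
                   dt=features.bin_ms / 1000.0)

    def fit(self) -> "KalmanResults":
        """Closed-form least-squares estimation of A, W, H, Q."""
        X, Z = self.states, self.features
        n = len(X)
        if n < STATE_DIM * 10:
            warnings.warn(f"only {n} aligned bins; recommend >= {STATE_DIM * 10}",
                          stacklevel=2)
        stds = X[:, :6].std(axis=0)
        if np.any(stds == 0):
            dim = int(np.argmin(stds))
            raise SingularFitError(
                f"state dimension {_STATE_NAMES[dim]!r} is constant; "
                "cannot fit transition/observation models", deficient_dimension=dim)

        A = np.eye(STATE_DIM)
        A[0:3, 3:6] = self.dt * np.eye(3)
        V0, V1 = X[:-1, 3:6], X[1:, 3:6]
        Av, *_ = np.linalg.lstsq(V0, V1, rcond=None)
        A[3:6, 3:6] = Av.T
        resid_v = V1 - V0 @ Av
        W = np.zeros((STATE_DIM, STATE_DIM))
        W[3:6, 3:6] = (resid_v.T @ resid_v) / max(n - 1, 1)
        W[np.diag_indices_from(W)] += 1e-12

        Ht, *_ = np.linalg.lstsq(X, Z, rcond=None)
        H = Ht.T
        resid_z = Z - X @ Ht
        Q = (resid_z.T @ resid_z) / n
        ridge = max(1e-8, 1e-6 * float(np.mean(np.diag(Q))))
        Q[np.diag_indices_from(Q)] += ridge

        res = KalmanResults(model=self, A=A, W=W, H=H, Q=Q, dt=self.dt)
        res.training_cc = _cc_columns(
            res.predict(Z, check_psd=False).position, X[:, 0:3])
        return res


@dataclass
class KalmanResults:
    """Fitted position-velocity Kalman filter.

    Carries the closed-form estimates, decodes feature streams with the
    standard predict/update recursion (initial state zero, large diagonal
    covariance, fixed unit bias) and reports diagnostics via ``summary()``.
    """

    model: KalmanDecoder
    A: np.ndarray                # (7, 7) state transition
    W: np.ndarray                # (7, 7) process noise covariance
    H: np.ndarray                # (n_features, 7) observation matrix
    Q: np.ndarray                # (n_features, n_features) observation noise
    dt: float
    training_cc: np.ndarray = None
    burn_in_bins: int = 10       # excluded from CC scoring downstream

    def predict(self, features, check_psd: bool = False,
                gain_tol: float = 1e-9) -> KinematicTrace:
        """Decode a feature stream into a position/velocity trace.

        Runs predict (``x <- Ax``, ``P <- APA' + W``) and update (Kalman gain
        from ``H``, ``Q``) per bin.  Once the gain converges the steady-state
        gain is reused, which keeps long sessions cheap without changing the
        estimates beyond ``gain_tol``.
        """
        Z = _as_feature_array(features)
        if Z.size and Z.shape[1] != self.H.shape[0]:
            raise InvalidArgumentError(
                f"feature dim {Z.shape[1]} does not match observation model "
                f"{self.H.shape[0]}")
        n = len(Z) if Z.size else 0
        t = np.arange(1, n + 1) * self.dt
        if n == 0:
            empty = np.empty((0, 3))
            return KinematicTrace(timestamps=np.empty(0), position=empty,
                                  speed=empty, effector_label="decoded")
        bad = ~np.isfinite(Z).all(axis=1)
        if bad.any():
            raise InvalidArgumentError(
                f"non-finite features at bin index {int(np.nonzero(bad)[0][0])}")

        A, W, H, Q = self.A, self.W, self.H, self.Q
        x = np.zeros(STATE_DIM)
        x[6] = 1.0
        P = 10.0 * np.eye(STATE_DIM)
        P[6, 6] = 0.0
        K_prev = None
        frozen = False
        I = np.eye(STATE_DIM)
        out = np.empty((n, STATE_DIM))
        for i in range(n):
            x = A @ x
            if not frozen:
                P = A @ P @ A.T + W
                S = H @ P @ H.T + Q
                K = np.linalg.solve(S.T, (P @ H.T).T).T  # P H' S^-1
                P = (I - K @ H) @ P
                P = 0.5 * (P + P.T)
                if check_psd:
                    if np.linalg.eigvalsh(P).min() < -1e-6:
                        raise AssertionError(f"state covariance not PSD at bin {i}")
                if K_prev is not None and np.linalg.norm(K - K_prev) <= \
                        gain_tol * max(np.linalg.norm(K), 1.0):
                    frozen = True
                K_prev = K
            x = x + K_prev @ (Z[i] - H @ x)
            x[6] = 1.0
            out[i] = x
        return KinematicTrace(timestamps=t, position=out[:, 0:3],
                              speed=out[:, 3:6], effector_label="decoded")

    def summary(self) -> str:
        """Human-readable diagnostic table."""
        ev = np.abs(np.linalg.eigvals(self.A[3:6, 3:6]))
        lines = [
            "Position-velocity Kalman filter",
            "=" * 47,
            f"{'state dim':<28}{STATE_DIM} (3 pos + 3 vel + bias)",
            f"{'features':<28}{self.H.shape[0]}",
            f"{'training bins':<28}{len(self.model.features)}",
            f"{'bin duration dt':<28}{self.dt:.3f} s",
            f"{'velocity dynamics |eig|':<28}" + ", ".join(f"{e:.3f}" for e in ev),
            f"{'obs noise tr(Q)/F':<28}{np.trace(self.Q) / self.Q.shape[0]:.4g}",
        ]
        if self.training_cc is not None:
            cc = ", ".join(f"{c:.3f}" for c in self.training_cc)
            lines.append(f"{'training position CC':<28}{cc}")
        lines.append("=" * 47)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_kalman(features, states, dt: float = 0.1) -> KalmanResults:
    """Fit the position-velocity Kalman filter (wrapper over KalmanDecoder)."""
    return KalmanDecoder(features, states, dt=dt).fit()


def kalman_decode(results: KalmanResults, features, **kw) -> KinematicTrace:
    """Decode features with a fitted model (wrapper over results.predict)."""
    return results.predict(features, **kw)


def train_test_split_bins(n_bins: int, split_ratio: float = 0.7) -> tuple:
    """Chronological 7:3 split: (train_slice, test_slice)."""
    n_train = int(np.floor(split_ratio * n_bins))
    return slice(0, n_train), slice(n_train, n_bins)


def decode_cc(results: KalmanResults, features, states,
              burn_in: int | None = None) -> np.ndarray:
    """Per-axis position CC of decoded vs true states, excluding burn-in."""
    b = results.burn_in_bins if burn_in is None else burn_in
    pred = results.predict(features)
    true = _as_state_array(states)[:, 0:3]
    return _cc_columns(pred.position[b:], true[b:])


# ---------------------------------------------------------------------------
# Channel-dropout robustness
# ---------------------------------------------------------------------------

@dataclass
class DropoutCurve:
    fractions: np.ndarray        # (k,)
    mean_cc: np.ndarray          # (k, 3) per-axis mean over repeats
    sd_cc: np.ndarray            # (k, 3)


def eval_channel_dropout(results: KalmanResults, features, states,
                         drop_fractions, n_repeats: int = 5,
                         seed: int = 0) -> DropoutCurve:
    """Decoding CC when a random share of channels is zeroed at test time.

    Zeroing a z-scored feature column pins it at its training mean, emulating
    a silently lost channel.  Fraction 0 reproduces the baseline exactly.
    """
    fractions = np.asarray(list(drop_fractions), dtype=float)
    if np.any((fractions < 0) | (fractions >= 1)):
        raise InvalidArgumentError("drop fractions must be in [0, 1)")
    Z = _as_feature_array(features)
    rng = np.random.default_rng(seed)
    n_ch = Z.shape[1]
    mean = np.empty((len(fractions), 3))
    sd = np.empty((len(fractions), 3))
    for i, frac in enumerate(fractions):
        n_drop = int(round(frac * n_ch))
        ccs = []
        reps = 1 if n_drop == 0 else n_repeats
        for _ in range(reps):
            Zr = Z.copy()
            if n_drop:
                drop = rng.choice(n_ch, size=n_drop, replace=False)
                Zr[:, drop] = 0.0
            ccs.append(decode_cc(results, Zr, states))
        ccs = np.asarray(ccs)
        mean[i] = ccs.mean(axis=0)
        sd[i] = ccs.std(axis=0)
    return DropoutCurve(fractions=fractions, mean_cc=mean, sd_cc=sd)


# ---------------------------------------------------------------------------
# Optional recurrent decoder
# ---------------------------------------------------------------------------

@dataclass
class RNNConfig:
    """Training configuration for the recurrent decoder."""

    layer_sizes: tuple = (300, 100, 50)
    lr: float = 1e-3
    l2_weight: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 32
    bptt_window: int = 50        # bins per truncated-BPTT sequence
    patience: int = 10           # early-stopping patience, epochs
    split_ratio: float = 0.7
    seed: int = 0


@dataclass
class RNNModel:
    config: RNNConfig
    output_dim: int
    state_dict: dict             # trained weights (opaque)
    training_log: list           # (epoch, train_loss, val_loss)
    best_epoch: int


def fit_rnn(features, states, config: RNNConfig | None = None) -> RNNModel:
    """Train the three-layer (300/100/50) LSTM decoder with early stopping.

    Requires the optional ``torch`` dependency (``pip install ecogpipe[rnn]``);
    the Kalman path is the dependency-light decoder used by the analysis
    experiments.
    """
    try:
        import torch
        from torch import nn
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the recurrent decoder requires torch; install ecogpipe[rnn] "
            "or use the Kalman decoder") from exc

    cfg = config or RNNConfig()
    Z = _as_feature_array(features)
    X = _as_state_array(states)[:, 0:6]
    n = len(Z)
    if n < 500:
        warnings.warn(f"only {n} bins; recommend >= 500 for RNN training",
                      stacklevel=2)
    torch.manual_seed(cfg.seed)

    class _Net(nn.Module):
        def __init__(self, n_in, n_out):
            super().__init__()
            sizes = cfg.layer_sizes
            self.l1 = nn.LSTM(n_in, sizes[0], batch_first=True)
            self.l2 = nn.LSTM(sizes[0], sizes[1], batch_first=True)
            self.l3 = nn.LSTM(sizes[1], sizes[2], batch_first=True)
            self.out = nn.Linear(sizes[2], n_out)

        def forward(self, x):
            x, _ = self.l1(x)
            x, _ = self.l2(x)
            x, _ = self.l3(x)
            return self.out(x)

    net = _Net(Z.shape[1], X.shape[1])
    opt = torch.optim.Adam(net.parameters(), lr=cfg.lr,
                           weight_decay=cfg.l2_weight)
    loss_fn = nn.MSELoss()

    w = cfg.bptt_window
    starts = np.arange(0, n - w, w)
    n_train = int(np.floor(cfg.split_ratio * len(starts)))
    tr_starts, va_starts = starts[:n_train], starts[n_train:]

    def _batchify(idx):
        zs = torch.tensor(np.stack([Z[s:s + w] for s in idx]), dtype=torch.float32)
        xs = torch.tensor(np.stack([X[s:s + w] for s in idx]), dtype=torch.float32)
        return zs, xs

    log, best_val, best_state, best_epoch, stall = [], np.inf, None, 0, 0
    gen = np.random.default_rng(cfg.seed)
    for epoch in range(cfg.max_epochs):
        net.train()
        order = gen.permutation(tr_starts)
        tr_losses = []
        for i in range(0, len(order), cfg.batch_size):
            zs, xs = _batchify(order[i:i + cfg.batch_size])
            opt.zero_grad()
            loss = loss_fn(net(zs), xs)
            if not torch.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            tr_losses.append(float(loss))
        net.eval()
        with torch.no_grad():
            zs, xs = _batchify(va_starts)
            val = float(loss_fn(net(zs), xs))
        log.append((epoch, float(np.mean(tr_losses)), val))
        if val < best_val:
            best_val, best_epoch, stall = val, epoch, 0
            best_state = {k: v.clone() for k, v in net.state_dict().items()}
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return RNNModel(config=cfg, output_dim=X.shape[1], state_dict=best_state,
                    training_log=log, best_epoch=best_epoch)
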