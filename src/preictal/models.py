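"""Classifiers: a 3-cell LSTM with a 2-unit softmax readout, and gradient-boosted trees.

The LSTM cell follows the standard gated recurrence

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
    o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
    c_t = f_t (.) c_{t-1} + i_t (.) tanh(W_c x_t + U_c h_{t-1} + b_c)
    h_t = o_t (.) tanh(c_t)

with (.) the Hadamard product, followed by a dense layer with two units and a
softmax. The state is reset to zero for every input sample, so each
classification sees only its own n-window history. Total parameter count is
4*((F+1)*C + C^2) + 2*C + 2 for F input features and C cells.

Training is class-weighted cross-entropy with 20% dropout on the input (W)
and recurrent (U) contributions, optimized with Adadelta. The network is
implemented directly in numpy (it is tiny -- three cells); gradients are
exact backpropagation-through-time and are verified against finite
differences in the test suite.

The gradient-boosted-tree route (XGBoost, depth-3 trees, logistic objective,
positive-class weight equal to the class imbalance ratio) treats the windows
of a history as time-independent features and supplies gain-based feature
importances for band/group/site-level aggregation and feature-subset
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import N_BANDS
from .features import parse_feature_name

__all__ = [
    "LstmConfig",
    "LstmParams",
    "lstm_param_count",
    "init_lstm_params",
    "lstm_step",
    "lstm_forward",
    "lstm_loss_and_grads",
    "train_lstm",
    "predict_proba",
    "GbtConfig",
    "flatten_samples",
    "train_gbt",
    "ImportanceReport",
    "aggregate_importance",
    "REDUCED_POWER_BANDS",
    "REDUCED_COHERENCE_BANDS",
    "select_reduced_features",
]

_GATES = ("f", "i", "o", "c")  # slices of the packed 4C axis


def lstm_param_count(n_features: int, n_cells: int) -> int:
    """4*((F+1)*C + C^2) + 2*C + 2 parameters for the LSTM plus dense readout."""
    if n_features < 0 or n_cells < 1:
        raise ValueError("need n_features >= 0 and n_cells >= 1")
    return 4 * ((n_features + 1) * n_cells + n_cells**2) + 2 * n_cells + 2


@dataclass
class LstmParams:
    """Packed gate parameters; per-gate views via :meth:`W`, :meth:`U`, :meth:`b_gate`."""

    Wx: np.ndarray  # (F, 4C) input weights, gate order f,i,o,c
    Wh: np.ndarray  # (C, 4C) recurrent weights
    b: np.ndarray  # (4C,)
    D: np.ndarray  # (C, 2) dense readout
    d: np.ndarray  # (2,)

    @property
    def n_cells(self) -> int:
        return self.Wh.shape[0]

    @property
    def n_features(self) -> int:
        return self.Wx.shape[0]

    def _sl(self, gate: str) -> slice:
        g = _GATES.index(gate)
        c = self.n_cells
        return slice(g * c, (g + 1) * c)

    def W(self, gate: str) -> np.ndarray:
        """Input weight matrix W_gate, shape (cells, features)."""
        return self.Wx[:, self._sl(gate)].T

    def U(self, gate: str) -> np.ndarray:
        """Recurrent weight matrix U_gate, shape (cells, cells)."""
        return self.Wh[:, self._sl(gate)].T

    def b_gate(self, gate: str) -> np.ndarray:
        return self.b[self._sl(gate)]

    @property
    def n_params(self) -> int:
        return sum(a.size for a in (self.Wx, self.Wh, self.b, self.D, self.d))

    def arrays(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b, "D": self.D, "d": self.d}


def init_lstm_params(
    n_features: int, n_cells: int = 3, seed: int = 0, forget_bias: float = 1.0
) -> LstmParams:
    """Glorot-uniform weights, zero biases except a unit forget-gate bias."""
    rng = np.random.default_rng(seed)

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, shape)

    b = np.zeros(4 * n_cells)
    b[: n_cells] = forget_bias
    return LstmParams(
        Wx=glorot((n_features, 4 * n_cells)),
        Wh=glorot((n_cells, 4 * n_cells)),
        b=b,
        D=glorot((n_cells, 2)),
        d=np.zeros(2),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LstmParams):
    """One cell update; returns (h_t, c_t). Accepts (F,) vectors or (B, F) batches."""
    x_t = np.atleast_2d(x_t)
    h_prev = np.atleast_2d(h_prev)
    c_prev = np.atleast_2d(c_prev)
    if x_t.shape[1] != p.n_features or h_prev.shape[1] != p.n_cells:
        raise ValueError("dimension mismatch between input/state and parameters")
    C = p.n_cells
    z = x_t @ p.Wx + h_prev @ p.Wh + p.b
    f = _sigmoid(z[:, :C])
    i = _sigmoid(z[:, C : 2 * C])
    o = _sigmoid(z[:, 2 * C : 3 * C])
    g = np.tanh(z[:, 3 * C :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return np.squeeze(h), np.squeeze(c)


def _forward(p: LstmParams, X: np.ndarray, mx=None, mh=None, keep_cache=False):
    """Run the recurrence from zero state over X (B, T, F); softmax probabilities."""
    B, T, F = X.shape
    C = p.n_cells
    h = np.zeros((B, C))
    c = np.zeros((B, C))
    cache = []
    for t in range(T):
        xd = X[:, t, :] if mx is None else X[:, t, :] * mx
        hd = h if mh is None else h * mh
        z = xd @ p.Wx + hd @ p.Wh + p.b
        f = _sigmoid(z[:, :C])
        i = _sigmoid(z[:, C : 2 * C])
        o = _sigmoid(z[:, 2 * C : 3 * C])
        g = np.tanh(z[:, 3 * C :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if keep_cache:
            cache.append((xd, hd, f, i, o, g, c, tc))
        h, c = h_new, c_new
    logits = h @ p.D + p.d
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, h, cache


def lstm_forward(p: LstmParams, X: np.ndarray) -> np.ndarray:
    """Class probabilities (interictal, preictal) for histories X (B, T, F) or (T, F)."""
    single = X.ndim == 2
    X3 = X[None] if single else X
    probs, _, _ = _forward(p, X3)
    return probs[0] if single else probs


def lstm_loss_and_grads(p: LstmParams, X: np.ndarray, y: np.ndarray, w: np.ndarray, mx=None, mh=None):
    """Weighted cross-entropy and exact BPTT gradients for a batch."""
    B, T, F = X.shape
    C = p.n_cells
    probs, hT, cache = _forward(p, X, mx, mh, keep_cache=True)
    wsum = w.sum()
    loss = float(-(w * np.log(probs[np.arange(B), y] + 1e-300)).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    g = {k: np.zeros_like(v) for k, v in p.arrays().items()}
    g["D"] = hT.T @ dlogits
    g["d"] = dlogits.sum(axis=0)
    dh = dlogits @ p.D.T
    dc = np.zeros((B, C))
    for t in range(T - 1, -1, -1):
        xd, hd, f, i, o, gg, c_prev, tc = cache[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        df = dc * c_prev
        di = dc * gg
        dg = dc * i
        dz = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), do * o * (1 - o), dg * (1 - gg**2)], axis=1
        )
        g["Wx"] += xd.T @ dz
        g["Wh"] += hd.T @ dz
        g["b"] += dz.sum(axis=0)
        dh_raw = dz @ p.Wh.T
        dh = dh_raw if mh is None else dh_raw * mh
        dc = dc * f
    return loss, g


@dataclass
class LstmConfig:
    n_cells: int = 3
    dropout: float = 0.2  # on both the W (input) and U (recurrent) contributions
    epochs: int = 30
    batch_size: int = 64
    patience: int = 6
    min_delta: float = 1e-4  # relative training-loss improvement for early stop
    rho: float = 0.95  # Adadelta decay
    eps: float = 1e-7
    seed: int = 0


def train_lstm(
    X: np.ndarray,
    y: np.ndarray,
    class_weight: dict[int, float] | None = None,
    cfg: LstmConfig = LstmConfig(),
) -> tuple[LstmParams, list[float]]:
    """Fit the LSTM on histories X (B, T, F) with labels y in {0, 1}.

    Returns the fitted parameters and the per-epoch training-loss trace.
    Dropout masks are drawn once per sequence per epoch; inference uses no
    dropout. Raises on divergence (non-finite loss).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if class_weight is None:
        class_weight = {0: 1.0, 1: 1.0}
    w_all = np.array([class_weight[int(t)] for t in y], dtype=float)
    B, T, F = X.shape
    rng = np.random.default_rng(cfg.seed)
    p = init_lstm_params(F, cfg.n_cells, seed=int(rng.integers(2**31 - 1)))
    acc_g = {k: np.zeros_like(v) for k, v in p.arrays().items()}
    acc_dx = {k: np.zeros_like(v) for k, v in p.arrays().items()}
    losses: list[float] = []
    best = np.inf
    stale = 0
    keep = 1.0 - cfg.dropout
    for _epoch in range(cfg.epochs):
        order = rng.permutation(B)
        ep_loss = 0.0
        ep_w = 0.0
        for s in range(0, B, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            mx = mh = None
            if cfg.dropout > 0:
                mx = rng.uniform(size=(idx.size, F)) < keep
                mh = rng.uniform(size=(idx.size, cfg.n_cells)) < keep
                mx = mx.astype(float) / keep
                mh = mh.astype(float) / keep
            loss, grads = lstm_loss_and_grads(p, X[idx], y[idx], w_all[idx], mx, mh)
            if not np.isfinite(loss):
                raise FloatingPointError("LSTM training diverged (non-finite loss)")
            arrays = p.arrays()
            for k in arrays:
                gk = grads[k]
                acc_g[k] = cfg.rho * acc_g[k] + (1 - cfg.rho) * gk**2
                step = -np.sqrt(acc_dx[k] + cfg.eps) / np.sqrt(acc_g[k] + cfg.eps) * gk
                acc_dx[k] = cfg.rho * acc_dx[k] + (1 - cfg.rho) * step**2
                arrays[k] += step
            bw = w_all[idx].sum()
            ep_loss += loss * bw
            ep_w += bw
        ep_loss /= ep_w
        losses.append(ep_loss)
        if ep_loss < best * (1 - cfg.min_delta):
            best = ep_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return p, losses


def predict_proba(p: LstmParams, X: np.ndarray) -> np.ndarray:
    """Preictal probability per history."""
    return lstm_forward(p, np.asarray(X, dtype=float))[..., 1]


# ---------------------------------------------------------------------------
# gradient-boosted trees


@dataclass
class GbtConfig:
    max_depth: int = 3
    rounds: int = 100  # boosting rounds (no validation set exists for early stopping)
    eta: float = 0.3
    scale_pos_weight: float | None = None  # None -> class imbalance ratio of the data
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.scale_pos_weight is not None and self.scale_pos_weight <= 0:
            raise ValueError("scale_pos_weight must be positive")


@dataclass
class ImportanceReport:
    """Per-feature gain importances, normalized to sum to one."""

    table: pd.DataFrame  # columns: feature, base_feature, importance

    def by_base_feature(self) -> pd.Series:
        return self.table.groupby("base_feature")["importance"].sum()


def flatten_samples(X: np.ndarray, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Histories (B, T, F) -> (B, T*F); window positions become independent columns."""
    B, T, F = X.shape
    names = [f"{c}@t{t}" for t in range(T) for c in columns]
    return X.reshape(B, T * F), names


def train_gbt(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    cfg: GbtConfig = GbtConfig(),
):
    """Fit XGBoost (binary logistic, depth-3 trees, imbalance-weighted).

    Returns (booster, ImportanceReport). Feature names may carry a window
    suffix ``@t<k>``; importances aggregate over it in ``base_feature``.
    """
    import xgboost as xgb

    y = np.asarray(y, dtype=int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    spw = cfg.scale_pos_weight if cfg.scale_pos_weight is not None else n0 / n1
    safe = [n.replace("[", "(").replace("]", ")").replace("<", "lt") for n in feature_names]
    dtrain = xgb.DMatrix(np.asarray(X, dtype=np.float32), label=y, feature_names=safe)
    booster = xgb.train(
        {
            "max_depth": cfg.max_depth,
            "objective": "binary:logistic",
            "scale_pos_weight": spw,
            "eta": cfg.eta,
            "seed": cfg.seed,
            "nthread": 1,
            "verbosity": 0,
        },
        dtrain,
        num_boost_round=cfg.rounds,
    )
    score = booster.get_score(importance_type="total_gain")
    imp = np.array([score.get(n, 0.0) for n in safe], dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    table = pd.DataFrame(
        {
            "feature": feature_names,
            "base_feature": [n.split("@t")[0] for n in feature_names],
            "importance": imp,
        }
    )
    return booster, ImportanceReport(table)


def gbt_predict(booster, X: np.ndarray, feature_names: list[str]) -> np.ndarray:
    import xgboost as xgb

    safe = [n.replace("[", "(").replace("]", ")").replace("<", "lt") for n in feature_names]
    return booster.predict(xgb.DMatrix(np.asarray(X, dtype=np.float32), feature_names=safe))


def aggregate_importance(
    report: ImportanceReport, by: str, channel_grid: np.ndarray | None = None
) -> pd.Series | np.ndarray:
    """Aggregate importances by frequency band, feature group, or array site.

    ``band`` and ``group`` aggregates sum to 1; the ``site`` aggregate is
    ranked to a 0..1 scale (max site = 1) and, when ``channel_grid`` is
    given, returned as a 2-D map over the electrode array.
    """
    base = report.by_base_feature()
    tags = [parse_feature_name(n) for n in base.index]
    if by == "band":
        s = pd.Series(0.0, index=range(N_BANDS))
        for t, v in zip(tags, base.values):
            if t["band"] is not None:
                s[t["band"]] += v
        return s / s.sum() if s.sum() > 0 else s
    if by == "group":
        s: dict[str, float] = {}
        for t, v in zip(tags, base.values):
            s[t["group"]] = s.get(t["group"], 0.0) + v
        out = pd.Series(s)
        return out / out.sum() if out.sum() > 0 else out
    if by == "site":
        chans = [t["channel"] for t in tags if t["channel"] is not None]
        n_ch = max(chans) + 1
        s = np.zeros(n_ch)
        for t, v in zip(tags, base.values):
            if t["channel"] is not None:
                s[t["channel"]] += v
        if s.max() > 0:
            s = s / s.max()
        if channel_grid is None:
            return s
        side = int(channel_grid.max()) + 1
        grid = np.zeros((side, side))
        for c in range(n_ch):
            r, col = channel_grid[c]
            grid[r, col] = s[c]
        return grid
    raise ValueError("by must be 'band', 'group' or 'site'")


#: LFP power bands kept in the reduced feature subset (50-80, 80-150 Hz)
REDUCED_POWER_BANDS = (6, 7)
#: coherence-eigenvector bands kept in the reduced subset (0.3-4, 300-500 Hz)
REDUCED_COHERENCE_BANDS = (0, 9)


def select_reduced_features(columns: list[str]) -> list[str]:
    """The reduced feature subset identified by tree-based importance ranking.

    LFP power in the 50-80 and 80-150 Hz bands, coherence eigenvectors in the
    0.3-4 and 300-500 Hz bands, per-channel MUA totals, and the
    MUA-envelope correlation eigenvector: 6 x n_channels features.
    """
    want = []
    have_groups = set()
    for c in columns:
        t = parse_feature_name(c)
        have_groups.add(t["group"])
        if t["group"] == "lfp_power" and t["band"] in REDUCED_POWER_BANDS:
            want.append(c)
        elif t["group"] == "lfp_coherence" and t["kind"] == "ev" and t["band"] in REDUCED_COHERENCE_BANDS:
            want.append(c)
        elif t["group"] == "mua_count":
            want.append(c)
        elif t["group"] == "mua_correlation" and t["source"] == "env" and t["kind"] == "ev":
            want.append(c)
    missing = set(GROUPS_REQUIRED) - have_groups
    if missing:
        raise ValueError(f"reduced subset needs all feature groups; missing {sorted(missing)}")
    return want


GROUPS_REQUIRED = ("lfp_power", "lfp_coherence", "mua_count", "mua_correlation")
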