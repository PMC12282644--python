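"""Single-cell GRU / LSTM binary sequence classifiers.

Pure-NumPy implementation (one recurrent cell, a fully connected sigmoid
head, binary cross-entropy, Adam) so training is deterministic under the
seed and has no GPU/toolkit dependency.  Scale is the synthetic-cohort
scale; the backward pass is verified against numerical gradients in the
test suite.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .errors import ContractError, ProtocolError
from .pose_features import PoseWindow
from .physio_models import MetricsReport


@dataclass
class SequenceModelSpec:
    cell: str = "gru"            # 'gru' | 'lstm'
    input_dim: int = 52
    hidden_dim: int = 64
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    #: keep every n-th frame of each window before the cell (scale control)
    time_subsample: int = 1
    threshold: float = 0.5

    def validate(self) -> "SequenceModelSpec":
        if self.cell not in ("gru", "lstm"):
            raise ContractError(f"unknown cell {self.cell!r}")
        if self.input_dim <= 0 or self.hidden_dim <= 0:
            raise ContractError("dims must be positive")
        return self


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


class RecurrentBinaryClassifier:
    """One GRU or LSTM cell plus a sigmoid head, trained with Adam on BCE."""

    def __init__(self, spec: SequenceModelSpec):
        self.spec = spec.validate()
        rng = np.random.default_rng(spec.seed)
        d, h = spec.input_dim, spec.hidden_dim
        n_gates = 3 if spec.cell == "gru" else 4
        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))
        self.params = {
            "W": glorot(d, n_gates * h),      # input-to-gates
            "U": glorot(h, n_gates * h),      # hidden-to-gates
            "b": np.zeros(n_gates * h),
            "w_out": glorot(h, 1),
            "b_out": np.zeros(1),
        }
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in self.params.items()}
        self._adam_t = 0
        self._rng = rng
        self.mu_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None
        self.loss_history_: list[float] = []

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        """X: (batch, T, d) standardized. Returns final hidden state (+cache)."""
        B, T, d = X.shape
        h_dim = self.spec.hidden_dim
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, h_dim))
        cache = []
        if self.spec.cell == "gru":
            for t in range(T):
                g = X[:, t] @ W + h @ U + b
                z = _sigmoid(g[:, :h_dim])
                r = _sigmoid(g[:, h_dim:2 * h_dim])
                # candidate uses the reset-gated hidden state
                n_pre = X[:, t] @ W[:, 2 * h_dim:] + (r * h) @ U[:, 2 * h_dim:] + b[2 * h_dim:]
                n = np.tanh(n_pre)
                h_new = (1.0 - z) * h + z * n
                if keep_cache:
                    cache.append((h, z, r, n))
                h = h_new
            return (h, cache) if keep_cache else h
        c = np.zeros((B, h_dim))
        for t in range(T):
            g = X[:, t] @ W + h @ U + b
            i = _sigmoid(g[:, :h_dim])
            f = _sigmoid(g[:, h_dim:2 * h_dim])
            o = _sigmoid(g[:, 2 * h_dim:3 * h_dim])
            gg = np.tanh(g[:, 3 * h_dim:])
            c_new = f * c + i * gg
            h_new = o * np.tanh(c_new)
            if keep_cache:
                cache.append((h, c, i, f, o, gg, c_new))
            h, c = h_new, c_new
        return (h, cache) if keep_cache else h

    # -- backward ----------------------------------------------------------

    def _backward(self, X: np.ndarray, y: np.ndarray):
        """Mean-BCE gradients for a standardized batch. Returns (loss, grads)."""
        B, T, _ = X.shape
        h_dim = self.spec.hidden_dim
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h_T, cache = self._forward(X, keep_cache=True)
        logits = (h_T @ self.params["w_out"] + self.params["b_out"]).ravel()
        p = _sigmoid(logits)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogit = ((p - y) / B)[:, None]                       # (B, 1)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["w_out"] = h_T.T @ dlogit
        grads["b_out"] = dlogit.sum(axis=0)
        dh = dlogit @ self.params["w_out"].T                  # (B, h)
        if self.spec.cell == "gru":
            for t in range(T - 1, -1, -1):
                h_prev, z, r, n = cache[t]
                dz = dh * (n - h_prev) * z * (1 - z)
                dn = dh * z * (1 - n**2)
                dr = (dn @ U[:, 2 * h_dim:].T) * h_prev * r * (1 - r)
                dg = np.concatenate([dz, dr], axis=1)
                grads["W"][:, :2 * h_dim] += X[:, t].T @ dg
                grads["U"][:, :2 * h_dim] += h_prev.T @ dg
                grads["b"][:2 * h_dim] += dg.sum(axis=0)
                grads["W"][:, 2 * h_dim:] += X[:, t].T @ dn
                grads["U"][:, 2 * h_dim:] += (r * h_prev).T @ dn
                grads["b"][2 * h_dim:] += dn.sum(axis=0)
                dh = (
                    dh * (1 - z)
                    + (dg @ U[:, :2 * h_dim].T)
                    + (dn @ U[:, 2 * h_dim:].T) * r
                )
        else:
            dc = np.zeros_like(dh)
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, o, gg, c_new = cache[t]
                tanh_c = np.tanh(c_new)
                do = dh * tanh_c * o * (1 - o)
                dc = dc + dh * o * (1 - tanh_c**2)
                di = dc * gg * i * (1 - i)
                df = dc * c_prev * f * (1 - f)
                dgg = dc * i * (1 - gg**2)
                dg = np.concatenate([di, df, do, dgg], axis=1)
                grads["W"] += X[:, t].T @ dg
                grads["U"] += h_prev.T @ dg
                grads["b"] += dg.sum(axis=0)
                dh = dg @ U.T
                dc = dc * f
        return loss, grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m, v = self._adam[k]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mh = m / (1 - b1**self._adam_t)
            vh = v / (1 - b2**self._adam_t)
            self.params[k] -= lr * mh / (np.sqrt(vh) + eps)

    # -- public API --------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.time_subsample > 1:
            X = X[:, :: self.spec.time_subsample]
        if self.mu_ is not None:
            X = (X - self.mu_) / self.sd_
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RecurrentBinaryClassifier":
        """X: (n, T, input_dim) raw features, y: 0/1 labels."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.spec.input_dim:
            raise ContractError(f"expected (n, T, {self.spec.input_dim}) input, got {X.shape}")
        if self.spec.time_subsample > 1:
            X = X[:, :: self.spec.time_subsample]
        flat = X.reshape(-1, X.shape[2])
        self.mu_ = flat.mean(axis=0)
        self.sd_ = flat.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Xs = (X - self.mu_) / self.sd_
        y = np.asarray(y, dtype=float)
        n = len(y)
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                loss, grads = self._backward(Xs[idx], y[idx])
                self._adam_step(grads)
                epoch_loss += loss * len(idx)
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = self._forward(self._prepare(X))
        return _sigmoid((h @ self.params["w_out"] + self.params["b_out"]).ravel())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.spec.threshold).astype(int)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def windows_to_arrays(windows: list[PoseWindow], feature_idx=None):
    lengths = {w.frames.shape[0] for w in windows}
    if len(lengths) != 1:
        raise ContractError(f"non-uniform window lengths: {sorted(lengths)}")
    X = np.stack([w.frames for w in windows])
    if feature_idx is not None:
        X = X[:, :, feature_idx]
    y = np.array([1 if w.label == "agitation" else 0 for w in windows])
    return X, y


def _episode_groups(windows: list[PoseWindow]) -> np.ndarray:
    """Contiguous same-label runs get one group id (episode-level splitting)."""
    groups = np.zeros(len(windows), dtype=int)
    gid = 0
    for i in range(1, len(windows)):
        if windows[i].label != windows[i - 1].label:
            gid += 1
        groups[i] = gid
    return groups


def train_sequence_model(
    windows: list[PoseWindow],
    spec: SequenceModelSpec,
    test_fraction: float = 0.3,
    split_mode: str = "window",
    feature_idx=None,
) -> tuple[RecurrentBinaryClassifier, MetricsReport]:
    """Stratified 70/30 split, train on BCE, report on the untouched test set.

    ``split_mode='window'`` splits the (overlapping) windows at random, the
    published protocol; ``'episode'`` keeps contiguous same-label runs on
    one side of the split for leakage-free evaluation.
    """
    if len(windows) < 4:
        raise ProtocolError("need at least 4 windows to split")
    X, y = windows_to_arrays(windows, feature_idx)
    if len(np.unique(y)) < 2:
        raise ProtocolError("both classes must be present")
    idx = np.arange(len(y))
    if split_mode == "window":
        idx_tr, idx_te = train_test_split(idx, test_size=test_fraction,
                                          random_state=spec.seed, stratify=y)
    elif split_mode == "episode":
        groups = _episode_groups(windows)
        rng = np.random.default_rng(spec.seed)
        gids = rng.permutation(np.unique(groups))
        n_test = max(1, int(round(test_fraction * len(gids))))
        test_g = set(gids[:n_test].tolist())
        idx_te = idx[np.isin(groups, list(test_g))]
        idx_tr = idx[~np.isin(groups, list(test_g))]
        if len(np.unique(y[idx_te])) < 2 or len(np.unique(y[idx_tr])) < 2:
            raise ProtocolError("episode-level split left a single-class partition")
    else:
        raise ContractError(f"unknown split_mode {split_mode!r}")
    model = RecurrentBinaryClassifier(spec).fit(X[idx_tr], y[idx_tr])
    proba = model.predict_proba(X[idx_te])
    pred = (proba >= spec.threshold).astype(int)
    y_te = y[idx_te]
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    n = len(y_te)
    report = MetricsReport(
        participant_id=f"video[{split_mode}]",
        algo=spec.cell,
        accuracy=(tp + tn) / n,
        auc=float(roc_auc_score(y_te, proba)) if len(np.unique(y_te)) > 1 else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn, n_train=len(idx_tr), n_test=n,
    )
    return model, report


def evaluate_latency(model: RecurrentBinaryClassifier, windows: list[PoseWindow],
                     repetitions: int = 3, feature_idx=None) -> dict[str, float]:
    """Median and IQR of wall-clock per-window inference time (descriptive
    metadata only, never an acceptance value)."""
    if repetitions < 1:
        raise ProtocolError("repetitions must be >= 1")
    X, _ = windows_to_arrays(windows, feature_idx)
    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        model.predict_proba(X)
        times.append((time.perf_counter() - t0) / len(windows))
    q25, q50, q75 = np.percentile(times, [25, 50, 75])
    return {"median_s": float(q50), "iqr_s": float(q75 - q25), "repetitions": repetitions}


def compare_sequence_models(
    windows: list[PoseWindow],
    feature_names: list[str],
    reduced_names: list[str],
    cells=("lstm", "gru"),
    spec_template: SequenceModelSpec | None = None,
    test_fraction: float = 0.3,
    split_mode: str = "window",
    latency_repetitions: int = 3,
):
    """The model × feature-set comparison grid (accuracy/AUC/F1/recall/time)."""
    import pandas as pd
    template = spec_template or SequenceModelSpec()
    reduced_idx = [feature_names.index(n) for n in reduced_names]
    rows = []
    for cell in cells:
        for label, idx in (("full", None), ("reduced", reduced_idx)):
            dim = len(feature_names) if idx is None else len(idx)
            spec = SequenceModelSpec(
                cell=cell, input_dim=dim, hidden_dim=template.hidden_dim,
                epochs=template.epochs, batch_size=template.batch_size,
                learning_rate=template.learning_rate, seed=template.seed,
                time_subsample=template.time_subsample, threshold=template.threshold,
            )
            model, rep = train_sequence_model(windows, spec, test_fraction, split_mode, idx)
            lat = evaluate_latency(model, windows, latency_repetitions, idx)
            rows.append({
                "cell": cell, "feature_set": label, "n_features": dim,
                "accuracy": rep.accuracy, "auc": rep.auc, "f1": rep.f1,
                "recall": rep.recall, "latency_median_s": lat["median_s"],
            })
    return pd.DataFrame(rows)
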