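"""Training and evaluation protocols for the wristband classifiers.

Implements the personalized (per participant) and general (pooled) 70/30
protocols with minority up-sampling on the training partition only, the
standard metric set, and the paired statistical comparison across
algorithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .errors import ContractError, ProtocolError

logger = logging.getLogger(__name__)

ALGOS = ("extra_trees", "gradient_boosting", "random_forest", "mlp")

POSITIVE = "agitation"


@dataclass
class ModelConfig:
    n_estimators: int = 300
    mlp_hidden: int = 100
    mlp_max_iter: int = 300
    gb_n_estimators: int | None = None  # defaults to n_estimators

    def gb_estimators(self) -> int:
        return self.gb_n_estimators if self.gb_n_estimators is not None else self.n_estimators


@dataclass
class MetricsReport:
    participant_id: str
    algo: str
    accuracy: float
    auc: float
    recall: float
    precision: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_train: int
    n_test: int

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        if total != self.n_test:
            raise ContractError("confusion counts do not sum to n_test")


@dataclass
class ComparisonReport:
    reference: str
    mean_accuracy: dict[str, float]
    sd_accuracy: dict[str, float]
    ci_accuracy: dict[str, tuple[float, float]]
    mean_auc: dict[str, float]
    sd_auc: dict[str, float]
    ci_auc: dict[str, tuple[float, float]]
    p_vs_reference: dict[str, float | None]
    exact_difference: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for algo in self.mean_accuracy:
            rows.append({
                "algo": algo,
                "mean_accuracy": self.mean_accuracy[algo],
                "sd_accuracy": self.sd_accuracy[algo],
                "ci_accuracy_lo": self.ci_accuracy[algo][0],
                "ci_accuracy_hi": self.ci_accuracy[algo][1],
                "mean_auc": self.mean_auc[algo],
                "sd_auc": self.sd_auc[algo],
                "ci_auc_lo": self.ci_auc[algo][0],
                "ci_auc_hi": self.ci_auc[algo][1],
                "p_vs_reference": self.p_vs_reference.get(algo),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def frame_to_xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a labelled feature frame into (X, y, feature_names).

    All-NaN columns (missing channels) are excluded; remaining NaNs are
    median-imputed per column.
    """
    meta = [c for c in ("window_start", "window_end", "label", "participant_id") if c in df.columns]
    feats = df.drop(columns=meta)
    feats = feats.dropna(axis=1, how="all")
    feats = feats.fillna(feats.median(numeric_only=True))
    y = (df["label"] == POSITIVE).to_numpy(dtype=int)
    return feats.to_numpy(dtype=float), y, list(feats.columns)


def upsample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random minority over-sampling with replacement to equal class counts.

    Applies to a *training* partition only; callers must never pass test
    rows through here.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ProtocolError("up-sampling requires both classes present")
    if counts[0] == counts[1]:
        return X, y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    idx_min = np.nonzero(y == minority)[0]
    extra = rng.choice(idx_min, size=int(counts.max() - counts.min()), replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return X[keep], y[keep]


def make_classifier(algo: str, seed: int, config: ModelConfig | None = None):
    config = config or ModelConfig()
    if algo == "extra_trees":
        return ExtraTreesClassifier(n_estimators=config.n_estimators, random_state=seed, n_jobs=1)
    if algo == "random_forest":
        return RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed, n_jobs=1)
    if algo == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=config.gb_estimators(), random_state=seed)
    if algo == "mlp":
        return MLPClassifier(hidden_layer_sizes=(config.mlp_hidden,), early_stopping=True,
                             max_iter=config.mlp_max_iter, random_state=seed)
    raise ContractError(f"unknown algorithm {algo!r}")


def train_classifier(X: np.ndarray, y: np.ndarray, algo: str, seed: int,
                     config: ModelConfig | None = None, min_per_class: int = 10):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < min_per_class:
        raise ProtocolError(f"need >= {min_per_class} windows per class, got {dict(zip(classes, counts))}")
    model = make_classifier(algo, seed, config)
    model.fit(X, y)
    return model


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray, participant_id: str,
             algo: str, n_train: int) -> MetricsReport:
    y_pred = model.predict(X_test)
    proba = model.predict_proba(X_test)[:, 1]
    tp = int(np.sum((y_pred == 1) & (y_test == 1)))
    fp = int(np.sum((y_pred == 1) & (y_test == 0)))
    tn = int(np.sum((y_pred == 0) & (y_test == 0)))
    fn = int(np.sum((y_pred == 0) & (y_test == 1)))
    n = len(y_test)
    auc = float(roc_auc_score(y_test, proba)) if len(np.unique(y_test)) > 1 else float("nan")
    return MetricsReport(
        participant_id=participant_id,
        algo=algo,
        accuracy=(tp + tn) / n,
        auc=auc,
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_train=n_train, n_test=n,
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _split(X, y, test_fraction, seed):
    if not 0.0 < test_fraction < 1.0:
        raise ProtocolError("test fraction must be in (0, 1)")
    return train_test_split(X, y, np.arange(len(y)), test_size=test_fraction,
                            random_state=seed, stratify=y)


def _fit_eval(X, y, algo, seed, test_fraction, pid, config):
    X_tr, X_te, y_tr, y_te, idx_tr, idx_te = _split(X, y, test_fraction, seed)
    assert not set(idx_tr) & set(idx_te)
    X_bal, y_bal = upsample(X_tr, y_tr, seed)
    model = train_classifier(X_bal, y_bal, algo, seed, config)
    return model, evaluate(model, X_te, y_te, pid, algo, n_train=len(y_bal))


def run_personalized_protocol(
    features_by_pid: dict[str, pd.DataFrame],
    algos=ALGOS,
    test_fraction: float = 0.3,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> list[MetricsReport]:
    """Per-participant stratified 70/30 split, up-sample train, fit, test."""
    if not 0.0 < test_fraction < 1.0:
        raise ProtocolError("test fraction must be in (0, 1)")
    reports = []
    for pid, df in features_by_pid.items():
        X, y, _ = frame_to_xy(df)
        if len(np.unique(y)) < 2:
            logger.warning("participant %s has a single class; skipped", pid)
            continue
        for algo in algos:
            try:
                _, rep = _fit_eval(X, y, algo, seed, test_fraction, pid, config)
            except ProtocolError as exc:
                logger.warning("participant %s / %s skipped: %s", pid, algo, exc)
                continue
            reports.append(rep)
    return reports


def run_general_protocol(
    features_by_pid: dict[str, pd.DataFrame],
    algos=ALGOS,
    test_fraction: float = 0.3,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> list[MetricsReport]:
    """Pool all participants' windows and run one stratified split per algo."""
    if len(features_by_pid) < 2:
        raise ProtocolError("general protocol needs >= 2 participants")
    pooled = pd.concat(list(features_by_pid.values()), ignore_index=True)
    X, y, _ = frame_to_xy(pooled)
    reports = []
    for algo in algos:
        _, rep = _fit_eval(X, y, algo, seed, test_fraction, "all", config)
        reports.append(rep)
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


# ---------------------------------------------------------------------------
# Statistical comparison
# ---------------------------------------------------------------------------

def _mean_sd_ci(values: np.ndarray, confidence: float = 0.95):
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(sstats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n))
    else:
        half = 0.0
    return mean, sd, (mean - half, mean + half)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float | None, bool]:
    """Two-sided paired t-test p-value; constant nonzero differences are
    flagged ``exact_difference`` (p undefined, reported as 0.0)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0.0):
        return 1.0, False
    if np.std(d, ddof=1) == 0.0:
        return 0.0, True
    t = float(np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d))))
    p = float(2 * sstats.t.sf(abs(t), len(d) - 1))
    return p, False


def compare_models(reports: list[MetricsReport], reference: str = "extra_trees") -> ComparisonReport:
    """Mean/SD/95% CI per algorithm plus paired t-tests against the reference,
    computed on per-participant accuracies."""
    df = reports_to_frame([r for r in reports if r.participant_id != "all"])
    by_algo = {a: g.sort_values("participant_id") for a, g in df.groupby("algo")}
    if reference not in by_algo:
        raise ContractError(f"reference algo {reference!r} missing from reports")
    pids = None
    for a, g in by_algo.items():
        cur = tuple(g["participant_id"])
        if pids is None:
            pids = cur
        elif cur != pids:
            raise ContractError("participant sets differ across algorithms")
    if len(pids) < 3:
        raise ProtocolError("comparison needs >= 3 participants")
    out = ComparisonReport(reference, {}, {}, {}, {}, {}, {}, {}, {})
    ref_acc = by_algo[reference]["accuracy"].to_numpy()
    for algo, g in by_algo.items():
        acc = g["accuracy"].to_numpy()
        auc = g["auc"].to_numpy()
        out.mean_accuracy[algo], out.sd_accuracy[algo], out.ci_accuracy[algo] = _mean_sd_ci(acc)
        out.mean_auc[algo], out.sd_auc[algo], out.ci_auc[algo] = _mean_sd_ci(auc)
        if algo == reference:
            out.p_vs_reference[algo] = None
            out.exact_difference[algo] = False
        else:
            p, exact = paired_t(acc, ref_acc)
            out.p_vs_reference[algo] = p
            out.exact_difference[algo] = exact
    return out
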