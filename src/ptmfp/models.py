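"""Function-potential models: logistic baselines and the 6-3-1 tanh network.

The network maps the six MAP features (PTM count, SASA, conservation, PPI,
neighbor count, neighbor known count) through one hidden layer of three tanh
units to a logistic output probability. Training minimises L2-penalised
cross-entropy with a deterministic full-batch quasi-Newton optimiser from a
seed-controlled initialisation; 33% of the data is randomly held back for
validation. Evaluation is ROC/AUC throughout (rank-statistic AUC, ties
counted one half), with DeLong's paired chi-square test for AUC comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import LogisticRegression

from .maps import FEATURE_NAMES, KFSC_BIN_LABELS

N_HIDDEN = 3
DEFAULT_HOLDBACK = 0.33
DEFAULT_L2_PENALTY = 1e-3


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """An ROC curve with its rank-statistic AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve by threshold sweep; AUC by the Mann–Whitney rank statistic.

    AUC equals the probability a random positive outscores a random negative,
    with ties counted 1/2. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    # one curve point per distinct threshold
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    idx = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_labels)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(auc), n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# single-feature logistic baselines
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    intercept: float
    slope: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.intercept + self.slope * np.asarray(x, dtype=float))


def fit_single_feature_logistic(
    x: np.ndarray, labels: np.ndarray
) -> tuple[LogisticModel, ROCResult]:
    """Univariate maximum-likelihood logistic fit with an ROC on the fit data.

    Complete separation (non-convergent unpenalised fit) falls back to a
    small ridge penalty with a warning.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    if np.ptp(x) == 0:
        model = LogisticModel(intercept=float(_logit(y.mean())), slope=0.0)
    else:
        separated = False
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                fit = LogisticRegression(penalty=None, max_iter=2000).fit(x, y)
            except Warning:
                separated = True
        if separated:
            warnings.warn("separation suspected; refitting with a small ridge penalty")
            fit = LogisticRegression(C=1e3, max_iter=2000).fit(x, y)
        model = LogisticModel(float(fit.intercept_[0]), float(fit.coef_[0, 0]))
    return model, roc_auc(model.predict(x.ravel()), y)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


# ---------------------------------------------------------------------------
# the neural network
# ---------------------------------------------------------------------------

@dataclass
class NNModel:
    """Fully connected 6 → 3 (tanh) → 1 (logistic) network with input scaling."""

    center: np.ndarray  # (6,) training-partition feature means
    scale: np.ndarray  # (6,) training-partition feature standard deviations
    W1: np.ndarray  # (6, 3)
    b1: np.ndarray  # (3,)
    W2: np.ndarray  # (3,)
    b2: float
    metadata: dict = field(default_factory=dict)

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Probability scores, strictly inside (0, 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        hidden = np.tanh(self.normalize(X) @ self.W1 + self.b1)
        z = hidden @ self.W2 + self.b2
        return np.clip(_sigmoid(z), 1e-12, 1 - 1e-12)

    def to_json(self) -> str:
        return json.dumps(
            {
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
                "W1": self.W1.tolist(),
                "b1": self.b1.tolist(),
                "W2": self.W2.tolist(),
                "b2": self.b2,
                "hidden_transfer": "tanh",
                "output_transfer": "logistic",
                "features": FEATURE_NAMES,
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NNModel":
        d = json.loads(text)
        return cls(
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            W1=np.array(d["W1"]),
            b1=np.array(d["b1"]),
            W2=np.array(d["W2"]),
            b2=float(d["b2"]),
            metadata=d.get("metadata", {}),
        )


def nn_forward(model: NNModel, feature_vector: np.ndarray) -> float:
    """Score one feature vector through the trained network."""
    return float(model.forward(np.asarray(feature_vector, dtype=float))[0])


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _unpack(theta, n_features, n_hidden):
    k = n_features * n_hidden
    W1 = theta[:k].reshape(n_features, n_hidden)
    b1 = theta[k : k + n_hidden]
    W2 = theta[k + n_hidden : k + 2 * n_hidden]
    b2 = theta[-1]
    return W1, b1, W2, b2


def _loss_grad(theta, X, y, l2, n_features, n_hidden):
    W1, b1, W2, b2 = _unpack(theta, n_features, n_hidden)
    n = len(y)
    H = np.tanh(X @ W1 + b1)  # (n, h)
    z = H @ W2 + b2
    p = _sigmoid(z)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    loss += l2 * (np.sum(W1**2) + np.sum(W2**2))
    dz = (p - y) / n  # (n,)
    gW2 = H.T @ dz + 2 * l2 * W2
    gb2 = dz.sum()
    dH = np.outer(dz, W2) * (1 - H**2)
    gW1 = X.T @ dH + 2 * l2 * W1
    gb1 = dH.sum(axis=0)
    return loss, _pack(gW1, gb1, gW2, gb2)


def holdback_split(
    n: int, labels: np.ndarray, holdback: float, seed: int, max_retries: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """One random holdback partition with both classes in both halves."""
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        n_val = int(round(holdback * n))
        val, train = perm[:n_val], perm[n_val:]
        if len(set(labels[train])) == 2 and len(set(labels[val])) == 2:
            return train, val
    raise ValueError("could not draw a holdback partition with both classes")


def train_nn(
    X: np.ndarray,
    y: np.ndarray,
    holdback: float = DEFAULT_HOLDBACK,
    seed: int = 0,
    l2: float = DEFAULT_L2_PENALTY,
    max_iter: int = 2000,
    min_samples: int = 200,
) -> tuple[NNModel, ROCResult, ROCResult]:
    """Train the network with random holdback validation.

    Returns (model, training ROC, validation ROC). Features are standardised
    on the training partition; optimisation is full-batch L-BFGS from a
    seed-controlled random initialisation, so identical inputs and seed give
    bit-identical parameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, n_features = X.shape
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {n}")
    train_idx, val_idx = holdback_split(n, y, holdback, seed)
    center = X[train_idx].mean(axis=0)
    scale = X[train_idx].std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - center) / scale

    rng = np.random.default_rng(seed)
    n_hidden = N_HIDDEN
    theta0 = _pack(
        rng.normal(scale=0.5, size=(n_features, n_hidden)),
        np.zeros(n_hidden),
        rng.normal(scale=0.5, size=n_hidden),
        0.0,
    )
    result = optimize.minimize(
        _loss_grad,
        theta0,
        args=(Xs[train_idx], y[train_idx], l2, n_features, n_hidden),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    if not np.isfinite(result.fun):
        raise RuntimeError(f"training diverged: {result.message}")
    W1, b1, W2, b2 = _unpack(result.x, n_features, n_hidden)
    model = NNModel(
        center=center,
        scale=scale,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=float(b2),
        metadata={
            "seed": int(seed),
            "holdback": holdback,
            "l2_penalty": l2,
            "optimizer": "L-BFGS-B",
            "iterations": int(result.nit),
            "n_train": int(len(train_idx)),
            "n_validation": int(len(val_idx)),
        },
    )
    scores = model.forward(X)
    roc_train = roc_auc(scores[train_idx], y[train_idx])
    roc_val = roc_auc(scores[val_idx], y[val_idx])
    return model, roc_train, roc_val


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_var(scores: np.ndarray, labels: np.ndarray):
    """AUC and its DeLong structural components for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.r_[pos, neg])
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n  # per-positive components
    v01 = 1.0 - (tz[m:] - ty) / m  # per-negative components
    return auc, v10, v01


def compare_auc(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, int, float]:
    """DeLong chi-square test for two paired AUCs on identical samples.

    Returns (chi-square statistic, df=1, p). The statistic is
    (AUC_a − AUC_b)² / Var(AUC_a − AUC_b) with the paired DeLong covariance.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired comparison needs aligned score/label vectors")
    auc_a, v10_a, v01_a = _delong_auc_var(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_auc_var(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or np.isclose(auc_a, auc_b, atol=1e-15):
        diff = auc_a - auc_b
        if abs(diff) < 1e-15:
            return 0.0, 1, 1.0
        var_diff = max(var_diff, 1e-300)
    statistic = (auc_a - auc_b) ** 2 / var_diff
    return float(statistic), 1, float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# stratified evaluations
# ---------------------------------------------------------------------------

def auc_vs_ptm_count_threshold(
    X: np.ndarray,
    y: np.ndarray,
    thresholds: range | list[int] = range(1, 11),
    seed: int = 0,
    holdback: float = DEFAULT_HOLDBACK,
) -> pd.DataFrame:
    """AUC per model after restricting to MAPs with PTM count 1..t.

    For each threshold t the sample is restricted to PTM count ≤ t, every
    single-feature logistic model is refitted, and the network retrained.
    Rows where a class vanishes are marked undefined (NaN).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    pc = X[:, 0]
    rows = []
    for t in thresholds:
        mask = (pc >= 1) & (pc <= t)
        row: dict = {"threshold": int(t), "n": int(mask.sum())}
        Xt, yt = X[mask], y[mask]
        if len(np.unique(yt)) < 2:
            for name in FEATURE_NAMES:
                row[f"auc_{name}"] = np.nan
            row["auc_nn"] = np.nan
            rows.append(row)
            continue
        for j, name in enumerate(FEATURE_NAMES):
            _, roc = fit_single_feature_logistic(Xt[:, j], yt)
            row[f"auc_{name}"] = roc.auc
        try:
            _, _, roc_val = train_nn(Xt, yt, holdback=holdback, seed=seed)
            row["auc_nn"] = roc_val.auc
        except ValueError:
            row["auc_nn"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def auc_by_kfsc(
    scores: np.ndarray,
    labels: np.ndarray,
    kfsc_bins: list[str | None],
) -> pd.DataFrame:
    """Per-KFSC-bin AUC: positives are known MAPs in the bin, negatives all unknown."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    bins = np.array([b if b is not None else "" for b in kfsc_bins], dtype=object)
    neg_mask = labels == 0
    rows = []
    for b in KFSC_BIN_LABELS:
        pos_mask = (labels == 1) & (bins == b)
        row = {"kfsc_bin": b, "n_pos": int(pos_mask.sum()), "n_neg": int(neg_mask.sum())}
        if pos_mask.sum() == 0:
            row["auc"] = np.nan
        else:
            sel = pos_mask | neg_mask
            row["auc"] = roc_auc(scores[sel], labels[sel]).auc
        rows.append(row)
    return pd.DataFrame(rows)
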