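"""Downstream probes on frozen encoder features.

Four protocols evaluate a pretrained encoder without touching its weights:

* **k-NN probe** — cosine-similarity weighted vote among the k nearest
  training features (weights ``exp(sim / T)``), swept over k with the best
  top-1 accuracy reported.
* **Linear probe** — a single affine layer with softmax cross-entropy on the
  frozen features, swept over learning rates.
* **Semi-supervised splits** — class-balanced stratified subsamples of the
  training labels at a given fraction (the test set is never subsampled).
* **Regression** — ordinary least squares from features to a continuous
  score in [0, 1], reported as test MSE and Kendall tau-b concordance.

Accuracies are reported in percent (Table-style, two decimals meaningful).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FeatureTable",
    "ProbeResult",
    "knn_probe",
    "linear_probe",
    "semi_supervised_split",
    "regression_eval",
    "export_embedding_2d",
]

DEFAULT_K_SWEEP = (5, 10, 20, 50, 100)
KNN_TEMPERATURE = 0.07


@dataclass
class FeatureTable:
    """Frozen features with tile ids and optional labels / scores."""

    features: np.ndarray  # (n, d)
    ids: list
    labels: np.ndarray | None = None
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n, d)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        n = self.features.shape[0]
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != n:
            raise ValueError("ids length mismatch")
        if len(set(self.ids)) != n:
            raise ValueError("duplicated ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length mismatch")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64)
            if len(self.scores) != n:
                raise ValueError("scores length mismatch")

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class ProbeResult:
    """One probe metric with the hyperparameter sweep that produced it."""

    metric: str  # top1_accuracy | topk_accuracy | mse | kendall_tau
    value: float
    sweep: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.metric in ("top1_accuracy", "topk_accuracy"):
            if not 0 <= self.value <= 100:
                raise ValueError("accuracy outside [0, 100]")
        elif self.metric == "kendall_tau":
            if not -1 - 1e-9 <= self.value <= 1 + 1e-9:
                raise ValueError("tau outside [-1, 1]")
        elif self.metric == "mse":
            if self.value < 0:
                raise ValueError("mse must be non-negative")
        else:
            raise ValueError(f"unknown metric {self.metric!r}")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {"metric": self.metric, "value": self.value, "sweep": self.sweep},
                fh,
                indent=2,
            )


def _l2_normalize(x: np.ndarray) -> np.ndarray:
    return x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-12)


# ------------------------------------------------------------------- k-NN
def knn_probe(
    train: FeatureTable,
    test: FeatureTable,
    k_values=DEFAULT_K_SWEEP,
    temperature: float = KNN_TEMPERATURE,
) -> ProbeResult:
    """Cosine k-NN with similarity-weighted voting, best top-1 over the sweep.

    Vote weight of neighbor i for its class is ``exp(cos_sim_i / T)``;
    sweep values exceeding the training-set size are skipped."""
    if train.labels is None or test.labels is None:
        raise ValueError("both tables must be labeled")
    if train.n == 0:
        raise ValueError("empty training set")
    classes, train_y = np.unique(train.labels, return_inverse=True)
    test_y = np.searchsorted(classes, test.labels)
    if not np.all(classes[test_y] == test.labels):
        raise ValueError("test labels contain classes absent from training")
    sims = _l2_normalize(test.features) @ _l2_normalize(train.features).T
    usable = [k for k in k_values if 1 <= k <= train.n]
    if not usable:
        raise ValueError(f"no usable k in {list(k_values)} for n_train={train.n}")
    accs = {}
    order = np.argsort(-sims, axis=1, kind="stable")
    for k in usable:
        idx = order[:, :k]  # (n_test, k)
        w = np.exp(np.take_along_axis(sims, idx, axis=1) / temperature)
        votes = np.zeros((test.n, len(classes)))
        np.add.at(
            votes,
            (np.repeat(np.arange(test.n), k), train_y[idx].ravel()),
            w.ravel(),
        )
        pred = votes.argmax(axis=1)
        accs[k] = 100.0 * float((pred == test_y).mean())
    best_k = max(accs, key=lambda k: accs[k])
    return ProbeResult(
        metric="top1_accuracy",
        value=accs[best_k],
        sweep={"k": best_k, "all": {str(k): v for k, v in accs.items()}},
    )


# ------------------------------------------------------------ linear probe
def _softmax_rows(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def linear_probe(
    train: FeatureTable,
    test: FeatureTable,
    learning_rates=(0.01, 0.1, 1.0),
    epochs: int = 200,
) -> ProbeResult:
    """Softmax regression on frozen features; best test top-1 over the sweep.

    Full-batch gradient descent on standardized features; deterministic
    (zero init), so the result is invariant to training-row order."""
    if train.labels is None or test.labels is None:
        raise ValueError("both tables must be labeled")
    if not np.all(np.isfinite(train.features)) or not np.all(
        np.isfinite(test.features)
    ):
        raise ValueError("non-finite features")
    classes, y = np.unique(train.labels, return_inverse=True)
    y_test = np.searchsorted(classes, test.labels)
    mu = train.features.mean(axis=0)
    sd = train.features.std(axis=0) + 1e-8
    xtr = (train.features - mu) / sd
    xte = (test.features - mu) / sd
    n, d = xtr.shape
    c = len(classes)
    onehot = np.eye(c)[y]
    accs = {}
    for lr in learning_rates:
        w = np.zeros((d, c))
        b = np.zeros(c)
        for _ in range(epochs):
            p = _softmax_rows(xtr @ w + b)
            g = (p - onehot) / n
            w -= lr * (xtr.T @ g)
            b -= lr * g.sum(axis=0)
        pred = (xte @ w + b).argmax(axis=1)
        accs[lr] = 100.0 * float((pred == y_test).mean())
    best = max(accs, key=lambda r: accs[r])
    return ProbeResult(
        metric="top1_accuracy",
        value=accs[best],
        sweep={"learning_rate": best, "all": {str(r): v for r, v in accs.items()}},
    )


# ------------------------------------------------------ semi-supervised split
def semi_supervised_split(
    labels, fraction: float, seed: int = 0, min_one_per_class: bool = False
) -> np.ndarray:
    """Class-balanced stratified index sample of a label vector.

    Per-class counts are ``round(fraction * class size)`` (within 1 of exact
    proportionality). A fraction so small that a class would receive zero
    samples raises, unless ``min_one_per_class`` explicitly bumps those
    classes to one. Deterministic under ``seed``; sorted indices returned."""
    labels = np.asarray(labels)
    if not 0 < fraction <= 1:
        raise ValueError("fraction outside (0, 1]")
    rng = np.random.default_rng(seed)
    chosen = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_c = int(round(fraction * len(idx)))
        if n_c == 0:
            if not min_one_per_class:
                raise ValueError(
                    f"fraction {fraction} gives class {c!r} zero samples "
                    "(pass min_one_per_class=True to force one)"
                )
            n_c = 1
        chosen.append(rng.choice(idx, size=n_c, replace=False))
    return np.sort(np.concatenate(chosen))


# --------------------------------------------------------------- regression
def regression_eval(train: FeatureTable, test: FeatureTable):
    """OLS from features to score; returns (mse, kendall_tau) ProbeResults.

    MSE is the mean squared test residual; tau is the tie-corrected tau-b
    between predicted and true test scores."""
    if train.scores is None or test.scores is None:
        raise ValueError("both tables must carry continuous scores")
    if train.n < 2 or test.n < 2:
        raise ValueError("need at least 2 samples")
    x = np.hstack([train.features, np.ones((train.n, 1))])
    beta, *_ = np.linalg.lstsq(x, train.scores, rcond=None)
    xt = np.hstack([test.features, np.ones((test.n, 1))])
    pred = xt @ beta
    mse = float(np.mean((pred - test.scores) ** 2))
    tau = float(stats.kendalltau(test.scores, pred, variant="b").statistic)
    return (
        ProbeResult(metric="mse", value=mse),
        ProbeResult(metric="kendall_tau", value=tau),
    )


# ------------------------------------------------------------- 2-D export
def export_embedding_2d(
    features, n_neighbors: int = 15, min_dist: float = 0.1, seed: int = 0
) -> np.ndarray:
    """UMAP 2-D coordinates of a feature matrix (qualitative export only)."""
    x = np.asarray(features, dtype=np.float64)
    if x.shape[0] < 16:
        raise ValueError("need at least 16 points for a 2-D embedding")
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(x))


# --------------------------------------------------------------------- IO
def load_label_table(path):
    """Read an ``id,label[,score]`` CSV into (ids, labels, scores)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "label" not in df.columns:
        raise ValueError("label CSV needs 'id' and 'label' columns")
    scores = df["score"].to_numpy() if "score" in df.columns else None
    return list(df["id"]), df["label"].to_numpy(), scores
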