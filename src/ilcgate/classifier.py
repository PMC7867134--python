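"""Boosted L1-regularised linear classifier under binary logistic loss.

The model is additive-linear, fitted by rounds of cyclic coordinate
Newton updates (gblinear-style boosting): in each round the bias and then
every weight receive a second-order update with L1 soft-thresholding,
scaled by a learning rate.  Defaults: 3 rounds, L1 penalty 0.05, no L2,
learning rate 0.5, 70/30 stratified train/test split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ilcgate.normalize import NormalizedMatrix
from ilcgate.signature import SignatureGeneSet


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class LabeledTrainingSet:
    """samples × signature-genes logCPM features with binary labels."""

    features: np.ndarray  # (n_samples, n_genes)
    labels: np.ndarray  # binary, 1 = ILC2
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if feats.ndim != 2:
            raise ValueError("features must be samples × genes")
        if feats.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("features shape does not match identifiers")
        if labels.shape != (feats.shape[0],):
            raise ValueError("one label per sample required")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(set(np.unique(labels))) < 2:
            raise ValueError("both classes must be present")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def subset(self, idx: Sequence[int]) -> "LabeledTrainingSet":
        idx = list(idx)
        return LabeledTrainingSet(
            self.features[idx], self.labels[idx],
            tuple(self.sample_ids[i] for i in idx), self.gene_ids)

    @classmethod
    def from_normalized(cls, norm: NormalizedMatrix,
                        labels: dict[str, int] | np.ndarray,
                        signature: SignatureGeneSet | None = None
                        ) -> "LabeledTrainingSet":
        """Build from a genes × samples normalised matrix (transposed here)."""
        if signature is not None and tuple(norm.gene_ids) != signature.gene_ids:
            raise ValueError("matrix gene order does not match signature; "
                             "run align_genes first")
        if isinstance(labels, dict):
            lab = np.array([labels[s] for s in norm.sample_ids], dtype=int)
        else:
            lab = np.asarray(labels, dtype=int)
        return cls(norm.values.T.copy(), lab, norm.sample_ids,
                   tuple(norm.gene_ids))


@dataclass(frozen=True)
class ModelHyperparams:
    booster: str = "linear"
    objective: str = "binary-logistic"
    n_rounds: int = 3
    l1_alpha: float = 0.05
    l2_lambda: float = 0.0
    learning_rate: float = 0.5
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.booster != "linear":
            raise ValueError("only the linear booster is supported")
        if self.objective != "binary-logistic":
            raise ValueError("only binary-logistic objective is supported")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be positive")
        if self.l1_alpha < 0 or self.l2_lambda < 0:
            raise ValueError("penalties must be non-negative")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass(frozen=True)
class TrainedModel:
    weights: np.ndarray
    bias: float
    hyperparams: ModelHyperparams
    signature: SignatureGeneSet
    centroids: "object | None" = None  # ClassCentroids; set by the pipeline

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.signature),):
            raise ValueError("weight vector length must equal signature length")
        object.__setattr__(self, "weights", w)

    def decision_margin(self, features: np.ndarray) -> np.ndarray:
        return self.bias + features @ self.weights

    def to_json(self) -> str:
        from ilcgate.transfer_gate import ClassCentroids

        payload = {
            "weights": list(self.weights),
            "bias": self.bias,
            "hyperparams": asdict(self.hyperparams),
            "signature": {
                "gene_ids": list(self.signature.gene_ids),
                "hvg_rank": list(self.signature.hvg_rank),
                "panel_name": self.signature.panel_name,
                "hvg_source": self.signature.hvg_source,
                "n_hvg_requested": self.signature.n_hvg_requested,
            },
            "centroids": None,
        }
        if self.centroids is not None:
            assert isinstance(self.centroids, ClassCentroids)
            payload["centroids"] = {
                "ilc2": list(self.centroids.ilc2),
                "rest": list(self.centroids.rest),
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        from ilcgate.transfer_gate import ClassCentroids

        d = json.loads(text)
        sig = SignatureGeneSet(
            tuple(d["signature"]["gene_ids"]),
            tuple(d["signature"]["hvg_rank"]),
            d["signature"]["panel_name"],
            d["signature"]["hvg_source"],
            d["signature"]["n_hvg_requested"],
        )
        centroids = None
        if d.get("centroids") is not None:
            centroids = ClassCentroids(
                np.array(d["centroids"]["ilc2"], dtype=float),
                np.array(d["centroids"]["rest"], dtype=float))
        return cls(np.array(d["weights"], dtype=float), float(d["bias"]),
                   ModelHyperparams(**d["hyperparams"]), sig, centroids)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def split_train_test(data: LabeledTrainingSet, fraction: float, seed: int
                     ) -> tuple[LabeledTrainingSet, LabeledTrainingSet]:
    """Stratified, seeded, exhaustive and disjoint train/test partition.

    Per-class training counts are allocated by largest remainder so the
    total training size equals round(fraction · n); each class keeps at
    least one sample on each side.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    labels = data.labels
    classes = [0, 1]
    class_idx = {c: np.where(labels == c)[0] for c in classes}
    for c in classes:
        if len(class_idx[c]) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    n_total_train = int(round(fraction * data.n_samples))
    quota = {c: fraction * len(class_idx[c]) for c in classes}
    n_train = {c: int(np.floor(quota[c])) for c in classes}
    leftover = n_total_train - sum(n_train.values())
    order = sorted(classes, key=lambda c: (-(quota[c] - n_train[c]), c))
    for c in order[:max(leftover, 0)]:
        n_train[c] += 1
    for c in classes:  # both sides must hold every class
        n_train[c] = min(max(n_train[c], 1), len(class_idx[c]) - 1)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        perm = rng.permutation(class_idx[c])
        train_idx.extend(perm[:n_train[c]])
        test_idx.extend(perm[n_train[c]:])
    train_idx.sort()
    test_idx.sort()
    return data.subset(train_idx), data.subset(test_idx)


def _coordinate_delta(g_sum: float, h_sum: float, w: float,
                      alpha: float, lam: float) -> float:
    """Second-order coordinate update with L1 soft-thresholding."""
    if h_sum < 1e-10:
        return 0.0
    g_l2 = g_sum + lam * w
    h_l2 = h_sum + lam
    tmp = w - g_l2 / h_l2
    if tmp >= 0:
        return max(-(g_l2 + alpha) / h_l2, -w)
    return min(-(g_l2 - alpha) / h_l2, -w)


def train_boosted_linear(train: LabeledTrainingSet,
                         hp: ModelHyperparams | None = None,
                         signature: SignatureGeneSet | None = None
                         ) -> TrainedModel:
    """Fit the additive linear model by boosting rounds of coordinate updates."""
    hp = hp or ModelHyperparams()
    if not np.all(np.isfinite(train.features)):
        raise ValueError("non-finite feature values")
    # centre features for conditioning (standard for coordinate descent);
    # the means are folded back into the bias below, so the returned model
    # is an ordinary linear model on raw features
    mu = train.features.mean(axis=0)
    x = train.features - mu
    y = train.labels.astype(float)
    n, p = x.shape
    w = np.zeros(p)
    bias = 0.0
    margin = np.zeros(n)
    for _ in range(hp.n_rounds):
        prob = _sigmoid(margin)
        grad = prob - y
        hess = prob * (1.0 - prob)
        db = hp.learning_rate * (-grad.sum() / max(hess.sum(), 1e-10))
        bias += db
        margin += db
        for j in range(p):
            prob = _sigmoid(margin)
            grad = prob - y
            hess = prob * (1.0 - prob)
            xj = x[:, j]
            g_sum = float(grad @ xj)
            h_sum = float(hess @ (xj * xj))
            dw = hp.learning_rate * _coordinate_delta(
                g_sum, h_sum, w[j], hp.l1_alpha, hp.l2_lambda)
            if dw != 0.0:
                w[j] += dw
                margin += dw * xj
    bias -= float(w @ mu)
    if signature is None:
        signature = SignatureGeneSet(train.gene_ids,
                                     tuple(range(1, p + 1)))
    return TrainedModel(w, float(bias), hp, signature)


def predict_confidence(model: TrainedModel,
                       cohort: NormalizedMatrix | np.ndarray,
                       gene_ids: Sequence[str] | None = None) -> np.ndarray:
    """Per-sample class-1 probability logistic(bias + w·x)."""
    if isinstance(cohort, NormalizedMatrix):
        gene_ids = cohort.gene_ids
        features = cohort.values.T
    else:
        features = np.asarray(cohort, dtype=float)
    if gene_ids is not None and tuple(gene_ids) != model.signature.gene_ids:
        raise ValueError("cohort gene space does not match the model "
                         "signature; align with align_genes first")
    if features.shape[1] != len(model.signature):
        raise ValueError("feature dimension does not match signature length; "
                         "align with align_genes first")
    return _sigmoid(model.decision_margin(features))


@dataclass(frozen=True)
class HoldoutEvaluation:
    accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int


def evaluate_holdout(model: TrainedModel, test: LabeledTrainingSet,
                     threshold: float = 0.5) -> HoldoutEvaluation:
    """Accuracy and confusion counts on held-out labelled data."""
    if test.n_samples == 0:
        raise ValueError("empty test set")
    conf = predict_confidence(model, test.features, test.gene_ids)
    pred = (conf > threshold).astype(int)
    y = test.labels
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return HoldoutEvaluation((tp + tn) / len(y), tp, tn, fp, fn)
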