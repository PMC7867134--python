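"""Out-of-distribution gate for cohort samples.

Each cohort sample gets a Euclidean distance to the two training class
centroids over the signature genes, an RBF-kernel similarity
s = exp(−γ·d²), and a binary call: ILC2-high iff confidence > τ_conf
(default 0.20) and similarity > τ_sim (default 0.90), both strict.  The
bandwidth γ defaults to the median heuristic on the training rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from ilcgate.classifier import LabeledTrainingSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassCentroids:
    """Per-class mean expression over the signature genes."""

    ilc2: np.ndarray  # class 1
    rest: np.ndarray  # class 0

    def __post_init__(self) -> None:
        ilc2 = np.asarray(self.ilc2, dtype=float)
        rest = np.asarray(self.rest, dtype=float)
        if ilc2.shape != rest.shape or ilc2.ndim != 1:
            raise ValueError("centroids must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(ilc2)) and np.all(np.isfinite(rest))):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "ilc2", ilc2)
        object.__setattr__(self, "rest", rest)


@dataclass(frozen=True)
class GateParams:
    gamma: float
    tau_conf: float = 0.20
    tau_sim: float = 0.90
    similarity_rule: Literal["max-over-centroids", "ilc2-centroid-only"] = \
        "max-over-centroids"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (0 < self.tau_conf < 1) or not (0 < self.tau_sim < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class GateResult:
    sample_id: str
    confidence: float
    distance_ilc2: float
    distance_rest: float
    similarity: float
    call: int


def compute_centroids(train: LabeledTrainingSet) -> ClassCentroids:
    """Arithmetic mean of feature rows per class."""
    mask1 = train.labels == 1
    mask0 = train.labels == 0
    if not mask1.any() or not mask0.any():
        raise ValueError("both classes must be present to form centroids")
    return ClassCentroids(train.features[mask1].mean(axis=0),
                          train.features[mask0].mean(axis=0))


def centroid_distance(sample_profile: np.ndarray, centroids: ClassCentroids
                      ) -> tuple[float, float]:
    """Euclidean distances (d_ilc2, d_rest) over the signature genes."""
    x = np.asarray(sample_profile, dtype=float)
    if x.shape != centroids.ilc2.shape:
        raise ValueError(
            f"profile length {x.shape} does not match centroid length "
            f"{centroids.ilc2.shape}")
    d1 = float(np.sqrt(np.sum((x - centroids.ilc2) ** 2)))
    d0 = float(np.sqrt(np.sum((x - centroids.rest) ** 2)))
    return d1, d0


def median_heuristic_gamma(train: LabeledTrainingSet | np.ndarray) -> float:
    """γ = 1/(2σ²) with σ the median pairwise distance among training rows."""
    rows = train.features if isinstance(train, LabeledTrainingSet) else \
        np.asarray(train, dtype=float)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    sigma = float(np.median(pdist(rows)))
    if sigma == 0:
        raise ValueError("all training rows identical (median distance 0); "
                         "supply an explicit gamma")
    return 1.0 / (2.0 * sigma ** 2)


def rbf_similarity(distance: float | np.ndarray, gamma: float
                   ) -> float | np.ndarray:
    """s = exp(−γ·d²) ∈ (0, 1]."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    s = np.exp(-gamma * d ** 2)
    return float(s) if s.ndim == 0 else s


def gate_samples(sample_ids: Sequence[str],
                 confidences: np.ndarray,
                 similarities: np.ndarray,
                 params: GateParams,
                 distances_ilc2: np.ndarray | None = None,
                 distances_rest: np.ndarray | None = None
                 ) -> list[GateResult]:
    """Apply the dual confidence/similarity threshold (strict inequalities)."""
    conf = np.asarray(confidences, dtype=float)
    sim = np.asarray(similarities, dtype=float)
    if len(sample_ids) != conf.size or conf.size != sim.size:
        raise ValueError("sample_ids, confidences and similarities must "
                         "have equal length")
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidence outside [0, 1]")
    if np.any((sim < 0) | (sim > 1)):
        raise ValueError("similarity outside [0, 1]")
    d1 = distances_ilc2 if distances_ilc2 is not None else np.full(conf.size, np.nan)
    d0 = distances_rest if distances_rest is not None else np.full(conf.size, np.nan)
    results = []
    for i, sid in enumerate(sample_ids):
        call = int(conf[i] > params.tau_conf and sim[i] > params.tau_sim)
        results.append(GateResult(sid, float(conf[i]), float(d1[i]),
                                  float(d0[i]), float(sim[i]), call))
    n_pos = sum(r.call for r in results)
    logger.info("gate: %d/%d samples called ILC2-high "
                "(tau_conf=%g, tau_sim=%g)", n_pos, len(results),
                params.tau_conf, params.tau_sim)
    return results


def score_cohort(model, cohort, params: GateParams) -> list[GateResult]:
    """Confidence + distance + similarity + call for every cohort sample.

    ``model`` must carry centroids; ``cohort`` is a NormalizedMatrix
    aligned to the model signature.
    """
    from ilcgate.classifier import predict_confidence

    if model.centroids is None:
        raise ValueError("model has no class centroids; "
                         "train via the pipeline or set them explicitly")
    conf = predict_confidence(model, cohort)
    features = cohort.values.T
    d1 = np.sqrt(np.sum((features - model.centroids.ilc2) ** 2, axis=1))
    d0 = np.sqrt(np.sum((features - model.centroids.rest) ** 2, axis=1))
    s1 = np.exp(-params.gamma * d1 ** 2)
    s0 = np.exp(-params.gamma * d0 ** 2)
    if params.similarity_rule == "max-over-centroids":
        sim = np.maximum(s1, s0)
    else:
        sim = s1
    return gate_samples(cohort.sample_ids, conf, sim, params, d1, d0)
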