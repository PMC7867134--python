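"""Trimmed-mean-of-M-values scale factors and logCPM transformation.

Implements the published TMM definition directly: per sample vs a
reference, M- and A-values over genes expressed in both, rank-based
double trimming (30% on M, 5% on A by default), and a precision-weighted
mean of the surviving M-values using inverse asymptotic binomial
variances.  Factors are rescaled so their geometric mean is 1.  The
logCPM dialect is

    value(g, s) = log2( (c_gs + p) / (N_s·f_s + 2p) · 1e6 )

with pseudo-count p = 0.5.  This is one fixed dialect — self-consistent
rather than bit-identical to any external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from ilcgate.io_cohort import ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_TRIMMED_GENES = 10


@dataclass(frozen=True)
class NormalizationParams:
    trim_m: float = 0.30
    trim_a: float = 0.05
    prior: float = 0.5
    reference_rule: str = "auto-upper-quartile"  # or an explicit sample id

    def __post_init__(self) -> None:
        if not (0 <= self.trim_m < 0.5):
            raise ValueError("trim_m must be in [0, 0.5)")
        if not (0 <= self.trim_a < 0.5):
            raise ValueError("trim_a must be in [0, 0.5)")
        if self.prior <= 0:
            raise ValueError("prior must be positive")


@dataclass(frozen=True)
class NormalizedMatrix:
    """logCPM values plus the per-sample TMM factors that produced them."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # float64, genes × samples
    factors: np.ndarray  # float64, per sample, geometric mean 1
    params: NormalizationParams = field(default_factory=NormalizationParams)
    effective_lib: np.ndarray | None = None  # N_s·f_s of the source matrix

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        factors = np.asarray(self.factors, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape mismatch")
        if factors.shape != (len(self.sample_ids),):
            raise ValueError("one factor per sample required")
        if np.any(factors <= 0):
            raise ValueError("TMM factors must be strictly positive")
        if not np.all(np.isfinite(values)):
            raise ValueError("logCPM values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "factors", factors)
        if self.effective_lib is not None:
            object.__setattr__(self, "effective_lib",
                               np.asarray(self.effective_lib, dtype=float))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def zero_count_floor(self) -> np.ndarray:
        """Per-sample logCPM of a zero count (the matrix's detection floor)."""
        if self.effective_lib is None:
            raise ValueError("effective library sizes unavailable")
        p = self.params.prior
        return np.log2(p / (self.effective_lib + 2.0 * p) * 1e6)


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper quartile of nonzero CPM is closest to the mean."""
    uq = np.empty(counts.shape[1])
    for s in range(counts.shape[1]):
        nz = counts[:, s][counts[:, s] > 0]
        uq[s] = np.quantile(nz / lib[s] * 1e6, 0.75)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _pair_factor_log2(obs: np.ndarray, ref: np.ndarray,
                      n_obs: float, n_ref: float,
                      trim_m: float, trim_a: float) -> float:
    """log2 TMM factor for one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        logger.warning("no genes shared with reference; factor set to 1")
        return 0.0
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = m.size
    # rank-based double trim, keeping ranks strictly inside each cut
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep2.sum() < MIN_TRIMMED_GENES:
        logger.warning("only %d genes survive trimming (<%d); factor set to 1",
                       int(keep2.sum()), MIN_TRIMMED_GENES)
        return 0.0
    wk, mk = w[keep2], m[keep2]
    finite = np.isfinite(wk)
    wk, mk = wk[finite], mk[finite]
    if wk.size == 0 or wk.sum() == 0:
        return 0.0
    return float(np.sum(wk * mk) / np.sum(wk))


def compute_tmm_factors(matrix: ExpressionMatrix,
                        params: NormalizationParams | None = None) -> np.ndarray:
    """Per-sample TMM scale factors, geometric-mean normalised to 1."""
    params = params or NormalizationParams()
    counts = matrix.counts
    lib = matrix.library_sizes.astype(float)
    if np.any(lib == 0):
        bad = [matrix.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"all-zero samples: {bad}")
    if params.reference_rule == "auto-upper-quartile":
        ref_idx = _choose_reference(counts, lib)
    else:
        if params.reference_rule not in matrix.sample_ids:
            raise ValueError(
                f"reference sample {params.reference_rule!r} not in matrix")
        ref_idx = matrix.sample_ids.index(params.reference_rule)
    ref = counts[:, ref_idx]
    log2f = np.empty(matrix.n_samples)
    for s in range(matrix.n_samples):
        if s == ref_idx:
            log2f[s] = 0.0
        else:
            log2f[s] = _pair_factor_log2(counts[:, s], ref, lib[s], lib[ref_idx],
                                         params.trim_m, params.trim_a)
    factors = 2.0 ** log2f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def logcpm_transform(matrix: ExpressionMatrix, factors: np.ndarray,
                     prior: float = 0.5,
                     params: NormalizationParams | None = None
                     ) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-adjusted library sizes."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (matrix.n_samples,):
        raise ValueError("need exactly one factor per sample")
    if np.any(factors <= 0):
        raise ValueError("factors must be strictly positive")
    if prior <= 0:
        raise ValueError("prior must be positive")
    eff_lib = matrix.library_sizes.astype(float) * factors
    values = np.log2((matrix.counts + prior) / (eff_lib + 2.0 * prior) * 1e6)
    params = params or NormalizationParams(prior=prior)
    if params.prior != prior:
        params = replace(params, prior=prior)
    return NormalizedMatrix(matrix.gene_ids, matrix.sample_ids, values,
                            factors, params, effective_lib=eff_lib)


def extract_profile(norm: NormalizedMatrix, genes: "Sequence[str]",
                    missing_policy: str = "error") -> NormalizedMatrix:
    """Subset/permute a normalised matrix to the requested gene order.

    Normalisation is always computed on the full matrix first — slicing
    counts before CPM would cancel any class signal shared across the
    subset.  Under ``zero-fill`` an absent gene takes each sample's
    zero-count logCPM floor.
    """
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing and missing_policy == "error":
        raise KeyError(f"genes absent from normalised matrix: {missing}")
    if missing:
        logger.warning("filling %d absent genes at the zero-count floor: %s",
                       len(missing), missing)
    values = np.empty((len(genes), norm.n_samples))
    floor = norm.zero_count_floor() if missing else None
    for i, g in enumerate(genes):
        values[i] = norm.values[index[g]] if g in index else floor
    return NormalizedMatrix(tuple(genes), norm.sample_ids, values,
                            norm.factors, norm.params, norm.effective_lib)


def normalize_counts(matrix: ExpressionMatrix,
                     params: NormalizationParams | None = None
                     ) -> NormalizedMatrix:
    """Convenience: TMM factors followed by logCPM in one call."""
    params = params or NormalizationParams()
    factors = compute_tmm_factors(matrix, params)
    return logcpm_transform(matrix, factors, params.prior, params)
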