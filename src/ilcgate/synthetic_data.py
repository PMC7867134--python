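"""Synthetic inputs with known ground truth for the whole pipeline.

Counts are negative-binomial with log-normal gene baselines.  The
infiltration signal is an additive shift on the log-mean of the signature
genes, parameterised in within-class logCPM standard deviations (for NB
counts the asymptotic log2 SD is ≈ sqrt(dispersion)/ln2, so a shift of
``effect_size`` SDs multiplies the natural mean by
exp(effect_size·sqrt(dispersion))).  Domain shift perturbs every gene's
log-mean along a fixed random direction, which changes sample composition
(a pure library-size scalar would vanish under CPM).  Survival is
exponential with the hazard multiplied by ``true_hr`` for infiltrated
patients; censoring is an independent exponential whose rate is solved to
hit the requested marginal censoring probability.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ilcgate.io_cohort import (
    ClinicalRecord,
    ExpressionMatrix,
    GenePanel,
    save_clinical_table,
    save_counts_matrix,
)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_signature_genes: int = 50
    panel_size: int = 120
    n_ref_samples: int = 30  # per class
    n_cells: int = 120
    n_patients: int = 200
    pi_infiltrated: float = 0.278
    effect_size: float = 3.0  # within-class logCPM SDs
    nb_dispersion: float = 0.1
    domain_shift: float = 0.0  # log2 units along a fixed random direction
    base_log_mean: float = 4.0  # mean of per-gene log-normal baselines
    base_log_sd: float = 1.0
    true_hr: float = 0.72
    censor_rate: float = 0.3
    baseline_hazard: float = 1.0 / 1000.0  # per day
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_signature_genes", "panel_size",
                     "n_ref_samples", "n_cells", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if self.n_signature_genes > self.panel_size:
            raise ValueError("panel must be able to contain the signature")
        if not (0 < self.pi_infiltrated < 1):
            raise ValueError("pi_infiltrated must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if round(self.pi_infiltrated * self.n_patients) < 1:
            raise ValueError("pi_infiltrated · n_patients < 1: "
                             "no infiltrated patients would be planted")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes - 1))
        return tuple(f"g{i:0{width}d}" for i in range(self.n_genes))

    @property
    def signature_gene_ids(self) -> tuple[str, ...]:
        """Planted signal genes: the first ``n_signature_genes`` ids."""
        return self.gene_ids[:self.n_signature_genes]

    @property
    def fold_change(self) -> float:
        """Natural-scale mean multiplier realising ``effect_size``."""
        return math.exp(self.effect_size * math.sqrt(self.nb_dispersion))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent seeded stream per stage, so stages never interact."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())]))


def _base_log_means(config: SimulationConfig) -> np.ndarray:
    """Per-gene baseline log-means, shared by all three generators so the
    cohort is in-distribution at domain_shift = 0."""
    return _rng(config, "base").normal(loc=config.base_log_mean,
                                       scale=config.base_log_sd,
                                       size=config.n_genes)


def _nb_counts(means: np.ndarray, dispersion: float | np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """means: genes × samples. var = μ + dispersion·μ²."""
    size_param = 1.0 / np.asarray(dispersion)
    if size_param.ndim == 1:
        size_param = size_param[:, None]
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def simulate_reference(config: SimulationConfig
                       ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Labelled two-class reference profiles (1 = ILC2-like, 0 = rest).

    Signature-gene means differ between classes by ``effect_size``
    within-class SDs on the log scale; all other genes are exchangeable.
    """
    rng = _rng(config, "reference")
    base = _base_log_means(config)
    n_per = config.n_ref_samples
    labels = np.array([0] * n_per + [1] * n_per, dtype=int)
    means = np.exp(base)[:, None] * np.ones((1, 2 * n_per))
    sig = slice(0, config.n_signature_genes)
    means[sig, labels == 1] *= config.fold_change
    counts = _nb_counts(means, config.nb_dispersion, rng)
    sample_ids = tuple(f"ref{i:03d}" for i in range(2 * n_per))
    return ExpressionMatrix(config.gene_ids, sample_ids, counts), labels


def simulate_sc_source(config: SimulationConfig) -> ExpressionMatrix:
    """Single-cell style counts with the signature genes overdispersed.

    Planted genes get 10× the background dispersion (plus a bimodal
    on/off mean across cells), so variance-based HVG ranking recovers
    them.
    """
    rng = _rng(config, "sc")
    base = _base_log_means(config)
    means = np.exp(base)[:, None] * np.ones((1, config.n_cells))
    sig = slice(0, config.n_signature_genes)
    on = rng.random((config.n_signature_genes, config.n_cells)) < 0.5
    means[sig] *= np.where(on, config.fold_change ** 2, 1.0)
    dispersion = np.full(config.n_genes, config.nb_dispersion)
    dispersion[sig] *= 10.0
    counts = _nb_counts(means, dispersion, rng)
    sample_ids = tuple(f"cell{i:04d}" for i in range(config.n_cells))
    return ExpressionMatrix(config.gene_ids, sample_ids, counts)


def make_panel(config: SimulationConfig, name: str = "sim-immune-panel"
               ) -> GenePanel:
    """Panel containing every signature gene plus random decoys."""
    rng = _rng(config, "panel")
    others = list(config.gene_ids[config.n_signature_genes:])
    n_extra = config.panel_size - config.n_signature_genes
    decoys = rng.choice(others, size=n_extra, replace=False)
    return GenePanel(frozenset(config.signature_gene_ids) | set(decoys), name)


def _censoring_rate_param(config: SimulationConfig) -> float:
    """Exponential censoring rate giving the marginal censor probability."""
    if config.censor_rate == 0:
        return 0.0
    lam1 = config.baseline_hazard * config.true_hr
    lam0 = config.baseline_hazard
    pi = config.pi_infiltrated

    def marginal(mu: float) -> float:
        return pi * mu / (lam1 + mu) + (1 - pi) * mu / (lam0 + mu) \
            - config.censor_rate

    hi = max(lam0, lam1) * 1e6
    return float(brentq(marginal, 1e-15, hi))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[ExpressionMatrix, list[ClinicalRecord], np.ndarray]:
    """Domain-shifted tumour cohort with a planted infiltrated fraction.

    Returns the count matrix, clinical records whose hazard depends on
    the planted label, and the truth labels.
    """
    rng = _rng(config, "cohort")
    base = _base_log_means(config)
    n = config.n_patients
    n_pos = int(round(config.pi_infiltrated * n))
    truth = np.zeros(n, dtype=int)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    truth[pos_idx] = 1
    shift_dir = rng.standard_normal(config.n_genes)  # fixed OOD direction
    log2_means = base / math.log(2)
    means = 2.0 ** (log2_means[:, None] + config.domain_shift * shift_dir[:, None])
    means = means * np.ones((1, n))
    sig = slice(0, config.n_signature_genes)
    means[sig, truth == 1] *= config.fold_change
    counts = _nb_counts(means, config.nb_dispersion, rng)
    sample_ids = tuple(f"pt{i:04d}" for i in range(n))
    matrix = ExpressionMatrix(config.gene_ids, sample_ids, counts)

    # survival: exponential times, independent exponential censoring
    hazard = config.baseline_hazard * config.true_hr ** truth
    t_event = rng.exponential(1.0 / hazard)
    mu = _censoring_rate_param(config)
    if mu > 0:
        t_cens = rng.exponential(1.0 / mu, size=n)
    else:
        t_cens = np.full(n, np.inf)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    records = []
    for i in range(n):
        records.append(ClinicalRecord(
            sample_id=sample_ids[i],
            time=float(observed[i]),
            event=int(event[i]),
            age=float(np.round(rng.normal(65, 10), 1)),
            sex="male" if rng.random() < 0.5 else "female",
            node_positive=int(rng.random() < 0.4),
            stage=int(rng.integers(1, 5)),
        ))
    return matrix, records, truth


def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input file plus truth labels; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, labels = simulate_reference(config)
    sc = simulate_sc_source(config)
    panel = make_panel(config)
    cohort, records, truth = simulate_cohort(config)

    paths = {
        "ref_counts": outdir / "ref_counts.tsv",
        "ref_labels": outdir / "ref_labels.tsv",
        "sc_counts": outdir / "sc_counts.tsv",
        "panel": outdir / "panel.txt",
        "cohort_counts": outdir / "cohort_counts.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
    }
    save_counts_matrix(ref, paths["ref_counts"])
    with open(paths["ref_labels"], "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(ref.sample_ids, labels):
            fh.write(f"{sid}\t{lab}\n")
    save_counts_matrix(sc, paths["sc_counts"])
    with open(paths["panel"], "w") as fh:
        fh.write(f"# {panel.name}\n")
        for g in sorted(panel.gene_ids):
            fh.write(g + "\n")
    save_counts_matrix(cohort, paths["cohort_counts"])
    save_clinical_table(records, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\ttruth_label\n")
        for sid, lab in zip(cohort.sample_ids, truth):
            fh.write(f"{sid}\t{lab}\n")
    return paths
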