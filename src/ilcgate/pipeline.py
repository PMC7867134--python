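"""End-to-end orchestration: normalize → signature → train → gate → survival.

``run_pipeline`` is a pure function of (input files, config, seed): every
stochastic stage consumes a sub-seed derived from the config seed, so
stage outputs never perturb each other's random streams.  All thresholds
and sample-count transitions are logged at INFO.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ilcgate.classifier import (
    LabeledTrainingSet,
    ModelHyperparams,
    evaluate_holdout,
    split_train_test,
    train_boosted_linear,
)
from ilcgate.io_cohort import (
    load_clinical_table,
    load_counts_matrix,
    load_gene_panel,
    load_orthology_map,
    rename_genes,
)
from ilcgate.normalize import NormalizationParams, extract_profile, \
    normalize_counts
from ilcgate.signature import intersect_panel, select_hvg
from ilcgate.survival import COVARIATE_CHOICES, survival_report
from ilcgate.transfer_gate import (
    GateParams,
    compute_centroids,
    median_heuristic_gamma,
    score_cohort,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    ref_counts: Path
    ref_labels: Path
    sc_counts: Path
    panel: Path
    cohort_counts: Path
    clinical: Path
    outdir: Path
    seed: int = 0
    n_hvg: int = 1000
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    hyperparams: ModelHyperparams = field(default_factory=ModelHyperparams)
    tau_conf: float = 0.20
    tau_sim: float = 0.90
    gamma: float | None = None  # None → median heuristic on training rows
    similarity_rule: str = "max-over-centroids"
    covariates: tuple[str, ...] = COVARIATE_CHOICES
    orthology_map: Path | None = None

    def validate(self) -> None:
        for name in ("ref_counts", "ref_labels", "sc_counts", "panel",
                     "cohort_counts", "clinical"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.orthology_map is not None and not Path(self.orthology_map).exists():
            raise FileNotFoundError(f"orthology_map: {self.orthology_map}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        norm = NormalizationParams(**raw.pop("normalization", {}))
        hp = ModelHyperparams(**raw.pop("hyperparams", {}))
        for key in ("ref_counts", "ref_labels", "sc_counts", "panel",
                    "cohort_counts", "clinical", "outdir", "orthology_map"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(normalization=norm, hyperparams=hp, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclass(frozen=True)
class RunReport:
    n_cohort: int
    n_valid_survival: int
    n_gated_positive: int
    holdout_accuracy: float
    signature_size: int
    gamma: float
    outputs: dict[str, Path]


def _sub_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(stage.encode())]).generate_state(1)[0])


def _load_labels(path: Path, sample_ids: tuple[str, ...]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "label"} <= set(df.columns):
        raise ValueError("labels file needs columns sample_id, label")
    mapping = dict(zip(df["sample_id"].str.strip(), df["label"].astype(int)))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    return np.array([mapping[s] for s in sample_ids], dtype=int)


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ilcgate")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    except Exception as err:
        logger.error("pipeline aborted: %s", err)
        raise
    finally:
        handler.close()
        root.removeHandler(handler)


def _run(config: RunConfig, outdir: Path) -> RunReport:
    import ilcgate

    logger.info("ilcgate %s, seed %d", ilcgate.__version__, config.seed)
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

    # --- normalise reference and single-cell source
    ref_raw = load_counts_matrix(config.ref_counts)
    labels = _load_labels(Path(config.ref_labels), ref_raw.sample_ids)
    logger.info("reference: %d genes × %d samples (%d ILC2 / %d rest)",
                ref_raw.n_genes, ref_raw.n_samples,
                int(labels.sum()), int((labels == 0).sum()))
    sc_raw = load_counts_matrix(config.sc_counts)
    sc_norm = normalize_counts(sc_raw, config.normalization)

    # --- signature: HVGs on single-cell profiles ∩ immune panel
    hvg, _scores = select_hvg(sc_norm, config.n_hvg)
    panel = load_gene_panel(config.panel)
    signature = intersect_panel(hvg, panel, n_hvg_requested=config.n_hvg,
                                hvg_source=str(config.sc_counts))
    logger.info("signature: %d genes", len(signature))

    # --- training set: normalise the full matrix, then take signature genes
    ref_norm = normalize_counts(ref_raw, config.normalization)
    ref_sig = extract_profile(ref_norm, signature.gene_ids,
                              missing_policy="zero-fill")
    data = LabeledTrainingSet.from_normalized(ref_sig, labels, signature)
    hp = dataclasses.replace(config.hyperparams,
                             seed=_sub_seed(config.seed, "split"))
    train, test = split_train_test(data, hp.train_fraction, hp.seed)
    logger.info("split: %d train / %d test", train.n_samples, test.n_samples)

    model = train_boosted_linear(train, hp, signature)
    evaluation = evaluate_holdout(model, test)
    logger.info("holdout accuracy %.3f (tp=%d tn=%d fp=%d fn=%d)",
                evaluation.accuracy, evaluation.tp, evaluation.tn,
                evaluation.fp, evaluation.fn)

    centroids = compute_centroids(train)
    model = dataclasses.replace(model, centroids=centroids)
    gamma = config.gamma if config.gamma is not None \
        else median_heuristic_gamma(train)
    logger.info("gate bandwidth gamma=%.6g (%s)", gamma,
                "explicit" if config.gamma is not None else "median heuristic")
    model_path = outdir / "model.json"
    model.save(model_path)

    # --- cohort scoring and gating
    cohort_raw = load_counts_matrix(config.cohort_counts)
    if config.orthology_map is not None:
        cohort_raw = rename_genes(cohort_raw,
                                  load_orthology_map(config.orthology_map))
    logger.info("cohort: %d samples", cohort_raw.n_samples)
    cohort_full = normalize_counts(cohort_raw, config.normalization)
    cohort_norm = extract_profile(cohort_full, signature.gene_ids,
                                  missing_policy="zero-fill")
    gate_params = GateParams(gamma=gamma, tau_conf=config.tau_conf,
                             tau_sim=config.tau_sim,
                             similarity_rule=config.similarity_rule)  # type: ignore[arg-type]
    results = score_cohort(model, cohort_norm, gate_params)
    gate_path = outdir / "gate_results.tsv"
    gate_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    gate_df.to_csv(gate_path, sep="\t", index=False)
    n_pos = int(gate_df["call"].sum())
    logger.info("gated positive: %d / %d", n_pos, len(results))

    # --- survival stratification of gated patients
    records = load_clinical_table(config.clinical)
    calls = {r.sample_id: r.call for r in results}
    report = survival_report(records, calls, config.covariates)
    report["config"] = config.to_dict()
    report["holdout"] = dataclasses.asdict(evaluation)
    report["gamma"] = gamma
    report["signature_size"] = len(signature)
    survival_path = outdir / "survival_report.json"
    survival_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("cohort %d / valid survival %d / gated positive %d",
                len(results), report["n_valid_survival"], n_pos)

    return RunReport(
        n_cohort=len(results),
        n_valid_survival=report["n_valid_survival"],
        n_gated_positive=n_pos,
        holdout_accuracy=evaluation.accuracy,
        signature_size=len(signature),
        gamma=gamma,
        outputs={"model": model_path, "gate_results": gate_path,
                 "survival_report": survival_path,
                 "run_log": outdir / "run.log"},
    )
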