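"""Data model and I/O for count matrices, gene panels, and clinical tables.

Count matrices are genes × samples with raw integer counts.  Supported
on-disk formats: TSV/CSV (first column gene id, header row of sample ids)
and MatrixMarket triplet with two sidecar identifier files.  Clinical
tables are TSV with a fixed set of required columns; unknown columns are
ignored.  Gene identifiers are matched exactly after whitespace trimming —
no symbol or alias resolution.  An optional two-column orthology map
supports cross-species transfer of a trained model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "time_days", "event", "age_years", "sex",
                    "node_positive", "stage")

_STAGE_MAP = {"I": 1, "II": 2, "III": 3, "IV": 4,
              "1": 1, "2": 2, "3": 3, "4": 4}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(dups)}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Raw integer counts, genes × samples, with identifiers.

    ``library_sizes`` are always the exact column sums of ``counts``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes × samples array")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene identifiers (e.g. an immune gene panel)."""

    gene_ids: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = frozenset(g.strip() for g in self.gene_ids if g.strip())
        if not ids:
            raise ValueError("gene panel is empty")
        object.__setattr__(self, "gene_ids", ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's survival covariates; missing fields are ``None``."""

    sample_id: str
    time: float | None
    event: int | None
    age: float | None = None
    sex: Literal["female", "male"] | None = None
    node_positive: int | None = None
    stage: int | None = None

    def __post_init__(self) -> None:
        if self.time is not None and self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id!r}")
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r} "
                             f"for {self.sample_id!r}")

    @property
    def valid_for_survival(self) -> bool:
        return self.time is not None and self.event is not None and self.time > 0


def n_valid_for_survival(records: Iterable[ClinicalRecord]) -> int:
    return sum(1 for r in records if r.valid_for_survival)


# ---------------------------------------------------------------------------
# readers / writers


def load_counts_matrix(path: str | Path,
                       format: Literal["tsv", "csv", "mtx-triplet"] | None = None,
                       round_counts: bool = False) -> ExpressionMatrix:
    """Read a genes × samples count matrix.

    ``format`` defaults from the file suffix (.tsv/.csv/.mtx).  For
    ``mtx-triplet`` the MatrixMarket file must sit next to sidecar files
    ``<stem>.genes.txt`` and ``<stem>.samples.txt``.  ``round_counts``
    permits rounding near-integer expected counts on ingest (off by
    default: TMM is defined on integer counts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".mtx": "mtx-triplet"}.get(path.suffix.lower(), "tsv")
    if format == "mtx-triplet":
        return _load_mtx_triplet(path, round_counts)
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    genes = [str(g).strip() for g in df.index]
    samples = [str(s).strip() for s in df.columns]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(_is_number)(values))
        g, s = bad[0]
        raise ValueError(f"non-numeric count at gene {genes[g]!r}, "
                         f"sample {samples[s]!r}: {values[g, s]!r}")
    values = values.astype(float)
    if round_counts:
        values = np.rint(values)
    if np.any(values != np.floor(values)):
        g, s = np.argwhere(values != np.floor(values))[0]
        raise ValueError(f"non-integer count at gene {genes[g]!r}, "
                         f"sample {samples[s]!r}: {values[g, s]}")
    return ExpressionMatrix(tuple(genes), tuple(samples), values.astype(np.int64))


def _is_number(x: object) -> bool:
    try:
        float(x)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def _load_mtx_triplet(path: Path, round_counts: bool) -> ExpressionMatrix:
    stem = path.with_suffix("")
    genes_file = Path(f"{stem}.genes.txt")
    samples_file = Path(f"{stem}.samples.txt")
    for f in (genes_file, samples_file):
        if not f.exists():
            raise FileNotFoundError(f"MTX sidecar file missing: {f}")
    genes = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
    samples = [ln.strip() for ln in samples_file.read_text().splitlines() if ln.strip()]
    mat = np.asarray(mmread(path).todense(), dtype=float)
    if round_counts:
        mat = np.rint(mat)
    if np.any(mat != np.floor(mat)):
        g, s = np.argwhere(mat != np.floor(mat))[0]
        raise ValueError(f"non-integer count at gene {genes[g]!r}, "
                         f"sample {samples[s]!r}")
    return ExpressionMatrix(tuple(genes), tuple(samples), mat.astype(np.int64))


def save_counts_matrix(matrix: ExpressionMatrix, path: str | Path,
                       format: Literal["tsv", "csv", "mtx-triplet"] | None = None
                       ) -> None:
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv",
                  ".mtx": "mtx-triplet"}.get(path.suffix.lower(), "tsv")
    if format == "mtx-triplet":
        stem = path.with_suffix("")
        coo = coo_matrix(matrix.counts)
        mmwrite(str(path), coo, field="integer")
        Path(f"{stem}.genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(matrix.sample_ids) + "\n")
        return
    sep = "\t" if format == "tsv" else ","
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def load_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Plain text, one identifier per line; ``#`` starts a comment."""
    path = Path(path)
    ids = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    _check_unique(ids, "panel gene")
    return GenePanel(frozenset(ids), name or path.stem)


def _parse_optional_float(x: object) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    s = str(x).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE", "NULL"}:
        return None
    return float(s)


def load_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a TSV clinical table into :class:`ClinicalRecord` rows.

    Required columns: sample_id, time_days, event.  Covariate columns
    (age_years, sex, node_positive, stage) are optional per cell; absent
    values stay missing — nothing is imputed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "time_days", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        time = _parse_optional_float(row.get("time_days"))
        ev = _parse_optional_float(row.get("event"))
        if ev is not None:
            if ev not in (0.0, 1.0):
                raise ValueError(f"event must be 0 or 1, got {ev}")
            ev = int(ev)
        sex_raw = row.get("sex")
        sex = None
        if sex_raw is not None and str(sex_raw).strip().lower() in ("female", "male"):
            sex = str(sex_raw).strip().lower()
        node = _parse_optional_float(row.get("node_positive"))
        stage_raw = row.get("stage")
        stage = None
        if stage_raw is not None and str(stage_raw).strip():
            s = str(stage_raw).strip().upper()
            if s in _STAGE_MAP:
                stage = _STAGE_MAP[s]
        records.append(ClinicalRecord(
            sample_id=str(row["sample_id"]).strip(),
            time=time,
            event=ev,
            age=_parse_optional_float(row.get("age_years")),
            sex=sex,  # type: ignore[arg-type]
            node_positive=int(node) if node is not None else None,
            stage=stage,
        ))
    n_valid = n_valid_for_survival(records)
    logger.info("loaded %d clinical records, %d valid for survival",
                len(records), n_valid)
    return records


def save_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "time_days": "" if r.time is None else r.time,
            "event": "" if r.event is None else r.event,
            "age_years": "" if r.age is None else r.age,
            "sex": "" if r.sex is None else r.sex,
            "node_positive": "" if r.node_positive is None else r.node_positive,
            "stage": "" if r.stage is None else r.stage,
        })
    pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS)).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-space alignment


def align_genes(matrix: ExpressionMatrix, genes: Sequence[str],
                missing_policy: Literal["error", "zero-fill"] = "error"
                ) -> ExpressionMatrix:
    """Subset/permute ``matrix`` rows to exactly the requested gene order.

    Under ``zero-fill`` absent genes become all-zero rows (reported via
    logging); under ``error`` any absentee aborts.  Library sizes are the
    column sums of the aligned subset.
    """
    genes = [g.strip() for g in genes]
    if not genes:
        raise ValueError("requested gene list is empty")
    _check_unique(genes, "requested gene")
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in genes if g not in index]
    if missing:
        if missing_policy == "error":
            raise KeyError(f"genes absent from matrix: {missing}")
        logger.warning("zero-filling %d absent genes: %s", len(missing), missing)
    out = np.zeros((len(genes), matrix.n_samples), dtype=np.int64)
    for i, g in enumerate(genes):
        if g in index:
            out[i] = matrix.counts[index[g]]
    return ExpressionMatrix(tuple(genes), matrix.sample_ids, out)


def load_orthology_map(path: str | Path) -> dict[str, str]:
    """Two-column whitespace/tab separated file: source gene → target gene."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"orthology map line needs 2 columns: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def rename_genes(matrix: ExpressionMatrix, mapping: dict[str, str]
                 ) -> ExpressionMatrix:
    """Apply an orthology map; genes without a mapping keep their id."""
    new_ids = tuple(mapping.get(g, g) for g in matrix.gene_ids)
    return ExpressionMatrix(new_ids, matrix.sample_ids, matrix.counts)
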