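"""Signature gene space: HVG selection on single-cell profiles ∩ immune panel.

The variability score is the per-gene variance of logCPM across cells
(deterministic; ties broken lexicographically by gene id).  A
mean–variance-trend residual ranking is available behind
``method="trend-residual"`` for users who prefer dispersion-style HVGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ilcgate.io_cohort import GenePanel
from ilcgate.normalize import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureGeneSet:
    """Ordered signature genes = panel ∩ HVGs, ordered by HVG rank."""

    gene_ids: tuple[str, ...]
    hvg_rank: tuple[int, ...]  # 1-based rank in the HVG ordering
    panel_name: str = "panel"
    hvg_source: str = "sc"
    n_hvg_requested: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.hvg_rank):
            raise ValueError("one rank per gene required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate signature genes")
        if any(b <= a for a, b in zip(self.hvg_rank, self.hvg_rank[1:])):
            raise ValueError("signature must be ordered by ascending HVG rank")

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_hvg(sc_matrix: NormalizedMatrix, n: int,
               method: Literal["variance", "trend-residual"] = "variance"
               ) -> tuple[list[str], np.ndarray]:
    """Top-``n`` highly variable genes of a (log-normalised) cell matrix.

    Returns the ordered gene list and their scores.  Genes with zero
    variance are never returned; if fewer than ``n`` genes have positive
    variance, all of them are returned with a warning.
    """
    if n <= 0:
        raise ValueError("n must be a positive integer")
    if sc_matrix.n_samples < 2:
        raise ValueError("need at least 2 cells")
    values = sc_matrix.values
    var = values.var(axis=1, ddof=1)
    if method == "variance":
        score = var
    elif method == "trend-residual":
        mean = values.mean(axis=1)
        coef = np.polyfit(mean, var, deg=2)
        score = var - np.polyval(coef, mean)
    else:
        raise ValueError(f"unknown HVG method {method!r}")
    positive = var > 0
    if positive.sum() < n:
        logger.warning("requested %d HVGs but only %d genes have positive "
                       "variance; returning all of them", n, int(positive.sum()))
    idx = np.where(positive)[0]
    # sort by score descending, ties lexicographic on gene id
    order = sorted(idx, key=lambda i: (-score[i], sc_matrix.gene_ids[i]))
    chosen = order[:min(n, len(order))]
    return [sc_matrix.gene_ids[i] for i in chosen], score[chosen]


def intersect_panel(hvg: Sequence[str], panel: GenePanel,
                    n_hvg_requested: int = 0, hvg_source: str = "sc"
                    ) -> SignatureGeneSet:
    """Intersect an ordered HVG list with a gene panel, keeping HVG order."""
    if not hvg:
        raise ValueError("HVG list is empty")
    genes = []
    ranks = []
    for rank, g in enumerate(hvg, start=1):
        if g in panel:
            genes.append(g)
            ranks.append(rank)
    logger.info("panel size %d, HVG size %d, intersection %d",
                len(panel), len(hvg), len(genes))
    if not genes:
        raise ValueError("panel and HVG set are disjoint; "
                         "cannot build a signature")
    return SignatureGeneSet(tuple(genes), tuple(ranks),
                            panel_name=panel.name, hvg_source=hvg_source,
                            n_hvg_requested=n_hvg_requested or len(hvg))
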