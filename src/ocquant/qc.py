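"""Rule-based quality-control filtering of single-nucleus count matrices.

The filters compose in a fixed order:

1. :func:`filter_genes` — drop genes detected in fewer than 3 cells;
2. :func:`filter_cells` — drop cells below batch-specific nUMI/nGenes floors
   (developmental: > 1000 UMI and > 750 genes; adult: > 750 UMI and > 500
   genes; both strict) or with a mitochondrial fraction above 1%;
3. :func:`sd_outlier_filter` — single-pass removal of cells whose nUMI or
   nGenes lies more than two standard deviations from the mean (a multiplet
   screen), computed per batch group on the post-filter population.

Boundary semantics are strict everywhere ("fewer than", "more than"); the
mitochondrial metric defaults to the mito-UMI share of total UMI, with a
flag to switch to the share of *detected genes* that are mitochondrial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigError, InsufficientDataError, ParameterError

__all__ = [
    "CountMatrix",
    "QcThresholds",
    "filter_genes",
    "filter_cells",
    "sd_outlier_filter",
    "run_qc",
]

BATCHES = ("developmental", "adult")


@dataclass
class CountMatrix:
    """Sparse gene × cell integer count matrix with QC annotations.

    Attributes
    ----------
    counts : scipy.sparse matrix, shape (n_genes, n_cells)
    genes : list of unique gene names
    barcodes : list of unique cell barcodes
    mito : bool array per gene, True for mitochondrial genes
    batches : array of per-cell batch labels ("developmental" or "adult")
    """

    counts: sparse.spmatrix
    genes: list[str]
    barcodes: list[str]
    mito: np.ndarray
    batches: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ConfigError("counts must be non-negative")
        ng, nc = self.counts.shape
        if len(self.genes) != ng:
            raise ConfigError(f"{len(self.genes)} gene names for {ng} rows")
        if len(self.barcodes) != nc:
            raise ConfigError(f"{len(self.barcodes)} barcodes for {nc} columns")
        if len(set(self.genes)) != ng:
            raise ConfigError("gene names must be unique")
        if len(set(self.barcodes)) != nc:
            raise ConfigError("barcodes must be unique")
        self.mito = np.asarray(self.mito, bool)
        if self.mito.shape != (ng,):
            raise ConfigError("mito flags must align with genes")
        self.batches = np.asarray(self.batches, dtype=object)
        if self.batches.shape != (nc,):
            raise ConfigError("batch labels must align with cells")
        unknown = set(self.batches) - set(BATCHES)
        if unknown:
            raise ConfigError(f"unknown batch labels {sorted(unknown)}")

    # ---- per-cell summaries -------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def numi(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def ngenes_detected(self) -> np.ndarray:
        """Number of genes with nonzero counts, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self, metric: str = "umi_fraction") -> np.ndarray:
        """Mitochondrial load per cell.

        ``"umi_fraction"``: mito UMI / total UMI (the standard metric).
        ``"gene_fraction"``: detected mito genes / detected genes.
        Cells with a zero denominator get fraction 0.
        """
        if metric == "umi_fraction":
            num = np.asarray(self.counts[self.mito].sum(axis=0)).ravel()
            den = self.numi()
        elif metric == "gene_fraction":
            num = np.asarray((self.counts[self.mito] > 0).sum(axis=0)).ravel()
            den = self.ngenes_detected()
        else:
            raise ParameterError(f"unknown mito metric {metric!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        return frac

    # ---- subsetting ----------------------------------------------------
    def select_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.counts[keep], list(np.asarray(self.genes, object)[keep]),
            self.barcodes, self.mito[keep], self.batches,
        )

    def select_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.counts[:, keep], self.genes,
            list(np.asarray(self.barcodes, object)[keep]),
            self.mito, self.batches[keep],
        )


@dataclass
class QcThresholds:
    """All QC cutoffs, defaulting to the published rules.

    ``min_genes_base`` is the global floor ("fewer than 500 unique genes");
    the batch-specific floors are at least as strict and therefore govern.
    """

    min_cells_per_gene: int = 3
    min_genes_base: int = 500
    max_mito_fraction: float = 0.01
    sd_multiplier: float = 2.0
    dev_min_umi: int = 1000
    dev_min_genes: int = 750
    adult_min_umi: int = 750
    adult_min_genes: int = 500

    def __post_init__(self) -> None:
        vals = [self.min_cells_per_gene, self.min_genes_base,
                self.max_mito_fraction, self.dev_min_umi, self.dev_min_genes,
                self.adult_min_umi, self.adult_min_genes]
        if any(v < 0 for v in vals):
            raise ConfigError("thresholds must be >= 0")
        if self.sd_multiplier <= 0:
            raise ConfigError("sd_multiplier must be > 0")

    def min_umi(self, batch: str) -> int:
        return {"developmental": self.dev_min_umi, "adult": self.adult_min_umi}[batch]

    def min_genes(self, batch: str) -> int:
        floor = {"developmental": self.dev_min_genes, "adult": self.adult_min_genes}
        return max(floor[batch], self.min_genes_base)


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    detected_in = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    return m.select_genes(detected_in >= min_cells)


def filter_cells(
    m: CountMatrix,
    thresholds: QcThresholds | None = None,
    mito_metric: str = "umi_fraction",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the per-cell floors and the mitochondrial cap.

    A cell passes iff ``nGenes > min_genes(batch)`` AND
    ``nUMI > min_umi(batch)`` AND ``mito_fraction <= max_mito_fraction``
    (all strict per the printed wording).  Returns the filtered matrix and a
    per-cell log with pass/fail and semicolon-joined reasons.
    """
    thr = thresholds or QcThresholds()
    numi = m.numi()
    ngenes = m.ngenes_detected()
    mito = m.mito_fraction(mito_metric)

    reasons = []
    passed = np.ones(m.n_cells, bool)
    for i in range(m.n_cells):
        batch = m.batches[i]
        why = []
        if not ngenes[i] > thr.min_genes(batch):
            why.append("low_genes")
        if not numi[i] > thr.min_umi(batch):
            why.append("low_umi")
        if mito[i] > thr.max_mito_fraction:
            why.append("high_mito")
        if why:
            passed[i] = False
        reasons.append(";".join(why))

    log = pd.DataFrame(
        {
            "barcode": m.barcodes,
            "batch": m.batches,
            "n_umi": numi.astype(int),
            "n_genes": ngenes.astype(int),
            "mito_fraction": mito,
            "passed": passed,
            "reasons": reasons,
        }
    )
    return m.select_cells(passed), log


def sd_outlier_filter(
    m: CountMatrix,
    sd_multiplier: float = 2.0,
    per_batch: bool = True,
    log_scale: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Single-pass two-sided SD screen on nUMI and nGenes.

    Removes cells with ``|x - mean| > k·sd`` for either metric, with mean
    and (population) sd computed once on the input — the filter is applied
    ONCE, not iterated.  ``per_batch`` computes the statistics within each
    batch group; ``log_scale`` screens log10(1 + x) instead of raw counts.
    """
    if m.n_cells < 3:
        raise InsufficientDataError(f"need >= 3 cells, got {m.n_cells}")
    numi = m.numi().astype(float)
    ngenes = m.ngenes_detected().astype(float)
    if log_scale:
        numi = np.log10(1.0 + numi)
        ngenes = np.log10(1.0 + ngenes)

    keep = np.ones(m.n_cells, bool)
    groups = (
        [(b, np.flatnonzero(m.batches == b)) for b in dict.fromkeys(m.batches)]
        if per_batch
        else [("all", np.arange(m.n_cells))]
    )
    for _, idx in groups:
        for x in (numi, ngenes):
            mu, sd = x[idx].mean(), x[idx].std()
            if sd == 0:
                continue
            keep[idx] &= np.abs(x[idx] - mu) <= sd_multiplier * sd

    log = pd.DataFrame(
        {
            "barcode": m.barcodes,
            "batch": m.batches,
            "passed": keep,
        }
    )
    return m.select_cells(keep), log


def run_qc(
    m: CountMatrix,
    thresholds: QcThresholds | None = None,
    mito_metric: str = "umi_fraction",
    per_batch_sd: bool = True,
    log_scale_sd: bool = False,
) -> tuple[CountMatrix, dict]:
    """Full pipeline in the published order: genes → cells → SD screen.

    Returns the filtered matrix and a report dict with stage-by-stage
    dimensions and the per-cell logs.
    """
    thr = thresholds or QcThresholds()
    report: dict = {
        "input": {"genes": m.n_genes, "cells": m.n_cells},
    }
    m1 = filter_genes(m, thr.min_cells_per_gene)
    report["after_gene_filter"] = {"genes": m1.n_genes, "cells": m1.n_cells}
    m2, cell_log = filter_cells(m1, thr, mito_metric)
    report["after_cell_filter"] = {"genes": m2.n_genes, "cells": m2.n_cells}
    m3, sd_log = sd_outlier_filter(
        m2, thr.sd_multiplier, per_batch=per_batch_sd, log_scale=log_scale_sd
    )
    report["after_sd_filter"] = {"genes": m3.n_genes, "cells": m3.n_cells}
    report["cell_log"] = cell_log
    report["sd_log"] = sd_log
    return m3, report
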