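"""Sparse count matrices with planted low-quality cells and rare genes.

Healthy nuclei draw their library size well above the batch-specific QC
floors; planted failures violate exactly one rule each (too few genes, too
few UMI, excessive mitochondrial load, or an extreme outlier library), so
the expected survivor set of the QC pipeline is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ..errors import ParameterError
from ..qc import CountMatrix

__all__ = ["CountsSimParams", "simulate_counts"]


@dataclass
class CountsSimParams:
    """Parameters of the synthetic count matrix.

    Per batch ("developmental" / "adult"): ``n_good`` healthy cells plus one
    planted failure per listed mode.  ``n_genes`` includes ``n_mito``
    mitochondrial genes and ``n_rare`` genes expressed in fewer than three
    cells (so the gene filter has known casualties).
    """

    rng_seed: int = 0
    n_genes: int = 1200
    n_mito: int = 20
    n_rare: int = 8
    n_good_dev: int = 40
    n_good_adult: int = 40
    n_low_genes: int = 2      # cells violating the gene floor
    n_low_umi: int = 2        # cells violating the UMI floor
    n_high_mito: int = 2      # cells violating the mito cap
    n_outlier: int = 1        # cells violating the SD screen
    good_umi: tuple[float, float] = (4000.0, 400.0)  # mean, sd per healthy cell

    def __post_init__(self) -> None:
        if self.n_mito + self.n_rare >= self.n_genes:
            raise ParameterError("too few ordinary genes")
        if min(self.n_genes, self.n_good_dev, self.n_good_adult) <= 0:
            raise ParameterError("need positive gene and cell counts")


def _cell_counts(
    rng: np.random.Generator,
    n_genes: int,
    usable: np.ndarray,
    mito_idx: np.ndarray,
    total_umi: float,
    n_detected: int,
    mito_share: float,
) -> np.ndarray:
    """Multinomial draw over a chosen detected-gene set."""
    col = np.zeros(n_genes, np.int64)
    n_detected = int(min(n_detected, usable.size))
    chosen = rng.choice(usable, size=n_detected, replace=False)
    n_mito_det = (
        min(mito_idx.size, max(1, int(round(mito_share * n_detected))))
        if mito_share > 0 else 0
    )
    if n_mito_det:
        chosen = np.concatenate([
            chosen[: n_detected - n_mito_det],
            rng.choice(mito_idx, size=n_mito_det, replace=False),
        ])
    mito_mask = np.isin(chosen, mito_idx)
    w = rng.dirichlet(np.full(chosen.size, 2.0))
    if mito_share > 0 and mito_mask.any():
        # steer the UMI share (not just the gene share) toward mito genes
        w = np.where(mito_mask, w * mito_share / max(w[mito_mask].sum(), 1e-12),
                     w * (1 - mito_share) / max(w[~mito_mask].sum(), 1e-12))
    # one guaranteed count per detected gene; the rest multinomial, so the
    # cell's total UMI equals total_umi exactly
    spare = max(int(total_umi) - chosen.size, 0)
    counts = rng.multinomial(spare, w / w.sum()) + 1
    col[chosen] = counts
    return col


def simulate_counts(params: CountsSimParams) -> tuple[CountMatrix, dict]:
    """Build the matrix and the expected QC outcome.

    Returns the CountMatrix and a dict with the planted categories:
    ``expected_cell_survivors`` (barcodes that should pass the cell and SD
    filters), ``planted_failures`` (barcode → reason) and
    ``rare_genes`` (names the gene filter should drop).
    """
    rng = np.random.default_rng(params.rng_seed)
    g = params.n_genes
    mito_idx = np.arange(params.n_mito)
    rare_idx = np.arange(params.n_mito, params.n_mito + params.n_rare)
    common_idx = np.arange(params.n_mito + params.n_rare, g)

    genes = (
        [f"mt-Gene{i}" for i in range(params.n_mito)]
        + [f"Rare{i}" for i in range(params.n_rare)]
        + [f"Gene{i}" for i in range(len(common_idx))]
    )
    mito_mask = np.zeros(g, bool)
    mito_mask[mito_idx] = True

    floors = {"developmental": (1000, 750), "adult": (750, 500)}
    cols, batches, barcodes = [], [], []
    failures: dict[str, str] = {}
    survivors: list[str] = []
    bc = 0

    for batch, n_good in (("developmental", params.n_good_dev),
                          ("adult", params.n_good_adult)):
        min_umi, min_genes = floors[batch]
        for _ in range(n_good):
            umi = max(min_umi + 500,
                      rng.normal(*params.good_umi))
            ndet = int(min(min_genes + 50 + rng.integers(0, 60), len(common_idx)))
            cols.append(_cell_counts(rng, g, common_idx, mito_idx,
                                     umi, ndet, mito_share=0.0))
            name = f"{batch[:3]}-{bc:04d}"
            barcodes.append(name)
            batches.append(batch)
            survivors.append(name)
            bc += 1

        planted = (
            [("low_genes", params.n_low_genes),
             ("low_umi", params.n_low_umi),
             ("high_mito", params.n_high_mito),
             ("outlier", params.n_outlier)]
        )
        for reason, count in planted:
            for _ in range(count):
                if reason == "low_genes":
                    umi, ndet, mito = min_umi + 800, max(min_genes - 150, 20), 0.0
                elif reason == "low_umi":
                    # enough genes to pass the gene floor, too few UMI
                    umi, ndet, mito = min_umi - 100, min_genes + 30, 0.0
                elif reason == "high_mito":
                    umi, ndet, mito = min_umi + 800, min_genes + 60, 0.05
                else:  # outlier: enormous library, passes the floors
                    umi, ndet, mito = params.good_umi[0] * 12, min_genes + 120, 0.0
                cols.append(_cell_counts(rng, g, common_idx, mito_idx,
                                         umi, ndet, mito))
                name = f"{batch[:3]}-{bc:04d}"
                barcodes.append(name)
                batches.append(batch)
                failures[name] = reason
                bc += 1

    # rare genes: give each a count in exactly 2 cells
    mat = np.column_stack(cols)
    for ri in rare_idx:
        mat[ri, :] = 0
        picked = rng.choice(mat.shape[1], size=2, replace=False)
        mat[ri, picked] = 1

    m = CountMatrix(
        counts=sparse.csr_matrix(mat),
        genes=genes,
        barcodes=barcodes,
        mito=mito_mask,
        batches=np.array(batches, object),
    )
    planted = {
        "expected_cell_survivors": survivors,
        "planted_failures": failures,
        "rare_genes": [genes[i] for i in rare_idx],
    }
    return m, planted
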