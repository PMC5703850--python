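"""Post-quantification QC: noise-model fit and pre-clustering filters.

Technical noise in UMI counts follows an overdispersed Poisson: across
wells, a gene with mean molecule count m has coefficient of variation
CV = m^(-0.5) in the pure Poisson limit, and the observed relation is
fitted as an offset Poisson, Log2 CV = Log2(m^(-0.5) + c), with a single
offset parameter c capturing the excess variation.

The pre-clustering filters mirror a typical analysis: bounds on total
molecules per cell and on the molecules/genes ratio (whole cells), a
minimum molecule count (nuclei), gene prevalence filters, per-cell
normalization to a fixed total, and exclusion of doublets that co-express
markers of two distinct cell classes (e.g. Stmn2 for neurons together with
Mog for oligodendrocytes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)


@dataclass
class CVFit:
    """Offset-Poisson fit of the CV-mean relation."""

    offset: float  # c in Log2 CV = Log2(m^-0.5 + c)
    means: np.ndarray
    cvs: np.ndarray
    n_genes_used: int
    residual_rms: float

    def predicted_cv(self, mean: np.ndarray) -> np.ndarray:
        return mean ** -0.5 + self.offset


def fit_cv_mean(matrix: pd.DataFrame) -> CVFit:
    """Fit Log2 CV = Log2(m^(-0.5) + c) to per-gene mean/CV across wells.

    Rows are genes, columns wells. Genes with zero mean or zero variance
    are excluded from the fit (logged). The Poisson exponent is fixed at
    -0.5; only the offset c >= 0 is estimated, by least squares on log2 CV.
    """
    if matrix.shape[1] < 2:
        raise ValueError("CV fit needs at least 2 wells")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    usable = (means > 0) & (sds > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("CV fit: excluding %d genes with zero mean or variance", n_dropped)
    m = means[usable]
    cv = sds[usable] / m
    if m.size == 0:
        raise ValueError("no usable genes for CV fit")
    log_cv = np.log2(cv)

    def loss(c: float) -> float:
        return float(np.sum((log_cv - np.log2(m ** -0.5 + c)) ** 2))

    res = minimize_scalar(loss, bounds=(0.0, 100.0), method="bounded")
    c = float(res.x)
    resid = log_cv - np.log2(m ** -0.5 + c)
    return CVFit(
        offset=c,
        means=m,
        cvs=cv,
        n_genes_used=int(m.size),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


@dataclass
class FilterReport:
    """Kept set plus per-rule removal counts for one filter step."""

    kept: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def removal_counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}


def filter_cells(
    matrix: pd.DataFrame,
    min_molecules: int = 800,
    max_molecules: int = 2000,
    min_mol_gene_ratio: float = 1.2,
) -> FilterReport:
    """Whole-cell filter: bounds on total molecules and molecules/genes.

    A cell is kept iff min <= total <= max and total / genes detected
    (count > 0) strictly exceeds the ratio. Defaults are config, not
    gospel — tune them to the depth of the experiment.
    """
    totals = matrix.sum(axis=0)
    genes_detected = (matrix > 0).sum(axis=0)
    kept, removed = [], {"below_min": [], "above_max": [], "low_ratio": []}
    for well in matrix.columns:
        t, g = totals[well], genes_detected[well]
        if t < min_molecules:
            removed["below_min"].append(well)
        elif t > max_molecules:
            removed["above_max"].append(well)
        elif g == 0 or t / g <= min_mol_gene_ratio:
            removed["low_ratio"].append(well)
        else:
            kept.append(well)
    return FilterReport(kept=kept, removed=removed)


def filter_cells_min_only(matrix: pd.DataFrame, min_molecules: int = 500) -> FilterReport:
    """Nuclei filter: drop cells with fewer than ``min_molecules`` detected."""
    totals = matrix.sum(axis=0)
    kept = [w for w in matrix.columns if totals[w] >= min_molecules]
    removed = {"below_min": [w for w in matrix.columns if totals[w] < min_molecules]}
    return FilterReport(kept=kept, removed=removed)


def filter_genes(
    matrix: pd.DataFrame,
    min_cells: int = 20,
    max_cell_fraction: float = 0.6,
) -> FilterReport:
    """Keep genes expressed (count > 0) in >= min_cells and <= 60% of cells."""
    n_cells = matrix.shape[1]
    expressed_in = (matrix > 0).sum(axis=1)
    kept, removed = [], {"too_few_cells": [], "too_many_cells": []}
    for gene in matrix.index:
        n = expressed_in[gene]
        if n < min_cells:
            removed["too_few_cells"].append(gene)
        elif n > max_cell_fraction * n_cells:
            removed["too_many_cells"].append(gene)
        else:
            kept.append(gene)
    return FilterReport(kept=kept, removed=removed)


def normalize_cells(matrix: pd.DataFrame, target_total: float = 3000) -> pd.DataFrame:
    """Scale each cell (column) to a fixed molecule total.

    Zero-total cells cannot be normalized and are excluded with a warning.
    Within-cell gene proportions are preserved; the raw matrix is left
    untouched (a new frame is returned).
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("normalize_cells: excluding %d zero-total wells", len(zero))
    keep = matrix.loc[:, totals > 0]
    return keep * (target_total / keep.sum(axis=0))


DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "neurons": ["Stmn2"],
    "oligodendrocytes": ["Mog"],
    "astrocytes": ["Aqp4"],
    "endothelial": ["Fn1"],
    "microglia": ["C1qc"],
}


def flag_marker_doublets(
    matrix: pd.DataFrame,
    marker_panel: dict[str, list[str]] | None = None,
    expression_threshold: float = 1.0,
) -> list[str]:
    """Wells co-expressing markers of two or more distinct cell classes.

    A class counts as present in a well when any of its marker genes reaches
    ``expression_threshold`` molecules; a well with >= 2 classes present is
    flagged as a putative doublet. Panel classes must be disjoint; markers
    missing from the matrix are warned about and skipped.
    """
    panel = marker_panel if marker_panel is not None else DEFAULT_MARKER_PANEL
    seen: set[str] = set()
    for genes in panel.values():
        dup = seen & set(genes)
        if dup:
            raise ValueError(f"marker classes are not disjoint: {sorted(dup)}")
        seen |= set(genes)
    missing = sorted(seen - set(matrix.index))
    if missing:
        logger.warning("marker genes absent from matrix: %s", ", ".join(missing))
    flagged = []
    for well in matrix.columns:
        n_classes = sum(
            any(
                gene in matrix.index
                and matrix.loc[gene, well] >= expression_threshold
                for gene in genes
            )
            for genes in panel.values()
        )
        if n_classes >= 2:
            flagged.append(well)
    return flagged
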