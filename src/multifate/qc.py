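"""Per-cell quality metrics and hard filters for RNA and ATAC modalities.

RNA cells are kept when their transcript total lies in [500, 100000] and
their mitochondrial fraction is at most 0.40; ATAC cells when TSS
enrichment is at least 4, unique nuclear fragments at least 1000 and total
reads at most one million.  Boundary values survive: the published rules are
phrased as strict inequalities on the removal side ("fewer than 500",
"greater than 40%", "<4"), so equality keeps the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

QC_COLUMNS = ["cell_id", "total_transcripts", "mito_fraction",
              "tss_enrichment", "n_unique_fragments", "total_reads"]

MITO_PREFIXES = ("mt-", "MT-")


@dataclass(frozen=True)
class FilterThresholds:
    rna_min_transcripts: int = 500
    rna_max_transcripts: int = 100_000
    mito_max: float = 0.40
    tss_min: float = 4.0
    frag_min: int = 1000
    atac_reads_max: int = 1_000_000

    def __post_init__(self) -> None:
        if self.rna_min_transcripts >= self.rna_max_transcripts:
            raise ValueError("rna_min_transcripts must be < rna_max_transcripts")


def _dense_rows(X):
    return np.asarray(X.sum(axis=1)).ravel() if sparse.issparse(X) else X.sum(axis=1)


def compute_rna_qc(counts, gene_names: list[str] | None = None,
                   mito_gene_ids: set[str] | None = None,
                   mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
                   cell_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-cell RNA QC metrics from a cell x gene count matrix.

    ``counts`` may be an :class:`anndata.AnnData` (gene and cell names taken
    from it) or a matrix plus ``gene_names``.  Mitochondrial genes are either
    given explicitly via ``mito_gene_ids`` or identified by name prefix.
    Cells with zero total get mito_fraction 0.
    """
    if hasattr(counts, "X"):  # AnnData
        gene_names = list(counts.var_names)
        cell_ids = list(counts.obs_names)
        X = counts.X
    else:
        X = counts
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
    n_cells = X.shape[0]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]

    if mito_gene_ids is not None:
        missing = set(mito_gene_ids) - set(gene_names)
        if missing:
            logger.warning("%d mito gene ids absent from features; using the "
                           "intersection", len(missing))
        mito_idx = [i for i, g in enumerate(gene_names) if g in mito_gene_ids]
    else:
        mito_idx = [i for i, g in enumerate(gene_names)
                    if any(g.startswith(p) for p in mito_prefixes)]

    total = _dense_rows(X).astype(float)
    if mito_idx:
        sub = X[:, mito_idx]
        mito = _dense_rows(sub).astype(float)
    else:
        mito = np.zeros(n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.where(total > 0, total, 1.0), 0.0)
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "total_transcripts": total.astype(int),
            "mito_fraction": frac,
        }
    )


def filter_rna(qc: pd.DataFrame, t: FilterThresholds = FilterThresholds()
               ) -> np.ndarray:
    """Boolean keep-mask for the RNA filters (inclusive bounds)."""
    total = qc["total_transcripts"].to_numpy()
    keep = (total >= t.rna_min_transcripts) & (total <= t.rna_max_transcripts)
    if "mito_fraction" in qc.columns:
        keep &= qc["mito_fraction"].to_numpy() <= t.mito_max
    return keep


def filter_atac(qc: pd.DataFrame, t: FilterThresholds = FilterThresholds()
                ) -> np.ndarray:
    """Boolean keep-mask for the ATAC filters (inclusive bounds)."""
    keep = np.ones(len(qc), dtype=bool)
    if "tss_enrichment" in qc.columns:
        keep &= qc["tss_enrichment"].to_numpy() >= t.tss_min
    if "n_unique_fragments" in qc.columns:
        keep &= qc["n_unique_fragments"].to_numpy() >= t.frag_min
    if "total_reads" in qc.columns:
        keep &= qc["total_reads"].to_numpy() <= t.atac_reads_max
    return keep


def compute_tss_enrichment(
    fragments: dict[str, list[tuple[int, int]]],
    tss: list[int],
    window: int = 50,
    flank_inner: int = 1901,
    flank_outer: int = 2000,
    pseudo: float = 0.1,
) -> pd.Series:
    """Per-cell TSS enrichment from fragment intervals on one coordinate axis.

    The statistic is per-bp fragment coverage over TSS +/- ``window`` divided
    by per-bp coverage over the distal flanks
    [-flank_outer, -flank_inner] and [flank_inner, flank_outer], with a
    pseudo-coverage of ``pseudo`` added to the denominator.  Intervals are
    0-based half-open; cells with no fragments score 0.
    """
    tss_arr = np.asarray(sorted(tss))
    win_bp = (2 * window + 1) * len(tss_arr)
    flank_bp = 2 * (flank_outer - flank_inner + 1) * len(tss_arr)

    def overlap_bp(start: int, end: int, lo: np.ndarray, hi: np.ndarray) -> int:
        # total overlap of [start, end) with closed bp windows [lo, hi]
        s = np.maximum(start, lo)
        e = np.minimum(end, hi + 1)
        return int(np.maximum(0, e - s).sum())

    win_lo, win_hi = tss_arr - window, tss_arr + window
    fl_lo = np.concatenate([tss_arr - flank_outer, tss_arr + flank_inner])
    fl_hi = np.concatenate([tss_arr - flank_inner, tss_arr + flank_outer])

    out = {}
    for cell, ivals in fragments.items():
        if not ivals:
            out[cell] = 0.0
            continue
        w = sum(overlap_bp(s, e, win_lo, win_hi) for s, e in ivals)
        f = sum(overlap_bp(s, e, fl_lo, fl_hi) for s, e in ivals)
        out[cell] = (w / win_bp) / (f / flank_bp + pseudo)
    return pd.Series(out, name="tss_enrichment")


def filter_report(qc: pd.DataFrame, t: FilterThresholds = FilterThresholds()
                  ) -> dict[str, int]:
    """Counts of cells removed per rule (a cell may trip several rules)."""
    total = qc["total_transcripts"].to_numpy() if "total_transcripts" in qc else None
    report = {}
    if total is not None:
        report["low_count"] = int((total < t.rna_min_transcripts).sum())
        report["multiplet"] = int((total > t.rna_max_transcripts).sum())
    if "mito_fraction" in qc.columns:
        report["high_mito"] = int((qc["mito_fraction"] > t.mito_max).sum())
    if "tss_enrichment" in qc.columns:
        report["low_tss"] = int((qc["tss_enrichment"] < t.tss_min).sum())
    if "n_unique_fragments" in qc.columns:
        report["low_fragments"] = int((qc["n_unique_fragments"] < t.frag_min).sum())
    if "total_reads" in qc.columns:
        report["atac_multiplet"] = int((qc["total_reads"] > t.atac_reads_max).sum())
    return report
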