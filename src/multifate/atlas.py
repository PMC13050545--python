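"""Peak standardization, atlas construction and count normalization.

narrowPeak entries are re-centered at their summits and extended by 250 nt
each side (fixed 501-nt width), ENCODE-blacklist overlaps are removed, and a
non-redundant atlas is built by iteratively retaining the highest-scoring
peak and discarding everything it overlaps.  Sample count columns are
equalized with median-of-ratios size factors, and differential accessibility
is called on the normalized counts with a Welch test on log2 values,
Benjamini-Hochberg adjustment, and the |log2FC| >= 0.5, padj < 0.05 rule.
All coordinates are BED-convention 0-based half-open; the summit column is
an offset from the interval start as in narrowPeak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

PEAK_COLUMNS = ["chrom", "start", "end", "summit_offset", "score", "sample_id"]


def read_narrowpeak(path, sample_id: str = "") -> pd.DataFrame:
    """Read a narrowPeak (BED6+4) file into the internal peak table."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "summit_offset": df["peak"].astype(int),
            "score": df["signalValue"].astype(float),
            "sample_id": sample_id,
        }
    )


def write_bed(path, peaks: pd.DataFrame) -> None:
    cols = [c for c in PEAK_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", index=False, header=False)


def summit_extend(peaks: pd.DataFrame, flank: int = 250,
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Center each peak at its summit and extend ``flank`` nt each side.

    The result spans [summit - flank, summit + flank + 1), i.e. width
    2*flank + 1 (501 by default), clipped at chromosome bounds when sizes
    are provided.
    """
    out = peaks.copy()
    summit = out["start"] + out["summit_offset"]
    start = (summit - flank).clip(lower=0)
    end = summit + flank + 1
    if chrom_sizes:
        limits = out["chrom"].map(chrom_sizes)
        end = np.minimum(end, limits.fillna(np.inf)).astype(int)
    out["start"], out["end"] = start.astype(int), np.asarray(end, dtype=int)
    out["summit_offset"] = (summit - out["start"]).astype(int)
    return out


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def blacklist_filter(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove peaks overlapping any blacklist interval by >= 1 bp.

    Half-open convention: a peak ending exactly where a blacklist interval
    begins does not overlap and is kept.
    """
    if blacklist is None or len(blacklist) == 0:
        return peaks.copy()
    trees = _trees(blacklist)
    keep = [
        not (row.chrom in trees and trees[row.chrom].overlaps(row.start, row.end))
        for row in peaks.itertuples()
    ]
    return peaks[keep].reset_index(drop=True)


def merge_atlas(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Non-redundant atlas by iterative highest-score retention.

    Repeatedly keep the highest-scoring remaining peak and discard every
    peak overlapping it.  Ties are broken by (chrom, start) lexicographic
    order, making the result deterministic and input-order invariant.
    """
    allp = pd.concat(peak_sets, ignore_index=True) if peak_sets else pd.DataFrame(columns=PEAK_COLUMNS)
    if len(allp) == 0:
        return allp
    allp = allp.sort_values(["score", "chrom", "start"],
                            ascending=[False, True, True],
                            kind="mergesort").reset_index(drop=True)
    retained: dict[str, IntervalTree] = {}
    keep_rows = []
    for row in allp.itertuples():
        tree = retained.setdefault(row.chrom, IntervalTree())
        if not tree.overlaps(row.start, row.end):
            tree.addi(row.start, row.end)
            keep_rows.append(row.Index)
    out = allp.loc[keep_rows].sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and normalized counts.

    For each feature with all-positive counts, compute its geometric mean
    across samples; a sample's size factor is the median over those
    features of count / geometric mean, and normalized counts are
    count / size factor.
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; consider adding pseudo-counts"
        )
    logg = np.log(X[positive])
    geo = logg.mean(axis=1)
    ratios = np.exp(logg - geo[:, None])
    factors = pd.Series(np.median(ratios, axis=0), index=counts.columns,
                        name="size_factor")
    normalized = counts / factors
    return factors, normalized


def differential_peaks(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    condition: str | None = None,
    lfc_min: float = 0.5,
    fdr: float = 0.05,
    two_sided_abs: bool = True,
) -> pd.DataFrame:
    """Differential table on normalized counts at the standard thresholds.

    log2FC is computed on group means with a +1 pseudo-count; the test is
    Welch's t on log2(normalized + 1); p-values are Benjamini-Hochberg
    adjusted.  A peak passes when padj < ``fdr`` and |log2FC| >= ``lfc_min``
    (set ``two_sided_abs=False`` for the one-sided log2FC > rule).
    """
    conds = sorted(set(groups.values()))
    if len(conds) != 2:
        raise ValueError("need exactly two conditions")
    if condition is None:
        condition = conds[0]
    other = [c for c in conds if c != condition][0]
    a_cols = [s for s, c in groups.items() if c == condition]
    b_cols = [s for s, c in groups.items() if c == other]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    A = normalized[a_cols].to_numpy(dtype=float)
    B = normalized[b_cols].to_numpy(dtype=float)
    lfc = np.log2(A.mean(axis=1) + 1.0) - np.log2(B.mean(axis=1) + 1.0)
    tstat, pval = stats.ttest_ind(np.log2(A + 1.0), np.log2(B + 1.0),
                                  axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    padj = multipletests(pval, method="fdr_bh")[1]
    effect = np.abs(lfc) if two_sided_abs else lfc
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "p": pval,
            "padj": padj,
            "pass": (padj < fdr) & (effect >= lfc_min),
        },
        index=normalized.index,
    )
    return out
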