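"""PWM motif scanning, p-value-calibrated thresholds and cluster enrichment.

Motifs are scored as log2 odds against a background nucleotide model.  The
score threshold for calling a hit is calibrated so that a random background
word exceeds it with probability at most p (default 5e-05): the score
distribution is computed by dynamic programming over per-column score sums,
exactly when the number of distinct sums is tractable and by conservative
ceiling-discretization otherwise.  Per-cluster motif enrichment uses the
binomial Z statistic Z = (C - Np) / sqrt(Np(1-p)) for C motif-bearing peaks
among N cluster peaks with background rate p.  chromVAR-style accessibility
deviations, standardized against GC/accessibility-matched background peak
sets and filtered by positive Spearman correlation with the motif's TF
expression, select the motifs carried forward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """A position frequency matrix: 4 x width, column-stochastic (rows ACGT)."""

    id: str
    probs: np.ndarray
    source: str = "builtin"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape[0] != 4:
            raise ValueError(f"PWM {self.id}: need 4 rows (ACGT)")
        if not 4 <= probs.shape[1] <= 30:
            raise ValueError(f"PWM {self.id}: width must be in [4, 30]")
        if np.abs(probs.sum(axis=0) - 1.0).max() > 1e-6:
            raise ValueError(f"PWM {self.id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif_id: str
    offset: int
    strand: str
    score: float


def _counts_to_probs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    col = counts.sum(axis=0)
    # frequency-style matrices (columns already ~1) get a nominal depth
    if np.all(col <= 1.5):
        counts = counts * 20.0
        col = counts.sum(axis=0)
    return (counts + pseudocount / 4.0) / (col + pseudocount)


def read_motifs(path, format: str = "jaspar", pseudocount: float = 0.8) -> list[PWM]:
    """Read PWMs from a JASPAR or MEME (minimal) motif file.

    Counts are converted to column-stochastic probabilities with a
    pseudocount before storage; an all-zero column becomes uniform.
    A malformed record raises ``ValueError`` naming it.
    """
    from Bio import motifs as bio_motifs

    fmt = {"jaspar": "jaspar", "meme": "minimal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown motif format {format!r}")
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, fmt)
        except Exception as err:  # Bio raises assorted types on bad input
            raise ValueError(f"failed to parse motif file {path}: {err}") from err
    out = []
    for m in parsed:
        name = m.matrix_id if getattr(m, "matrix_id", None) else (m.name or f"motif{len(out)}")
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        try:
            out.append(PWM(id=str(name), probs=_counts_to_probs(counts, pseudocount),
                           source=format))
        except ValueError as err:
            raise ValueError(f"malformed motif record {name!r}: {err}") from err
    return out


def write_motifs(path, pwms: list[PWM]) -> None:
    """Write PWMs as JASPAR-format probability blocks (round-trips with
    ``read_motifs(path, pseudocount=0)``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            for base, row in zip("ACGT", pwm.probs):
                vals = " ".join(f"{v:.12f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def to_logodds(pwm: PWM, background: np.ndarray | None = None,
               pseudocount: float = 0.8, nsites: float = 100.0) -> np.ndarray:
    """4 x width log2-odds score matrix against a background model.

    The stored probabilities are treated as frequencies from ``nsites``
    count-equivalents and blended with ``pseudocount`` distributed by
    background composition:
    ``log2(((p * nsites + pc * b) / (nsites + pc)) / b)``.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be a strictly positive 4-vector summing to 1")
    p = (pwm.probs * nsites + pseudocount * bg[:, None]) / (nsites + pseudocount)
    return np.log2(p / bg[:, None])


# ---------------------------------------------------------------------------
# p-value threshold calibration
# ---------------------------------------------------------------------------


def pvalue_threshold(
    scores: np.ndarray,
    background: np.ndarray | None = None,
    p: float = 5e-5,
    bin_fraction: float | None = None,
    max_states: int = 2_000_000,
) -> float:
    """Smallest score t with P(random background word scores >= t) <= p.

    The null score distribution is computed by dynamic programming,
    convolving per-column score values position by position.  When every
    distinct partial sum can be tracked (and ``bin_fraction`` is not
    forced) the result is exact; otherwise entries are ceiled onto a grid
    of ``bin_fraction`` x score range (default 1/1000), which can only
    overstate word scores and therefore keeps the true tail at or below p.

    If even the maximum achievable score has tail probability above p the
    maximum score plus a tiny epsilon is returned with a warning (no word
    can be called).
    """
    scores = np.asarray(scores, dtype=float)
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")

    if bin_fraction is None:
        dist = _dp_exact(scores, bg, max_states)
        if dist is None:
            dist = _dp_binned(scores, bg, 1e-3)
    else:
        dist = _dp_binned(scores, bg, bin_fraction)

    values = np.array(sorted(dist))
    probs = np.array([dist[v] for v in values])
    tails = probs[::-1].cumsum()[::-1]  # tails[i] = P(score >= values[i])
    ok = np.nonzero(tails <= p)[0]
    if ok.size == 0:
        warnings.warn("requested p below the minimal achievable tail; "
                      "returning max score + eps (no word can be called)")
        return float(values[-1]) + 1e-9
    return float(values[ok[0]])


def _dp_exact(scores, bg, max_states):
    # accumulate left-to-right (same association order as the scanner), so
    # every DP value is bit-identical to an achievable window score
    dist = {0.0: 1.0}
    for j in range(scores.shape[1]):
        new: dict[float, float] = {}
        col = scores[:, j]
        for val, pr in dist.items():
            for b in range(4):
                nv = val + col[b]
                new[nv] = new.get(nv, 0.0) + pr * bg[b]
        if len(new) > max_states:
            return None
        dist = new
    return dist


def _dp_binned(scores, bg, bin_fraction):
    rng_span = scores.max(axis=0).sum() - scores.min(axis=0).sum()
    if rng_span <= 0:
        return {float(scores.sum(axis=0).min()): 1.0}
    width = bin_fraction * rng_span
    iscores = np.ceil(scores / width).astype(np.int64)  # ceil => conservative
    dist = {0: 1.0}
    for j in range(scores.shape[1]):
        new: dict[int, float] = {}
        col = iscores[:, j]
        for val, pr in dist.items():
            for b in range(4):
                nv = val + int(col[b])
                new[nv] = new.get(nv, 0.0) + pr * bg[b]
        dist = new
    return {v * width: pr for v, pr in dist.items()}


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Score of every window; windows containing N score -inf."""
    w = scores.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([scores, np.full((1, w), -np.inf)])  # row 4 = N
    total = np.zeros(n)
    for j in range(w):
        total += padded[codes[j:j + n], j]
    return total


def scan(sequences: dict[str, str], scores: np.ndarray, threshold: float,
         motif_id: str = "motif") -> list[MotifHit]:
    """Report every position on either strand scoring at or above threshold.

    ``sequences`` maps peak id to sequence; offsets are 0-based on the given
    (forward) sequence for both strands.  Windows containing N are skipped;
    sequences shorter than the motif yield no hits.
    """
    rc_scores = scores[::-1, ::-1]
    hits = []
    for peak_id, seq in sequences.items():
        codes = encode_sequence(seq)
        fwd = _window_scores(codes, scores)
        rev = _window_scores(codes, rc_scores)
        for off in np.nonzero(fwd >= threshold)[0]:
            hits.append(MotifHit(peak_id, motif_id, int(off), "+", float(fwd[off])))
        for off in np.nonzero(rev >= threshold)[0]:
            hits.append(MotifHit(peak_id, motif_id, int(off), "-", float(rev[off])))
    return hits


# ---------------------------------------------------------------------------
# binomial-Z enrichment
# ---------------------------------------------------------------------------


def binomial_z(N, C, p) -> float:
    """(C - Np) / sqrt(Np(1-p)): the binomial Z score for C motif-bearing
    peaks among N cluster peaks with background rate p."""
    N = np.asarray(N, dtype=float)
    C = np.asarray(C, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(N < 1):
        raise ValueError("N must be >= 1")
    if np.any((C < 0) | (C > N)):
        raise ValueError("C must lie in [0, N]")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    z = (C - N * p) / np.sqrt(N * p * (1 - p))
    return float(z) if z.ndim == 0 else z


def cluster_enrichment(membership: pd.DataFrame, clusters: pd.Series,
                       background: list[str] | None = None) -> pd.DataFrame:
    """Per (motif, cluster) binomial-Z enrichment table.

    ``membership`` is peaks x motifs boolean; ``clusters`` maps peak id to
    cluster id; ``background`` is the peak set defining p (defaults to all
    membership peaks).  Rows are ranked by Z within each cluster.  A motif
    absent from (or saturating) the background has no defined variance: its
    rows carry Z = NaN and ``flagged`` = True.
    """
    bg_ids = list(background) if background is not None else list(membership.index)
    if not bg_ids:
        raise ValueError("background peak set is empty")
    missing = set(clusters.index) - set(membership.index)
    if missing:
        raise ValueError(f"{len(missing)} cluster peaks missing from membership")
    bg = membership.loc[bg_ids]
    p_bg = bg.mean(axis=0).astype(float)
    rows = []
    for cluster_id, peak_ids in clusters.groupby(clusters).groups.items():
        sub = membership.loc[list(peak_ids)]
        N = len(sub)
        for motif in membership.columns:
            C = int(sub[motif].sum())
            p = float(p_bg[motif])
            if 0.0 < p < 1.0:
                z, flagged = binomial_z(N, C, p), False
            else:
                z, flagged = np.nan, True
            rows.append({"motif_id": motif, "cluster_id": cluster_id,
                         "N": N, "C": C, "p": p, "Z": z, "flagged": flagged})
    df = pd.DataFrame(rows)
    df = df.sort_values(["cluster_id", "Z"], ascending=[True, False],
                        na_position="last").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# chromVAR-style deviations
# ---------------------------------------------------------------------------


@dataclass
class DeviationMatrix:
    z: pd.DataFrame  # cells x motifs
    n_background: int
    excluded: list[str] = field(default_factory=list)
    #: per-draw mean |z| of the matched background peak sets (draws x motifs);
    #: the null distribution used to judge deviation significance
    null_mean_abs_z: pd.DataFrame | None = None


def _as_dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)


def deviation_scores(
    atac,
    membership: pd.DataFrame,
    n_background: int = 50,
    n_bins: int = 10,
    seed: int = 0,
    gc: pd.Series | None = None,
    min_peaks: int = 5,
) -> DeviationMatrix:
    """Background-standardized motif accessibility deviations per cell.

    The raw deviation of motif m in cell c is
    ``(observed - expected) / expected`` where the expectation follows the
    cell-depth x peak-mean product model.  Each motif's raw deviation is
    standardized against ``n_background`` random peak sets drawn within
    (GC, mean-accessibility) bins matched to the motif's member peaks.
    Motifs with fewer than ``min_peaks`` member peaks are excluded with a
    warning.
    """
    if n_background < 10:
        raise ValueError("n_background must be >= 10")
    if hasattr(atac, "X"):
        X = _as_dense(atac.X)
        peak_ids = list(atac.var_names)
        cell_ids = list(atac.obs_names)
    else:
        X = _as_dense(atac)
        peak_ids = list(membership.index)
        cell_ids = [f"cell{i}" for i in range(X.shape[0])]
    membership = membership.loc[peak_ids]
    M = membership.to_numpy(dtype=float)

    depth = X.sum(axis=1)
    peak_tot = X.sum(axis=0)
    grand = X.sum()
    expected = np.outer(depth, peak_tot) / grand  # cells x peaks

    peak_mean = X.mean(axis=0)
    gc_vals = (gc.loc[peak_ids].to_numpy() if gc is not None
               else np.zeros(len(peak_ids)))
    bins_gc = np.minimum(
        np.searchsorted(np.quantile(gc_vals, np.linspace(0, 1, n_bins + 1))[1:-1],
                        gc_vals, side="right"), n_bins - 1)
    bins_acc = np.minimum(
        np.searchsorted(np.quantile(peak_mean, np.linspace(0, 1, n_bins + 1))[1:-1],
                        peak_mean, side="right"), n_bins - 1)
    joint = bins_gc * n_bins + bins_acc
    pool: dict[int, np.ndarray] = {b: np.nonzero(joint == b)[0]
                                   for b in np.unique(joint)}

    rng = np.random.default_rng(seed)
    kept, excluded = [], []
    for motif in membership.columns:
        if M[:, membership.columns.get_loc(motif)].sum() < min_peaks:
            excluded.append(motif)
            logger.warning("motif %s has < %d member peaks; excluded", motif, min_peaks)
        else:
            kept.append(motif)
    Mk = membership[kept].to_numpy(dtype=float)

    exp = expected @ Mk
    exp = np.where(exp > 0, exp, 1.0)
    raw = (X @ Mk - expected @ Mk) / exp

    bg_dev = np.empty((n_background, X.shape[0], len(kept)))
    member_bins = [joint[Mk[:, j] > 0.5] for j in range(len(kept))]
    for it in range(n_background):
        Mb = np.zeros_like(Mk)
        for j in range(len(kept)):
            draws = [rng.choice(pool[b]) for b in member_bins[j]]
            Mb[draws, j] = 1.0
        expb = expected @ Mb
        expb = np.where(expb > 0, expb, 1.0)
        bg_dev[it] = (X @ Mb - expected @ Mb) / expb
    mu = bg_dev.mean(axis=0)
    sd = bg_dev.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (raw - mu) / sd
    zb = (bg_dev - mu[None]) / sd[None]  # standardized background draws
    null = pd.DataFrame(np.abs(zb).mean(axis=1), columns=kept)
    return DeviationMatrix(
        z=pd.DataFrame(z, index=cell_ids, columns=kept),
        n_background=n_background,
        excluded=excluded,
        null_mean_abs_z=null,
    )


def spearman_select(
    dev: DeviationMatrix,
    expr: pd.DataFrame,
    motif_to_gene: dict[str, str],
    fdr: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Motifs kept for downstream analysis: positively expression-correlated
    and with significant deviation magnitude.

    A motif passes when (a) the Spearman correlation between its per-cell
    deviation z and its TF gene's expression is positive with
    Benjamini-Hochberg adjusted p < ``fdr``, and (b) its mean |deviation z|
    exceeds the 95th percentile of a peak-relabeling null: ``n_perm``
    samples (seeded) drawn with replacement from the per-draw mean |z| of
    the matched background peak sets computed alongside the deviations.
    Motifs whose gene is constant are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for motif in dev.z.columns:
        gene = motif_to_gene.get(motif)
        if gene is None or gene not in expr.columns:
            raise ValueError(f"motif {motif} has no mapped gene in the expression matrix")
        e = expr[gene].to_numpy(dtype=float)
        if np.all(e == e[0]):
            logger.warning("gene %s constant; motif %s dropped", gene, motif)
            continue
        rho, pval = spearmanr(dev.z[motif].to_numpy(), e)
        rows.append({"motif_id": motif, "gene": gene, "rho": float(rho),
                     "p": float(pval), "mean_abs_z": float(np.abs(dev.z[motif]).mean())})
    if not rows:
        return pd.DataFrame(columns=["motif_id", "gene", "rho", "p", "padj",
                                     "mean_abs_z", "null_95", "selected"])
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]

    if dev.null_mean_abs_z is not None:
        null95 = []
        for motif in df["motif_id"]:
            draws = dev.null_mean_abs_z[motif].to_numpy()
            resampled = rng.choice(draws, size=n_perm, replace=True)
            null95.append(float(np.quantile(resampled, 0.95)))
        df["null_95"] = null95
    else:
        df["null_95"] = 0.0
    df["selected"] = (df["rho"] > 0) & (df["padj"] < fdr) & (df["mean_abs_z"] > df["null_95"])
    return df
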