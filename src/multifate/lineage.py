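"""Lineage signature scoring and Gaussian-mixture fate assignment.

A cell's (or sample's) epithelial output score for a lineage is the sum of
per-gene z-scores over that lineage's signature genes, where each gene is
standardized across units (sample standard deviation; zero-variance genes
contribute 0).  Score matrices are classified with a K-component Gaussian
mixture fitted by EM (K=2 for luminal/basal, K=3 for basal/L1/L2); discrete
fates are the maximum-posterior component.  Posterior summaries -- ECDFs of
class probabilities, ternary (barycentric) coordinates for three-class
posteriors, and lineage-proportion fold changes between genotypes -- support
the downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name} has duplicate genes")


def normalize_expression(counts) -> np.ndarray:
    """log(1 + 1e4 * x / cell_total) normalization; zero-total cells map to 0."""
    X = np.asarray(counts.todense()) if hasattr(counts, "todense") else np.asarray(counts, dtype=float)
    X = X.astype(float)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.where(totals > 0, 1e4 / np.where(totals > 0, totals, 1.0), 0.0)
    return np.log1p(X * scale)


def signature_zscore_sum(expr: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Sum of per-gene z-scores (across units, ddof=1) over signature genes.

    ``expr`` is units x genes with gene names as columns.  Genes missing from
    the matrix are ignored; an empty intersection raises.  Zero-variance
    genes contribute 0 to every unit, preserving signature length.
    """
    if len(expr) < 2:
        raise ValueError("need at least 2 units to standardize")
    present = [g for g in sig.genes if g in expr.columns]
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} found in matrix")
    sub = expr[present].to_numpy(dtype=float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.sum(axis=1), index=expr.index, name=sig.name)


def score_matrix(expr: pd.DataFrame, signatures: list[GeneSignature]) -> pd.DataFrame:
    """Units x signatures matrix of z-score sums."""
    return pd.DataFrame({s.name: signature_zscore_sum(expr, s) for s in signatures})


# ---------------------------------------------------------------------------
# Gaussian mixture EM
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D) diagonal, or (K, D, D) full
    log_likelihood_trace: np.ndarray
    posteriors: np.ndarray  # (n, K)
    bic: float
    seed: int
    covariance: str = "diag"

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])


def _log_gauss_diag(X: np.ndarray, means: np.ndarray, variances: np.ndarray
                    ) -> np.ndarray:
    # (n, K) log N(x | mu_k, diag(var_k))
    n, D = X.shape
    out = np.empty((n, means.shape[0]))
    for k in range(means.shape[0]):
        v = variances[k]
        out[:, k] = -0.5 * (
            np.sum(np.log(2 * np.pi * v)) + np.sum((X - means[k]) ** 2 / v, axis=1)
        )
    return out


def _log_gauss_full(X, means, covs):
    from scipy.stats import multivariate_normal

    out = np.empty((X.shape[0], means.shape[0]))
    for k in range(means.shape[0]):
        out[:, k] = multivariate_normal.logpdf(X, means[k], covs[k],
                                               allow_singular=False)
    return out


def fit_gmm(
    scores,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    covariance: str = "diag",
    var_floor: float = 1e-8,
    max_restarts: int = 5,
    n_init: int = 5,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM with k-means++ initialization.

    Covariances are diagonal by default (``covariance="full"`` is available).
    Iteration stops when the relative log-likelihood gain drops below
    ``tol``.  EM is run from ``n_init`` seeded k-means++ initializations and
    the fit with the highest final log-likelihood is returned; a run whose
    smallest variance collapses below ``var_floor`` is restarted with a
    fresh seed, at most ``max_restarts`` times.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, D = X.shape
    if n <= K:
        raise ValueError("need more units than components")
    if covariance not in ("diag", "full"):
        raise ValueError("covariance must be 'diag' or 'full'")

    best: MixtureFit | None = None
    last_err: Exception | None = None
    for init in range(max(n_init, 1)):
        fit = None
        for restart in range(max_restarts + 1):
            run_seed = seed + 7919 * init + 1000 * restart
            try:
                fit = _em_once(X, K, run_seed, tol, max_iter, covariance,
                               var_floor, report_seed=seed)
                break
            except _DegenerateComponent as err:
                last_err = err
        if fit is not None and (best is None or fit.log_likelihood > best.log_likelihood):
            best = fit
    if best is None:
        raise RuntimeError(
            f"GMM fit degenerate after {max_restarts} restarts: {last_err}"
        )
    return best


class _DegenerateComponent(RuntimeError):
    pass


def _em_once(X, K, seed, tol, max_iter, covariance, var_floor, report_seed):
    n, D = X.shape
    rng = np.random.RandomState(seed)
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=rng)
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
    assign = d2.argmin(axis=1)
    weights = np.array([(assign == k).sum() / n for k in range(K)])
    weights = np.clip(weights, 1e-6, None)
    weights /= weights.sum()
    means = centers.copy()
    global_var = X.var(axis=0) + 1e-6
    if covariance == "diag":
        variances = np.tile(global_var, (K, 1))
    else:
        variances = np.tile(np.diag(global_var), (K, 1, 1))

    trace = []
    for _ in range(max_iter):
        # E step
        if covariance == "diag":
            logp = _log_gauss_diag(X, means, variances)
        else:
            logp = _log_gauss_full(X, means, variances)
        logw = logp + np.log(weights)
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logw - norm[:, None])

        if trace and ll - trace[-1] < tol * abs(trace[-1]):
            trace.append(max(ll, trace[-1]))
            break
        trace.append(ll)

        # M step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        if covariance == "diag":
            variances = np.empty((K, D))
            for k in range(K):
                diff = X - means[k]
                variances[k] = (resp[:, k] @ (diff ** 2)) / nk[k]
            if variances.min() < var_floor:
                raise _DegenerateComponent(f"variance collapsed to {variances.min():.2e}")
        else:
            variances = np.empty((K, D, D))
            for k in range(K):
                diff = X - means[k]
                variances[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
                variances[k] += np.eye(D) * 1e-9
            if min(np.linalg.eigvalsh(variances[k]).min() for k in range(K)) < var_floor:
                raise _DegenerateComponent("covariance collapsed")

    # final posteriors at the converged parameters
    logp = (_log_gauss_diag if covariance == "diag" else _log_gauss_full)(
        X, means, variances
    )
    logw = logp + np.log(weights)
    norm = logsumexp(logw, axis=1)
    posteriors = np.exp(logw - norm[:, None])
    ll = float(norm.sum())
    n_params = (K - 1) + K * D + (K * D if covariance == "diag" else K * D * (D + 1) // 2)
    bic = -2 * ll + n_params * np.log(n)
    return MixtureFit(
        K=K, weights=weights, means=means, variances=variances,
        log_likelihood_trace=np.asarray(trace), posteriors=posteriors,
        bic=bic, seed=report_seed, covariance=covariance,
    )


def match_components(fit: MixtureFit, axis_names: list[str]) -> dict[int, str]:
    """Label components by matching component means to score axes.

    The component with the highest mean on the L1 axis becomes L1, etc.;
    ambiguity is resolved by maximum-weight bipartite assignment on the
    (component, axis) mean matrix.
    """
    if fit.K != len(axis_names) or fit.means.shape[1] != len(axis_names):
        raise ValueError("need one score axis per component")
    gain = fit.means  # (K, D); axis d corresponds to axis_names[d]
    row, col = linear_sum_assignment(-gain)
    return {int(r): axis_names[c] for r, c in zip(row, col)}


def classify_units(fit: MixtureFit, labels: dict[int, str]) -> np.ndarray:
    """Maximum-posterior discrete label per unit; ties go to the lower index."""
    if set(labels) != set(range(fit.K)):
        raise ValueError("labels must cover every component")
    comp = fit.posteriors.argmax(axis=1)  # argmax takes the first (lowest) on ties
    return np.array([labels[int(k)] for k in comp])


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def ecdf_eval(values, grid) -> np.ndarray:
    """Right-continuous empirical CDF F(t) = #{values <= t} / n on ``grid``."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot evaluate the ECDF of an empty sample")
    g = np.asarray(grid, dtype=float)
    return np.searchsorted(v, g, side="right") / v.size


#: Vertices of the unit ternary triangle (rows: class 0, 1, 2).
TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])


def ternary_coords(posteriors) -> np.ndarray:
    """Barycentric embedding of unit x 3 posteriors into the unit triangle."""
    P = np.asarray(posteriors, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.shape[1] != 3:
        raise ValueError("ternary coordinates need exactly 3 classes")
    if (P < 0).any():
        raise ValueError("posteriors must be non-negative")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("posterior rows must sum to 1")
    return P @ TERNARY_VERTICES


def ternary_to_posteriors(coords) -> np.ndarray:
    """Inverse of :func:`ternary_coords` (exact for points in the triangle)."""
    C = np.asarray(coords, dtype=float)
    if C.ndim == 1:
        C = C[None, :]
    p2 = C[:, 1] / TERNARY_VERTICES[2, 1]
    p1 = C[:, 0] - 0.5 * p2
    p0 = 1.0 - p1 - p2
    return np.column_stack([p0, p1, p2])


def proportions_and_foldchange(labels, groups, reference: str) -> pd.DataFrame:
    """Per-group lineage fractions and fold changes versus a reference group.

    Fold change is group fraction / reference fraction; a zero reference
    fraction yields ``inf`` with the ``unbounded`` flag set.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    group_names = list(pd.unique(groups))
    if reference not in group_names:
        raise ValueError(f"reference group {reference!r} not present")
    lineages = list(pd.unique(labels))
    rows = []
    ref_frac = {}
    for lin in lineages:
        mask = groups == reference
        if mask.sum() == 0:
            raise ValueError("empty reference group")
        ref_frac[lin] = (labels[mask] == lin).mean()
    for g in group_names:
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        for lin in lineages:
            frac = (labels[mask] == lin).mean()
            if ref_frac[lin] > 0:
                fc, unbounded = frac / ref_frac[lin], False
            else:
                fc, unbounded = np.inf, frac > 0
            rows.append({"group": g, "lineage": lin, "fraction": frac,
                         "fold_change": fc, "unbounded": unbounded})
    return pd.DataFrame(rows)
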