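"""Unbiased morphological clustering of astrocytes.

Pipeline: z-score normalization of the morphometric table, bimodality
screening with the multimodal index (MMI), Ward hierarchical clustering
on the selected features, cluster-number choice by the Thorndike elbow of
the within-cluster distance curve, silhouette validation, an optional
t-SNE embedding for visualization, and layer × cluster enrichment
statistics with a two-sided Fisher exact test (full enumeration for
small tables, seeded Monte Carlo otherwise).

The multimodal index of a feature with ``n`` samples is

    MMI = (M3² + 1) / (M4 + 3 (n − 1)² / ((n − 2)(n − 3)))

with M3 the bias-corrected sample skewness and M4 the bias-corrected
sample *excess* kurtosis (the bimodality-coefficient convention, whose
finite-sample correction term is exactly the one above).  Population
limits: 1/3 for a normal, 5/9 for a uniform, 1 for a balanced two-point
mixture; the conventional selection threshold 0.55 sits just below the
uniform benchmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "MMIResult",
    "ClusteringResult",
    "ContingencyResult",
    "zscore_normalize",
    "mmi",
    "mmi_table",
    "select_features",
    "ward_cluster",
    "within_cluster_distance",
    "thorndike_optimal_k",
    "silhouette",
    "embed_tsne",
    "fisher_exact_rxc",
    "layer_cluster_stats",
]


# ---------------------------------------------------------------- normalize

def zscore_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature to mean 0, sd 1 (sample sd, n−1 divisor).

    Constant (zero-variance) features are dropped with a log entry; a
    single-row table is rejected.
    """
    if len(table) < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    sd = table.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        logger.info("dropping constant features: %s", list(constant))
    kept = table.drop(columns=constant)
    return (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)


# ---------------------------------------------------------------- MMI

@dataclass(frozen=True)
class MMIResult:
    """Per-feature bimodality screen: moments and the MMI value."""

    m3: float  # bias-corrected sample skewness
    m4: float  # bias-corrected sample excess kurtosis
    n: int
    mmi: float

    def selected(self, threshold: float = 0.55) -> bool:
        return np.isfinite(self.mmi) and self.mmi > threshold


def mmi(values) -> MMIResult:
    """Multimodal index of one feature (see module docstring).

    Requires ``n >= 4`` and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        raise ValueError(f"MMI requires n >= 4 finite values, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("MMI undefined for zero-variance values")
    m3 = float(stats.skew(x, bias=False))
    m4 = float(stats.kurtosis(x, fisher=True, bias=False))
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return MMIResult(m3=m3, m4=m4, n=n, mmi=(m3**2 + 1.0) / (m4 + corr))


def mmi_table(table: pd.DataFrame) -> pd.DataFrame:
    """MMI screen of every feature; uncomputable features get NaN."""
    rows = {}
    for name in table.columns:
        try:
            r = mmi(table[name].to_numpy())
            rows[name] = (r.m3, r.m4, r.n, r.mmi)
        except ValueError as e:
            logger.info("MMI absent for %s: %s", name, e)
            rows[name] = (np.nan, np.nan, len(table), np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["m3", "m4", "n", "mmi"]
    )


def select_features(table: pd.DataFrame, threshold: float = 0.55) -> list[str]:
    """Features whose MMI strictly exceeds ``threshold``, in table order.

    An empty selection triggers a warning (clustering on all features
    then requires an explicit override by the caller).
    """
    mt = mmi_table(table)
    selected = [name for name in table.columns if mt.loc[name, "mmi"] > threshold]
    if not selected:
        warnings.warn(
            f"no feature exceeds MMI threshold {threshold}; "
            "pass the full feature list explicitly to cluster anyway",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------- clustering

@dataclass
class ClusteringResult:
    """Ward linkage with per-K labels, elbow curve and diagnostics."""

    linkage: np.ndarray
    k_range: tuple[int, ...]
    labels: dict[int, np.ndarray]
    within_distance: dict[int, float]
    chosen_k: int | None = None
    silhouette_values: np.ndarray | None = None
    embedding: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def ward_cluster(table, k_range=range(1, 9)) -> ClusteringResult:
    """Ward minimum-variance clustering (Euclidean, Ward.D2 contract).

    Returns labels (1..K) for every K in ``k_range`` plus the total
    within-cluster distance curve (sum of squared Euclidean distances to
    cluster centroids).  Ties are resolved by scipy's deterministic
    lowest-index merge order.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("table must be 2D")
    ks = tuple(int(k) for k in k_range)
    if not ks or min(ks) < 1 or max(ks) > len(X):
        raise ValueError(f"k_range must lie within [1, {len(X)}]")
    Z = hierarchy.linkage(X, method="ward")
    labels = {k: hierarchy.fcluster(Z, t=k, criterion="maxclust") for k in ks}
    wss = {k: within_cluster_distance(X, labels[k]) for k in ks}
    return ClusteringResult(linkage=Z, k_range=ks, labels=labels, within_distance=wss)


def within_cluster_distance(X, labels) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return total


def thorndike_optimal_k(
    result: ClusteringResult, rel_tol: float = 1e-6
) -> tuple[int | None, pd.Series]:
    """Elbow of the within-cluster distance curve.

    The "sudden marked flattening" is operationalized as the K that
    maximizes the second forward difference W(K−1) − 2 W(K) + W(K+1) of
    the curve; a curve that is linear in K (all second differences below
    ``rel_tol`` × curve range) has no elbow and returns ``None``.  The
    full curve is always returned for inspection.
    """
    ks = sorted(result.within_distance)
    curve = pd.Series([result.within_distance[k] for k in ks], index=ks, name="wss")
    if len(ks) < 3:
        return None, curve
    w = curve.to_numpy()
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]  # indexed by interior K
    rng = float(w.max() - w.min())
    if rng == 0 or d2.max() <= rel_tol * rng:
        logger.info("within-cluster distance curve has no elbow")
        return None, curve
    chosen = int(ks[1 + int(np.argmax(d2))])
    result.chosen_k = chosen
    return chosen, curve


def silhouette(table, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) and their mean.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the mean distance
    to the sample's own cluster (excluding itself) and b(i) the smallest
    mean distance to any other cluster.  Samples in singleton clusters
    get s(i) = 0, as does the degenerate a = b = 0 tie.
    """
    X = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    D = np.sqrt(
        np.maximum(
            0.0,
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T,
        )
    )
    n = len(X)
    s = np.zeros(n)
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (len(own) - 1)
        b = min(D[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return s, float(s.mean())


def embed_tsne(
    table,
    perplexity: float = 30.0,
    max_iter: int = 100_000,
    seed: int = 510,
) -> np.ndarray:
    """2D t-SNE embedding for visualization (never for assignment).

    Uses the exact-gradient t-SNE (the theta = 0 Barnes–Hut limit) with
    a fixed seed; requires ``n > 3 × perplexity``.
    """
    X = np.asarray(table, dtype=float)
    if len(X) <= 3 * perplexity:
        raise ValueError(
            f"n = {len(X)} too small for perplexity {perplexity}; "
            "need n > 3*perplexity — reduce perplexity or add samples"
        )
    from sklearn.manifold import TSNE

    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max(max_iter, 250),
        method="exact",
        init="pca",
        random_state=seed,
    )
    return ts.fit_transform(X)


# ---------------------------------------------------------------- Fisher exact

def _log_table_prob(table, lgf_rows, lgf_cols, lgf_n):
    return lgf_rows + lgf_cols - lgf_n - gammaln(np.asarray(table) + 1.0).sum()


def fisher_exact_rxc(
    table,
    max_tables: float = 1e7,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Two-sided Fisher exact test for an r×c contingency table.

    Full enumeration over all tables with the observed margins when
    their number stays below ``max_tables`` (two-sided p = total
    probability of tables no more probable than the observed one);
    otherwise a seeded Monte Carlo estimate from ``n_mc`` tables drawn
    from the null (multivariate hypergeometric via label permutation).
    Returns ``(p, method)`` with method "enumeration" or "monte-carlo".
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or np.any(T < 0):
        raise ValueError("table must be a non-negative 2D count array")
    T = T[T.sum(1) > 0][:, T.sum(0) > 0]
    if T.size == 0 or T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0, "degenerate"
    rows, cols = T.sum(1), T.sum(0)
    n = int(T.sum())
    lgf_rows = gammaln(rows + 1.0).sum()
    lgf_cols = gammaln(cols + 1.0).sum()
    lgf_n = gammaln(n + 1.0)
    logp_obs = _log_table_prob(T, lgf_rows, lgf_cols, lgf_n)
    tol = 1e-7  # tables within tol of the observed probability count as "as extreme"

    acc = 0.0
    count = 0
    r, c = T.shape
    lgf = gammaln(np.arange(n + 2) + 1.0)  # factorial lookup

    # cheap upper bound on the candidate-table count: compositions of
    # each column sum into r parts (ignores row constraints)
    import math

    est = 1.0
    for cj in cols:
        est *= math.comb(int(cj) + r - 1, r - 1)
        if est > max_tables:
            break
    enumerable = est <= max_tables

    def recurse(i, row_rem, col_rem, logfact_acc):
        # fill row i; returns False if the table budget is exhausted
        nonlocal acc, count
        if i == r - 1:
            count += 1
            if count > max_tables:
                return False
            lp = lgf_rows + lgf_cols - lgf_n - logfact_acc - lgf[col_rem].sum()
            if lp <= logp_obs + tol:
                acc += np.exp(lp)
            return True
        return _fill_row(i, 0, row_rem[i], row_rem, col_rem, logfact_acc)

    def _fill_row(i, j, rem, row_rem, col_rem, logfact_acc):
        if j == c - 1:
            if rem > col_rem[j]:
                return True
            col_rem2 = col_rem.copy()
            col_rem2[j] -= rem
            return recurse(i + 1, row_rem, col_rem2, logfact_acc + lgf[rem])
        lo = max(0, rem - int(col_rem[j + 1 :].sum()))
        hi = min(rem, int(col_rem[j]))
        for v in range(lo, hi + 1):
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            if not _fill_row(
                i, j + 1, rem - v, row_rem, col_rem2, logfact_acc + lgf[v]
            ):
                return False
        return True

    if enumerable and recurse(0, rows, cols.astype(np.int64).copy(), 0.0):
        return min(1.0, float(acc)), "enumeration"

    # Monte Carlo fallback: permute column labels of the pooled sample
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(r), rows)
    col_of = np.repeat(np.arange(c), cols)
    const = lgf_rows + lgf_cols - lgf_n
    hits = 0
    chunk = 50_000
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        keys = rng.random((b, n))
        perms = np.argsort(keys, axis=1)
        codes = row_of[None, :] * c + col_of[perms]
        offset = np.arange(b)[:, None] * (r * c)
        counts = np.bincount((codes + offset).ravel(), minlength=b * r * c).reshape(b, r, c)
        logp = const - lgf[counts].sum(axis=(1, 2))
        hits += int(np.count_nonzero(logp <= logp_obs + tol))
        done += b
    return (hits + 1) / (n_mc + 1), "monte-carlo"


@dataclass
class ContingencyResult:
    """Layer × cluster counts with enrichment statistics."""

    table: pd.DataFrame  # rows = layers, columns = clusters
    p_value: float
    method: str
    layer_composition: pd.DataFrame  # per-layer % across clusters (rows sum to 100)
    cluster_composition: pd.DataFrame  # per-cluster % across layers (columns sum to 100)


def layer_cluster_stats(
    labels, layers, n_mc: int = 1_000_000, seed: int = 0, max_tables: float = 1e7
) -> ContingencyResult:
    """Cross-tabulate cluster labels against layers and test association.

    Empty margin rows/columns are dropped (logged); the two-sided exact
    p comes from :func:`fisher_exact_rxc`.  Both composition views are
    returned: each layer's percentage split across clusters (rows sum to
    100) and each cluster's split across layers (columns sum to 100).
    """
    tab = pd.crosstab(pd.Series(layers, name="layer"), pd.Series(labels, name="cluster"))
    empty_rows = tab.index[tab.sum(1) == 0]
    empty_cols = tab.columns[tab.sum(0) == 0]
    if len(empty_rows) or len(empty_cols):
        logger.info("dropping empty margins: rows %s cols %s", list(empty_rows), list(empty_cols))
        tab = tab.drop(index=empty_rows, columns=empty_cols)
    p, method = fisher_exact_rxc(tab.to_numpy(), max_tables=max_tables, n_mc=n_mc, seed=seed)
    layer_comp = tab.div(tab.sum(1), axis=0) * 100.0
    cluster_comp = tab.div(tab.sum(0), axis=1) * 100.0
    return ContingencyResult(
        table=tab,
        p_value=p,
        method=method,
        layer_composition=layer_comp,
        cluster_composition=cluster_comp,
    )
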