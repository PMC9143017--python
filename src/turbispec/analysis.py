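"""Multi-endpoint statistics: PCA, spectral clustering, silhouettes,
information gain, group tests, and through-origin linearity.

The analysis treats each subject as a point in a 2-4 dimensional endpoint
space (subsets of TMRE, Bodipy FL C16, SO2, [Hb]).  Endpoints carry
incommensurable units, so every multivariate step starts by z-scoring.
Clustering is spectral: a full Gaussian-similarity graph (scale = median
pairwise distance unless given), symmetric-normalized Laplacian embedding,
and seeded k-means on the leading eigenvectors.  Per-point silhouette scores
S(i) = (b(i) - a(i)) / max(a(i), b(i)) quantify cluster fit; per-endpoint
information gain (equal-frequency discretization) quantifies how much each
variable explains the true labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .cohort import ENDPOINTS
from .errors import DegenerateInputError, InvalidArgumentError


@dataclass
class ClusteringResult:
    """Full record of one endpoint-subset clustering analysis."""

    endpoint_subset: tuple
    pc_scores: np.ndarray  # subjects x components
    explained_variance: np.ndarray  # percent, sums to 100
    assignments: np.ndarray  # cluster ids, 1-based
    silhouettes: np.ndarray
    mean_silhouette_by_cluster: dict
    mean_silhouette_by_true_label: dict
    information_gain: dict  # endpoint -> bits
    config: dict

    def report(self) -> dict:
        return {
            "endpoint_subset": list(self.endpoint_subset),
            "explained_variance_percent": [float(v) for v in self.explained_variance],
            "mean_silhouette_by_cluster": {str(k): float(v) for k, v in
                                           self.mean_silhouette_by_cluster.items()},
            "mean_silhouette_by_true_label": {str(k): float(v) for k, v in
                                              self.mean_silhouette_by_true_label.items()},
            "information_gain_bits": {k: float(v) for k, v in self.information_gain.items()},
            "mean_silhouette": float(np.mean(self.silhouettes)),
            "config": self.config,
        }


def pca_endpoints(table: pd.DataFrame, subset) -> dict:
    """PCA of z-scored endpoint columns.

    Returns ``{"pc_scores", "explained_variance", "loadings"}``; components
    are ordered by decreasing variance, variances expressed in percent of the
    total, and each component's sign fixed so its largest-magnitude loading
    is positive.
    """
    subset = tuple(subset)
    if len(subset) < 2:
        raise InvalidArgumentError("PCA subset needs at least 2 endpoints")
    x = table.loc[:, list(subset)].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise InvalidArgumentError("endpoint subset contains undefined values")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = subset[int(np.argmax(sd == 0))]
        raise DegenerateInputError(f"endpoint {bad!r} is constant; cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * s
    var = s**2
    explained = 100.0 * var / var.sum()
    return {"pc_scores": scores, "explained_variance": explained, "loadings": vt}


def spectral_cluster(pc_scores, k: int = 2, kernel_scale: float | None = None, seed: int = 0) -> np.ndarray:
    """Spectral clustering on a full Gaussian-similarity graph.

    Affinity W_ij = exp(-d_ij^2 / (2 sigma^2)) with sigma the median pairwise
    distance unless supplied; symmetric-normalized Laplacian embedding into
    the k leading eigenvectors (rows normalized) followed by seeded k-means.
    Returns 1-based labels; identity of the labels is arbitrary.
    """
    x = np.asarray(pc_scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k < 1 or k > n:
        raise InvalidArgumentError(f"k={k} incompatible with n={n} points")
    if k == 1:
        return np.ones(n, dtype=int)
    d = pdist(x)
    if kernel_scale is None:
        positive = d[d > 0]
        kernel_scale = float(np.median(positive)) if positive.size else 1.0
    if kernel_scale <= 0:
        raise InvalidArgumentError("kernel_scale must be positive")
    w = np.exp(-squareform(d) ** 2 / (2.0 * kernel_scale**2))
    deg = w.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    m = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(m)  # ascending; leading = last k
    emb = vecs[:, -k:]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    return km.fit_predict(emb).astype(int) + 1


def silhouette_scores(points, assignments) -> np.ndarray:
    """Per-point silhouette S(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i): mean Euclidean distance to the other members of i's cluster;
    b(i): smallest mean distance to another cluster (with two clusters, the
    opposite cluster).  Singleton clusters score 0, as does the degenerate
    a = b = 0 case.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise InvalidArgumentError("silhouette requires at least 2 clusters")
    dist = squareform(pdist(x))
    scores = np.zeros(x.shape[0])
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    for i in range(x.shape[0]):
        own = members[labels[i]]
        if own.size == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.size - 1)
        b = min(dist[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores


def information_gain(values, labels, n_bins: int = 3) -> float:
    """Reduction in label entropy (bits) from equal-frequency binning of a feature.

    IG = H(labels) - sum_bins p(bin) * H(labels | bin).  Always in
    [0, H(labels)]; returns 0 (with a warning) when only one label value.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise InvalidArgumentError("values and labels must be equal-length 1-D")
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    if np.unique(y).size < 2:
        warnings.warn("labels take a single value; information gain is 0", stacklevel=2)
        return 0.0

    def entropy(lab):
        _, counts = np.unique(lab, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(v, edges, right=True)
    h = entropy(y)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * entropy(y[mask])
    return max(0.0, h - cond)


def group_stats(table: pd.DataFrame, endpoint: str, group_a: str, group_b: str) -> dict:
    """Two-group comparison and time trend for one endpoint.

    Wilcoxon rank-sum: exact two-sided null distribution for combined n <= 20
    without ties, normal approximation otherwise.  Pearson r is computed
    against the timepoint column across both groups when it varies.
    """
    xa = table.loc[table["group"] == group_a, endpoint].to_numpy(dtype=float)
    xb = table.loc[table["group"] == group_b, endpoint].to_numpy(dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise InvalidArgumentError("each group needs at least 2 observations")
    combined = np.concatenate([xa, xb])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        stat = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="exact")
        p = float(stat.pvalue)
    else:
        p = float(stats.ranksums(xa, xb).pvalue)
    out = {"wilcoxon_p": p, "significant": p <= 0.05}
    sub = table[table["group"].isin([group_a, group_b])]
    t = sub["timepoint"].to_numpy(dtype=float)
    if np.unique(t).size > 1:
        r, rp = stats.pearsonr(t, sub[endpoint].to_numpy(dtype=float))
        out["pearson_r_vs_time"] = float(r)
        out["pearson_p"] = float(rp)
    else:
        out["pearson_r_vs_time"] = None
        out["pearson_p"] = None
    return out


def uptake_anova(curves: pd.DataFrame, dv: str = "intensity", within: str = "timepoint",
                 subject: str = "subject", between: str = "arm") -> float:
    """Mixed repeated-measures ANOVA; returns the between-arm main-effect p.

    One between factor (injection arm) and one within factor (timepoint);
    requires a balanced table with no missing cells.
    """
    import pingouin as pg

    counts = curves.groupby([subject, within]).size()
    if (counts != 1).any():
        raise InvalidArgumentError("each subject must have exactly one value per timepoint")
    per_subject = curves.groupby(subject)[within].nunique()
    if per_subject.nunique() != 1:
        raise InvalidArgumentError("timepoints must be balanced across subjects")
    if curves[between].nunique() < 2:
        raise InvalidArgumentError("need at least two arms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=curves, dv=dv, within=within, subject=subject, between=between)
    row = aov.loc[aov["Source"] == between]
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return float(row[pcol].iloc[0])


def linearity_r2(x, y, through_origin: bool = True) -> dict:
    """Best-fit line (optionally through the origin) and its R^2.

    Through-origin slope = sum(xy)/sum(x^2); in both cases R^2 is
    1 - SS_res / SS_tot with SS_tot taken about the mean of y, so a forced
    zero intercept is penalized when the data do not pass through the origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidArgumentError("need >= 3 paired points")
    if through_origin:
        sxx = float((x * x).sum())
        if sxx == 0:
            raise DegenerateInputError("all x are zero; through-origin slope undefined")
        slope = float((x * y).sum() / sxx)
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("y is constant; R^2 undefined")
    return {"slope": float(slope), "intercept": float(intercept),
            "r2": 1.0 - float((resid**2).sum()) / ss_tot}


def cluster_endpoints(
    table: pd.DataFrame,
    subset,
    k: int = 2,
    n_bins: int = 3,
    kernel_scale: float | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """End-to-end analysis of one endpoint subset: PCA on all components,
    spectral clustering, silhouettes, and per-endpoint information gain
    against the true group labels."""
    pca = pca_endpoints(table, subset)
    assignments = spectral_cluster(pca["pc_scores"], k=k, kernel_scale=kernel_scale, seed=seed)
    sil = silhouette_scores(pca["pc_scores"], assignments)
    labels = table["group"].to_numpy()
    by_cluster = {int(c): float(sil[assignments == c].mean()) for c in np.unique(assignments)}
    by_label = {str(lab): float(sil[labels == lab].mean()) for lab in np.unique(labels)}
    ig = {ep: information_gain(table[ep].to_numpy(dtype=float), labels, n_bins=n_bins)
          for ep in subset}
    return ClusteringResult(
        endpoint_subset=tuple(subset),
        pc_scores=pca["pc_scores"],
        explained_variance=pca["explained_variance"],
        assignments=assignments,
        silhouettes=sil,
        mean_silhouette_by_cluster=by_cluster,
        mean_silhouette_by_true_label=by_label,
        information_gain=ig,
        config={"k": k, "n_bins": n_bins, "binning": "equal_frequency",
                "kernel_scale": kernel_scale if kernel_scale is not None else "median_pairwise",
                "seed": seed,
                "note": "information gain conditions the labels on feature bins"},
    )


def endpoint_subsets(all_endpoints=ENDPOINTS, size: int = 3) -> list:
    """All size-``size`` combinations of the endpoints, in canonical order."""
    from itertools import combinations

    return [tuple(c) for c in combinations(all_endpoints, size)]
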