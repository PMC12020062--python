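"""Bioactivity clustering with multiscale-bootstrap cluster significance.

Materials are clustered on their endpoint/time-point-specific slice scores
by agglomerative clustering (Euclidean, Cityblock, Cosine, Hamming or
Minkowski distance; Ward, single, complete or average linkage).  The
number of clusters can be fixed or chosen by the elbow or silhouette
method, and clusterings are graded by the Silhouette, Davies-Bouldin and
Calinski-Harabasz indices.

Cluster support is assessed by multiscale bootstrap resampling in the
style of pvclust: the feature columns are resampled with replacement at a
range of relative sizes r, the data are reclustered, and for each original
dendrogram node the bootstrap probability BP_r of its member set
reappearing is recorded.  Fitting z_r = Phi^-1(1 - BP_r) against
v*sqrt(r) + c/sqrt(r) by weighted least squares yields the approximately
unbiased p-value AU = 1 - Phi(v - c) and the scale-1 bootstrap probability
BP = 1 - Phi(v + c).  Clusters with AU above 95% are conventionally taken
as strongly supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn import metrics as skm

SUPPORTED_METRICS = {"euclidean", "cityblock", "cosine", "hamming", "minkowski"}
SUPPORTED_LINKAGES = {"ward", "single", "complete", "average"}

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))


class ClusteringError(ValueError):
    pass


def _as_matrix(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ClusteringError("expected a 2-D materials x features matrix")
    if not np.isfinite(arr).all():
        raise ClusteringError("clustering input must not contain missing values")
    return arr


def agglomerate(X, metric: str = "euclidean", linkage: str = "ward") -> np.ndarray:
    """Hierarchical clustering; returns the merge (linkage) matrix."""
    arr = _as_matrix(X)
    if arr.shape[0] < 2:
        raise ClusteringError("need at least 2 materials")
    if metric not in SUPPORTED_METRICS:
        raise ClusteringError(f"unsupported metric {metric!r}")
    if linkage not in SUPPORTED_LINKAGES:
        raise ClusteringError(f"unsupported linkage {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ClusteringError("Ward linkage requires the Euclidean metric")
    return hierarchy.linkage(pdist(arr, metric=metric), method=linkage)


def cut_labels(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a dendrogram into k flat clusters (labels 1..k)."""
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def choose_k(
    X,
    method: str = "elbow",
    k_max: int | None = None,
    metric: str = "euclidean",
    linkage: str = "ward",
) -> int:
    """Pick the number of clusters by the elbow or silhouette method.

    Elbow: k maximizing the second difference W(k-1) - 2W(k) + W(k+1) of
    the total within-cluster sum of squares along the dendrogram cuts.
    Silhouette: k maximizing the mean silhouette coefficient.  Degenerate
    data with no usable optimum fall back to k = 2.
    """
    arr = _as_matrix(X)
    n = arr.shape[0]
    if n < 3:
        raise ClusteringError("need at least 3 materials to choose k")
    if k_max is None:
        k_max = min(10, n - 1)
    if not 2 <= k_max < n:
        raise ClusteringError("require 2 <= k_max < n")
    Z = agglomerate(arr, metric=metric, linkage=linkage)
    if method == "elbow":
        W = {k: _within_ss(arr, cut_labels(Z, k)) for k in range(1, k_max + 2)}
        curvature = {k: W[k - 1] - 2 * W[k] + W[k + 1] for k in range(2, k_max + 1)}
        best = max(curvature, key=curvature.get)
        if curvature[best] <= 0:
            return 2
        return best
    if method == "silhouette":
        scores = {}
        for k in range(2, k_max + 1):
            labels = cut_labels(Z, k)
            if len(np.unique(labels)) < 2:
                continue
            scores[k] = skm.silhouette_score(arr, labels, metric=metric)
        if not scores:
            return 2
        return max(scores, key=scores.get)
    raise ClusteringError(f"unknown method {method!r}")


def cluster_quality(X, labels) -> dict[str, float]:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz indices.

    An index undefined for the given partition (e.g. singleton-only
    clusterings) is reported as NaN.
    """
    arr = _as_matrix(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClusteringError("need at least 2 clusters")
    out = {}
    for name, fn in (
        ("silhouette", skm.silhouette_score),
        ("davies_bouldin", skm.davies_bouldin_score),
        ("calinski_harabasz", skm.calinski_harabasz_score),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = float(fn(arr, labels))
        except ValueError:
            out[name] = float("nan")
    return out


# ---------------------------------------------------------------------------
# pvclust-style multiscale bootstrap
# ---------------------------------------------------------------------------

def node_member_sets(Z: np.ndarray, n: int) -> list[frozenset]:
    """Member sets of the n-1 internal dendrogram nodes, in merge order."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, *_rest) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        out.append(merged)
    return out


@dataclass
class MultiscaleBootstrapFit:
    """Per-node multiscale bootstrap record and its (v, c) fit."""

    members: frozenset
    scales: np.ndarray
    bp_counts: np.ndarray
    n_boot: int
    v: float
    c: float
    au: float
    bp: float
    raw_bp: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_au_bp(
    scales, bp_values, n_boot: int
) -> tuple[float, float, float, float]:
    """WLS fit of z_r = v*sqrt(r) + c/sqrt(r) -> (v, c, AU, BP).

    BP_r are clipped to [1/(n_boot+1), n_boot/(n_boot+1)] before the
    probit; weights are the inverse delta-method variances of z_r from the
    binomial counts.  The fit uses only scales with interior BP (0 < BP_r
    < 1): a probit of a boundary value carries no information about the
    curve's shape.  When fewer than 2 interior scales remain the node is
    degenerate — unanimously recovered (AU = BP = 1) or never recovered
    (AU = BP = 0), decided by the mean raw BP_r.  A node with BP_r = 0.5
    everywhere fits v = c = 0, hence AU = BP = 0.5.
    """
    r = np.asarray(scales, dtype=float)
    bp = np.asarray(bp_values, dtype=float)
    ok = np.isfinite(bp) & np.isfinite(r)
    r, bp = r[ok], bp[ok]
    if r.size == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    interior = (bp > 0.0) & (bp < 1.0)
    if np.unique(r[interior]).size < 2:
        side = 1.0 if float(np.mean(bp)) >= 0.5 else 0.0
        return float("nan"), float("nan"), side, side
    r, bp = r[interior], bp[interior]
    lo = 1.0 / (n_boot + 1)
    bp = np.clip(bp, lo, 1.0 - lo)
    z = sps.norm.ppf(1.0 - bp)
    dens = sps.norm.pdf(z)
    w = n_boot * dens**2 / (bp * (1.0 - bp))
    A = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    Aw = A * np.sqrt(w)[:, None]
    zw = z * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(Aw, zw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - sps.norm.cdf(v - c))
    bp1 = float(1.0 - sps.norm.cdf(v + c))
    return v, c, au, bp1


def multiscale_bootstrap(
    X,
    metric: str = "euclidean",
    linkage: str = "ward",
    scales=DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MultiscaleBootstrapFit]:
    """AU/BP cluster support by resampling feature columns at several scales.

    For each scale r, ``round(r * p)`` feature columns are drawn with
    replacement, the materials are reclustered with the same metric and
    linkage, and each original node's member set is counted when it
    reappears among the resampled dendrogram's nodes.  Deterministic under
    a fixed seed.
    """
    arr = _as_matrix(X)
    n, p = arr.shape
    if p < 2:
        raise ClusteringError("multiscale bootstrap needs >= 2 feature columns")
    scales = np.asarray(scales, dtype=float)
    if np.unique(scales).size < 2:
        raise ClusteringError("need >= 2 distinct scales")
    rng = np.random.default_rng(seed)
    Z = agglomerate(arr, metric=metric, linkage=linkage)
    nodes = node_member_sets(Z, n)
    counts = np.zeros((len(scales), len(nodes)), dtype=int)
    node_index = {m: i for i, m in enumerate(nodes)}
    for si, r in enumerate(scales):
        m = max(2, int(round(r * p)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, size=m)
            Zb = agglomerate(arr[:, cols], metric=metric, linkage=linkage)
            for member_set in node_member_sets(Zb, n):
                j = node_index.get(member_set)
                if j is not None:
                    counts[si, j] += 1
    out = []
    for j, members in enumerate(nodes):
        bp_r = counts[:, j] / n_boot
        v, c, au, bp = fit_au_bp(scales, bp_r, n_boot)
        out.append(
            MultiscaleBootstrapFit(
                members=members,
                scales=scales.copy(),
                bp_counts=counts[:, j].copy(),
                n_boot=n_boot,
                v=v,
                c=c,
                au=au,
                bp=bp,
                raw_bp=bp_r,
            )
        )
    return out


def au_bp_table(
    fits: list[MultiscaleBootstrapFit], names: list[str] | None = None
) -> pd.DataFrame:
    """Summarize node fits as a table (members, AU, BP, v, c)."""
    rows = []
    for i, f in enumerate(fits):
        members = sorted(f.members)
        labels = [names[m] for m in members] if names else members
        rows.append(
            {
                "node": i,
                "n_members": len(members),
                "members": ";".join(str(x) for x in labels),
                "au": f.au,
                "bp": f.bp,
                "v": f.v,
                "c": f.c,
            }
        )
    return pd.DataFrame(rows)


def dendrogram_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (heights as lengths)."""
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    text = {i: names[i] for i in range(n)}
    for i, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        text[n + i] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
        height[n + i] = h
    return text[n + len(Z) - 1] + ";"
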