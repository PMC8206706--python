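"""Multiscale-bootstrap hierarchical clustering with AU p-values.

Items (population-type mean-correlation vectors) are clustered by UPGMA on
Euclidean distance.  Cluster support is assessed by resampling the feature
dimensions with replacement at a ladder of sample-size scale factors r: for
each internal node of the observed dendrogram the per-scale bootstrap
proportion BP_r (fraction of bootstrap trees containing the same member set)
is modelled as

    BP_r = 1 - Phi(v * sqrt(r) + c / sqrt(r)),

with (v, c) fitted by maximum binomial likelihood, yielding the approximately
unbiased support AU = 1 - Phi(v - c) and the scale-corrected bootstrap
probability BP_corrected = 1 - Phi(v + c).  Nodes whose counts are all-zero
or all-full across scales are assigned AU = 0 / 1 without fitting; a failed
likelihood fit falls back to weighted least squares on probit-transformed
proportions (flagged in the output).

A companion PCA-with-convex-hulls view projects the signatures onto two
centred principal axes and draws each sufficiently supported cluster as the
convex hull of its member coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import norm

__all__ = [
    "DEFAULT_SCALES",
    "Dendrogram",
    "ClusterNodeStats",
    "upgma",
    "fit_probit_model",
    "multiscale_au",
    "correlation_pca_hulls",
    "to_newick",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


@dataclass
class Dendrogram:
    """Binary merge tree with UPGMA heights.

    ``merges`` lists (cluster_id_a, cluster_id_b, height, size) rows in merge
    order, scipy linkage convention (leaves are 0..n-1, the i-th merge forms
    cluster n+i).  ``node_members`` holds the canonical sorted label tuple of
    each internal node, in merge order.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    node_members: list[tuple[str, ...]]

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def linkage(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h, _ in self.merges])


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def upgma(vectors: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomeration over Euclidean distances.

    Deterministic tie-breaking: among equal-distance candidate merges, the
    pair whose sorted member tuples are lexicographically smallest wins.
    Heights are the mean pairwise distance between the merged clusters
    (Lance–Williams update), non-decreasing from leaves to root.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 vectors to cluster")
    n = x.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length does not match the number of vectors")
    if len(set(labels)) != n:
        raise ValueError("duplicate item labels")

    dist = _pairwise_euclidean(x)
    # Active clusters: id -> (member tuple, size). Leaves get ids 0..n-1.
    members: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    node_members: list[tuple[str, ...]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for key, dij in d.items():
            i, j = sorted(key)
            mi, mj = sorted((members[i], members[j]))
            cand = (dij, mi, mj, i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        assert best is not None
        h, _, _, i, j = best
        new_members = tuple(sorted(members[i] + members[j]))
        new_size = sizes[i] + sizes[j]
        merges.append((i, j, h, new_size))
        node_members.append(new_members)
        active.discard(i)
        active.discard(j)
        for other in active:
            dio = d.pop(frozenset((i, other)))
            djo = d.pop(frozenset((j, other)))
            d[frozenset((next_id, other))] = (
                sizes[i] * dio + sizes[j] * djo
            ) / new_size
        del d[frozenset((i, j))]
        members[next_id] = new_members
        sizes[next_id] = new_size
        active.add(next_id)
        next_id += 1
    return Dendrogram(labels=list(labels), merges=merges, node_members=node_members)


@dataclass
class ClusterNodeStats:
    """Bootstrap support for one internal dendrogram node."""

    members: tuple[str, ...]
    scales: np.ndarray
    counts: np.ndarray
    nboot: int
    bp: np.ndarray  # per-scale bootstrap proportions
    v: float
    c: float
    au: float
    bp_corrected: float
    flag: str = "ml"  # ml | wls | degenerate | bp_only

    @property
    def bp_at_unit_scale(self) -> float:
        i = int(np.argmin(np.abs(self.scales - 1.0)))
        return float(self.bp[i])


def _wls_probit(counts: np.ndarray, nboot: int, scales: np.ndarray) -> tuple[float, float]:
    """Weighted least squares on probit-transformed proportions.

    Counts of 0 / nboot are pulled in by 0.5 so the probit is finite.
    """
    cc = np.clip(counts.astype(float), 0.5, nboot - 0.5)
    bp = cc / nboot
    z = norm.ppf(1.0 - bp)  # = v sqrt(r) + c / sqrt(r)
    sq = np.sqrt(scales)
    design = np.column_stack([sq, 1.0 / sq])
    w = nboot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    wsqrt = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * wsqrt[:, None], z * wsqrt, rcond=None)
    return float(beta[0]), float(beta[1])


def fit_probit_model(
    counts: np.ndarray, nboot: int, scales: np.ndarray
) -> tuple[float, float, str]:
    """Fit (v, c) of BP_r = 1 - Phi(v sqrt(r) + c / sqrt(r)).

    Maximum binomial likelihood with a WLS fall-back; returns (v, c, flag)
    where flag is ``'ml'`` or ``'wls'``.
    """
    counts = np.asarray(counts, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if counts.shape != scales.shape:
        raise ValueError("counts and scales must have equal length")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    sq = np.sqrt(scales)

    def nll(params: np.ndarray) -> float:
        v, c = params
        p = 1.0 - norm.cdf(v * sq + c / sq)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(counts * np.log(p) + (nboot - counts) * np.log(1.0 - p))

    v0, c0 = _wls_probit(counts, nboot, scales)
    res = minimize(nll, x0=np.array([v0, c0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if res.success and np.all(np.isfinite(res.x)):
        return float(res.x[0]), float(res.x[1]), "ml"
    return v0, c0, "wls"


def multiscale_au(
    vectors: np.ndarray,
    labels: list[str] | None = None,
    nboot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> tuple[Dendrogram, list[ClusterNodeStats]]:
    """Observed UPGMA tree plus per-node multiscale bootstrap support.

    The P feature dimensions are resampled with replacement at size
    ``round(r * P)`` for each scale factor r; a node's per-scale count is the
    number of bootstrap trees containing exactly its member set.  With a
    single scale the probit fit is impossible, so plain BP values are
    reported (AU/v/c = NaN) with a warning.
    """
    x = np.asarray(vectors, dtype=float)
    if nboot < 1:
        raise ValueError("nboot must be >= 1")
    scales_arr = np.asarray(scales, dtype=float)
    if np.any(scales_arr <= 0):
        raise ValueError("scales must be positive")
    tree = upgma(x, labels)
    p = x.shape[1]
    rng = np.random.default_rng(seed)

    observed = tree.node_members
    counts = {m: np.zeros(len(scales_arr), dtype=np.int64) for m in observed}
    for si, r in enumerate(scales_arr):
        m_r = max(1, int(round(r * p)))
        for _ in range(nboot):
            cols = rng.integers(0, p, size=m_r)
            boot_tree = upgma(x[:, cols], tree.labels)
            hit = set(boot_tree.node_members)
            for mem in observed:
                if mem in hit:
                    counts[mem][si] += 1

    single_scale = len(scales_arr) < 2
    if single_scale:
        warnings.warn(
            "multiscale_au: fewer than 2 scales — reporting plain BP only, "
            "AU fitting skipped",
            stacklevel=2,
        )

    stats: list[ClusterNodeStats] = []
    for mem in observed:
        cnt = counts[mem]
        bp = cnt / nboot
        if single_scale:
            stats.append(
                ClusterNodeStats(mem, scales_arr, cnt, nboot, bp,
                                 float("nan"), float("nan"), float("nan"),
                                 float("nan"), flag="bp_only")
            )
            continue
        if np.all(cnt == nboot):
            stats.append(
                ClusterNodeStats(mem, scales_arr, cnt, nboot, bp,
                                 float("nan"), float("nan"), 1.0, 1.0,
                                 flag="degenerate")
            )
            continue
        if np.all(cnt == 0):
            stats.append(
                ClusterNodeStats(mem, scales_arr, cnt, nboot, bp,
                                 float("nan"), float("nan"), 0.0, 0.0,
                                 flag="degenerate")
            )
            continue
        v, c, flag = fit_probit_model(cnt, nboot, scales_arr)
        au = float(1.0 - norm.cdf(v - c))
        bpc = float(1.0 - norm.cdf(v + c))
        stats.append(ClusterNodeStats(mem, scales_arr, cnt, nboot, bp, v, c, au, bpc, flag))
    return tree, stats


def au_cluster_assignment(
    tree: Dendrogram, stats: list[ClusterNodeStats], au_threshold: float = 0.75
) -> dict[tuple[str, ...], float]:
    """Maximal supported clusters: nodes with AU >= threshold not contained
    in any larger supported node."""
    supported = [s for s in stats if np.isfinite(s.au) and s.au >= au_threshold]
    supported.sort(key=lambda s: -len(s.members))
    chosen: list[ClusterNodeStats] = []
    for s in supported:
        if len(s.members) == tree.n_items:
            continue  # the root carries no grouping information
        if any(set(s.members) <= set(c.members) for c in chosen):
            continue
        chosen.append(s)
    return {s.members: s.au for s in chosen}


def correlation_pca_hulls(
    signatures: np.ndarray,
    labels: list[str],
    clusters: dict[str, int],
    cluster_au: dict[int, float] | None = None,
    au_threshold: float = 0.75,
) -> dict:
    """Centred PCA of signatures with per-cluster convex hulls.

    ``clusters`` maps item label -> cluster id; clusters whose AU support is
    below the threshold (when given) are skipped.  Clusters with fewer than
    3 points, or with degenerate (collinear) geometry, emit their raw point
    set as the hull.  Returns coordinates, hull vertex lists, the biplot
    loading vectors of the P feature dimensions, and explained-variance
    fractions.
    """
    x = np.asarray(signatures, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 signatures for the PCA view")
    if len(labels) != x.shape[0]:
        raise ValueError("labels length does not match signatures")
    centred = x - x.mean(axis=0)
    if np.allclose(centred, 0.0, atol=1e-12):
        raise ValueError("all signatures identical: no variance to project")
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    for j in range(vt.shape[0]):  # sign convention as in the trait-scape
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
    coords = centred @ vt[:2].T
    var_explained = svals**2 / np.sum(svals**2)

    hulls: dict[int, np.ndarray] = {}
    for cid in sorted(set(clusters.values())):
        if cluster_au is not None:
            au = cluster_au.get(cid, float("nan"))
            if not (np.isfinite(au) and au >= au_threshold):
                continue
        idx = [i for i, lab in enumerate(labels) if clusters.get(lab) == cid]
        pts = coords[idx]
        if len(idx) < 3:
            hulls[cid] = pts
            continue
        try:
            hull = ConvexHull(pts)
            hulls[cid] = pts[hull.vertices]
        except QhullError:  # collinear cluster: degenerate hull
            hulls[cid] = pts
    return {
        "coords": coords,
        "labels": list(labels),
        "hulls": hulls,
        "vectors": vt[:2].T,  # (P, 2) biplot loadings, rows = correlations
        "var_explained": var_explained[:2],
    }


def to_newick(tree: Dendrogram, node_labels: dict[tuple[str, ...], str] | None = None) -> str:
    """Serialize with branch lengths; internal-node labels (e.g. AU values)
    are attached via the optional member-set -> label mapping."""
    n = tree.n_items
    heights = {i: 0.0 for i in range(n)}
    reprs = {i: _escape(tree.labels[i]) for i in range(n)}
    for idx, (a, b, h, _) in enumerate(tree.merges):
        node_id = n + idx
        left = f"{reprs[a]}:{h - heights[a]:.10g}"
        right = f"{reprs[b]}:{h - heights[b]:.10g}"
        lab = ""
        if node_labels:
            lab = _escape(node_labels.get(tree.node_members[idx], ""))
        reprs[node_id] = f"({left},{right}){lab}"
        heights[node_id] = h
    return reprs[n + len(tree.merges) - 1] + ";"


def _escape(label: str) -> str:
    if label and any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
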