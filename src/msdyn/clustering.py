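"""Topographic clustering of GFP-peak maps.

The central algorithm is T-AAHC (Topographic Atomize and Agglomerate
Hierarchical Clustering): starting from singleton clusters, the cluster
contributing least global explained variance (GEV) is repeatedly dissolved
and its member maps reassigned to the remaining cluster whose centroid they
correlate with most strongly in absolute value. All comparisons are
polarity-invariant: a microstate map and its sign-flip are the same brain
state, because the generating dipole's orientation oscillates.

Cluster-number selection reimplements the usual battery of validity
indices (Davies-Bouldin, silhouette, Dunn, point-biserial, Gamma,
Krzanowski-Lai, predictive-residual cross-validation) on the
polarity-invariant correlation distance d = 1 - |r|, with a modal vote as
the meta-criterion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import TemplateSet

__all__ = [
    "gmd",
    "spatial_correlation",
    "normalize_maps",
    "taahc",
    "k_selection_criteria",
    "canonical_labels",
    "modified_kmeans",
    "group_templates",
]


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference each map and scale to unit L2 norm."""
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-GFP map cannot be normalized")
    return maps / norms


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation across channels of two topographies."""
    un = normalize_maps(u)[0]
    vn = normalize_maps(v)[0]
    return float(un @ vn)


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Polarity-invariant global map dissimilarity, in [0, sqrt(2)].

    Both maps are average-referenced and scaled to unit GFP; the returned
    value is the smaller RMS difference over the two polarities, so that
    GMD**2 = 2 * (1 - |r|) with r the spatial correlation.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = u.size
    # unit GFP = spatial standard deviation 1 = L2 norm sqrt(C) after
    # average reference
    un = normalize_maps(u)[0] * np.sqrt(c)
    vn = normalize_maps(v)[0] * np.sqrt(c)
    d_same = np.sqrt(np.mean((un - vn) ** 2))
    d_flip = np.sqrt(np.mean((un + vn) ** 2))
    return float(min(d_same, d_flip))


def _aligned_centroid(members: np.ndarray, init: np.ndarray | None = None,
                      mode: str = "pc1") -> np.ndarray:
    """Polarity-invariant representative map of a set of normalized maps.

    ``mode="pc1"`` (default): dominant spatial pattern — the leading
    eigenvector of the member scatter, which maximizes the cluster's GEV
    contribution and is sign-agnostic by construction. ``mode="mean"``:
    flip each member to positive correlation with the current centroid,
    average, renormalize (iterated to a fixed sign pattern); cheaper but
    can settle on poor fixed points for heterogeneous clusters.
    """
    if members.shape[0] == 1:
        return members[0]
    if mode == "pc1":
        m, c_dim = members.shape
        if m <= c_dim:  # eigenvector via the smaller Gram matrix
            g = members @ members.T
            vals, vecs = np.linalg.eigh(g)
            c = members.T @ vecs[:, -1]
        else:
            s = members.T @ members
            vals, vecs = np.linalg.eigh(s)
            c = vecs[:, -1]
        return c / np.linalg.norm(c)
    c = members[0] if init is None else init
    for _ in range(8):
        signs = np.sign(members @ c)
        signs[signs == 0] = 1.0
        new = (signs[:, None] * members).mean(axis=0)
        nrm = np.linalg.norm(new)
        if nrm == 0:  # perfectly cancelling pair; fall back to first member
            return members[0]
        new = new / nrm
        if np.array_equal(np.sign(members @ new), signs):
            return new
        c = new
    return c


class _AAHCState:
    """Mutable agglomeration state: clusters, centroids, GEV contributions."""

    def __init__(self, maps: np.ndarray, weights: np.ndarray, centroid_mode: str):
        self.maps = maps
        self.w2 = weights**2
        self.total_w2 = float(self.w2.sum())
        self.centroid_mode = centroid_mode
        self.members: dict[int, list[int]] = {i: [i] for i in range(len(maps))}
        self.centroids: dict[int, np.ndarray] = {
            i: maps[i] for i in range(len(maps))
        }
        self.contrib: dict[int, float] = {
            i: float(self.w2[i]) for i in range(len(maps))
        }

    def _refresh(self, cid: int) -> None:
        idx = np.asarray(self.members[cid])
        c = _aligned_centroid(self.maps[idx], self.centroids.get(cid),
                              self.centroid_mode)
        self.centroids[cid] = c
        r = self.maps[idx] @ c
        self.contrib[cid] = float(np.sum(self.w2[idx] * r**2))

    def atomize_worst(self) -> None:
        worst = min(self.contrib, key=self.contrib.get)
        freed = self.members.pop(worst)
        del self.centroids[worst]
        del self.contrib[worst]
        cids = list(self.members)
        cmat = np.stack([self.centroids[c] for c in cids])
        r = np.abs(self.maps[freed] @ cmat.T)  # |freed| x n_clusters
        dest = np.argmax(r, axis=1)
        touched = set()
        for m, d in zip(freed, dest):
            self.members[cids[d]].append(m)
            touched.add(cids[d])
        for cid in touched:
            self._refresh(cid)

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def template_set(self, labels: list[str] | None = None) -> TemplateSet:
        cids = sorted(self.members, key=lambda c: -self.contrib[c])
        maps = normalize_maps(np.stack([self.centroids[c] for c in cids]))
        if labels is None:
            labels = [f"M{i+1}" for i in range(len(cids))]
        gev = sum(self.contrib[c] for c in cids) / self.total_w2
        return TemplateSet(maps=maps, labels=labels, gev_total=float(gev))

    def assignment(self) -> np.ndarray:
        cids = sorted(self.members, key=lambda c: -self.contrib[c])
        out = np.empty(len(self.maps), dtype=np.int64)
        for rank, cid in enumerate(cids):
            out[np.asarray(self.members[cid])] = rank
        return out


def _run_aahc(
    maps: np.ndarray,
    weights: np.ndarray | None,
    stop_ks: set[int],
    centroid_mode: str,
) -> dict[int, tuple[TemplateSet, np.ndarray]]:
    maps = normalize_maps(maps)
    n = maps.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if min(stop_ks) < 1 or max(stop_ks) > n:
        raise ValueError("requested cluster counts outside [1, n_maps]")
    st = _AAHCState(maps, weights, centroid_mode)
    out: dict[int, tuple[TemplateSet, np.ndarray]] = {}
    if n in stop_ks:
        out[n] = (st.template_set(), st.assignment())
    while st.n_clusters > min(stop_ks):
        st.atomize_worst()
        if st.n_clusters in stop_ks:
            out[st.n_clusters] = (st.template_set(), st.assignment())
    return out


def taahc(
    maps: np.ndarray,
    k: int,
    weights: np.ndarray | None = None,
    centroid_mode: str = "pc1",
    return_assignment: bool = False,
):
    """Cluster N topographies into k templates by atomize-and-agglomerate.

    Parameters
    ----------
    maps
        N x C matrix of (typically GFP-peak) maps; normalized internally.
    k
        Number of clusters to stop at.
    weights
        Per-map weights (usually the GFP at the peak) entering the GEV
        objective; defaults to 1.
    centroid_mode
        ``"pc1"`` (default) for the first principal pattern of each
        cluster, or ``"mean"`` for the polarity-aligned member mean.

    Returns the :class:`TemplateSet` (templates sorted by descending GEV
    contribution), and the per-map cluster assignment when requested.
    """
    maps = np.atleast_2d(maps)
    if maps.shape[0] < k:
        raise ValueError(f"need at least k={k} maps, got {maps.shape[0]}")
    sols = _run_aahc(maps, weights, {k}, centroid_mode)
    ts, assign = sols[k]
    uniq = normalize_maps(ts.maps)
    if k > 1:
        cc = np.abs(uniq @ uniq.T)
        np.fill_diagonal(cc, 0.0)
        if cc.max() > 0.999:
            warnings.warn("duplicate templates: input maps may be degenerate")
    if return_assignment:
        return ts, assign
    return ts


# ---------------------------------------------------------------------------
# Cluster-number selection


def _pair_distance(maps_n: np.ndarray) -> np.ndarray:
    d = 1.0 - np.abs(maps_n @ maps_n.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def _dispersion(maps_n, assign, centroids) -> float:
    """Within-cluster sum of squared correlation distances to centroids."""
    r = np.abs(np.einsum("nc,nc->n", maps_n, centroids[assign]))
    return float(np.sum((1.0 - r) ** 2))


def k_selection_criteria(
    maps: np.ndarray,
    k_range: range | list[int] = range(2, 8),
    weights: np.ndarray | None = None,
    seed: int = 0,
    max_gamma_pairs: int = 4000,
) -> tuple[pd.DataFrame, int]:
    """Score T-AAHC solutions over a range of cluster counts.

    For each k the nested T-AAHC solution is evaluated with seven validity
    indices on the polarity-invariant distance d = 1 - |r|:
    Davies-Bouldin (min), silhouette (max), Dunn (max), point-biserial
    (max), Goodman-Kruskal Gamma (max, pair-subsampled), Krzanowski-Lai
    (max) and a predictive-residual cross-validation criterion (min).
    Returns the criteria table and the modal best k (ties -> smaller k).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if min(ks) < 2:
        raise ValueError("cluster-validity indices need k >= 2")
    maps_n = normalize_maps(maps)
    n, c = maps_n.shape
    # KL needs neighbours of each k
    need = set(ks) | {min(ks) - 1, max(ks) + 1} - {0}
    need = {k for k in need if 1 <= k <= n}
    sols = _run_aahc(maps_n, weights, need, "pc1")
    D = _pair_distance(maps_n)
    rng = np.random.default_rng(seed)

    disp = {
        k: _dispersion(maps_n, a, normalize_maps(ts.maps))
        for k, (ts, a) in sols.items()
    }

    rows = []
    for k in ks:
        ts, assign = sols[k]
        cent = normalize_maps(ts.maps)
        row = {"k": k}

        # Davies-Bouldin on correlation distance
        S = np.array(
            [
                np.mean(1.0 - np.abs(maps_n[assign == i] @ cent[i]))
                for i in range(k)
            ]
        )
        M = 1.0 - np.abs(cent @ cent.T)
        db = 0.0
        for i in range(k):
            ratios = [
                (S[i] + S[j]) / max(M[i, j], 1e-12) for j in range(k) if j != i
            ]
            db += max(ratios)
        row["davies_bouldin"] = db / k

        # silhouette
        from sklearn.metrics import silhouette_score

        if len(np.unique(assign)) > 1:
            row["silhouette"] = float(
                silhouette_score(D, assign, metric="precomputed")
            )
        else:
            row["silhouette"] = np.nan

        # Dunn: min between-cluster distance / max within-cluster diameter
        within_max, between_min = 0.0, np.inf
        for i in range(k):
            di = D[np.ix_(assign == i, assign == i)]
            if di.size > 1:
                within_max = max(within_max, float(di.max()))
            for j in range(i + 1, k):
                dij = D[np.ix_(assign == i, assign == j)]
                if dij.size:
                    between_min = min(between_min, float(dij.min()))
        row["dunn"] = between_min / max(within_max, 1e-12)

        # point-biserial: corr(pair distance, different-cluster indicator)
        iu = np.triu_indices(n, 1)
        dvec = D[iu]
        diff = (assign[iu[0]] != assign[iu[1]]).astype(float)
        sd = dvec.std()
        row["point_biserial"] = (
            float(np.corrcoef(dvec, diff)[0, 1]) if sd > 0 else np.nan
        )

        # Goodman-Kruskal Gamma, subsampled pairs of (within, between) dists
        wmask = diff == 0
        wd, bd = dvec[wmask], dvec[~wmask]
        if wd.size and bd.size:
            wi = rng.choice(wd.size, min(wd.size, max_gamma_pairs))
            bi = rng.choice(bd.size, min(bd.size, max_gamma_pairs))
            comp = bd[bi][None, :] - wd[wi][:, None]
            s_plus = np.count_nonzero(comp > 0)
            s_minus = np.count_nonzero(comp < 0)
            row["gamma"] = (s_plus - s_minus) / max(s_plus + s_minus, 1)
        else:
            row["gamma"] = np.nan

        # Krzanowski-Lai
        def _diff(kk: int) -> float:
            if kk - 1 not in disp or kk not in disp:
                return np.nan
            p = c - 1  # effective dimensionality after average reference
            return (kk - 1) ** (2 / p) * disp[kk - 1] - kk ** (2 / p) * disp[kk]

        d_k, d_k1 = _diff(k), _diff(k + 1)
        row["krzanowski_lai"] = (
            abs(d_k) / abs(d_k1) if np.isfinite(d_k) and d_k1 not in (0,) and
            np.isfinite(d_k1) else np.nan
        )

        # predictive-residual cross-validation criterion (min)
        r = np.abs(np.einsum("nc,nc->n", maps_n, cent[assign]))
        sigma2 = float(np.sum(1.0 - r**2)) / (n * (c - 1))
        row["cv"] = sigma2 * ((c - 1) / (c - 1 - k)) ** 2

        rows.append(row)

    table = pd.DataFrame(rows).set_index("k")
    direction = {
        "davies_bouldin": "min",
        "silhouette": "max",
        "dunn": "max",
        "point_biserial": "max",
        "gamma": "max",
        "krzanowski_lai": "max",
        "cv": "min",
    }
    votes = []
    for col, how in direction.items():
        s = table[col].dropna()
        if s.empty:
            continue
        votes.append(int(s.idxmax() if how == "max" else s.idxmin()))
    best = int(pd.Series(votes).mode().min()) if votes else ks[0]
    return table, best


# ---------------------------------------------------------------------------
# Canonical labeling


def canonical_labels(
    ts: TemplateSet, archetypes: TemplateSet | None = None
) -> TemplateSet:
    """Assign canonical letters A-D by matching against archetype maps.

    A one-to-one assignment maximizing total absolute spatial correlation
    (Hungarian algorithm) maps each template to an archetype; templates are
    reordered to A, B, C, D and sign-aligned with their archetype. The
    correlation matrix is stored as provenance. For K != 4 the templates
    keep generic M1..MK labels.
    """
    if archetypes is None:
        from .synthetic import make_templates

        if ts.ch_names is None:
            raise ValueError("channel names required to build archetypes")
        archetypes = make_templates(
            n_channels=len(ts.ch_names), k=4, ch_names=list(ts.ch_names)
        )
    if ts.k != archetypes.k:
        warnings.warn(
            f"K={ts.k} != {archetypes.k} archetypes; keeping generic labels"
        )
        return ts.reordered(range(ts.k), [f"M{i+1}" for i in range(ts.k)])
    R = normalize_maps(ts.maps) @ normalize_maps(archetypes.maps).T
    rows, cols = linear_sum_assignment(-np.abs(R))
    order = rows[np.argsort(cols)]  # template index assigned to archetype j
    maps = normalize_maps(ts.maps)[order]
    signs = np.sign(np.einsum("kc,kc->k", maps, normalize_maps(archetypes.maps)))
    signs[signs == 0] = 1.0
    out = TemplateSet(
        maps=maps * signs[:, None],
        labels=list(archetypes.labels),
        ch_names=ts.ch_names,
        gev_total=ts.gev_total,
        k_criteria=ts.k_criteria,
        label_provenance={
            "correlation_matrix": np.abs(R).tolist(),
            "assignment": order.tolist(),
        },
    )
    return out


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    weights: np.ndarray | None = None,
    n_init: int = 5,
    max_iter: int = 100,
    seed: int = 0,
) -> TemplateSet:
    """Polarity-invariant k-means on topographies (optional cross-check).

    Alternating assignment (max |r| to a centroid) and centroid update
    (first principal pattern), restarted ``n_init`` times from random
    seeds; the restart with the highest GEV wins. Serves as an independent
    check on :func:`taahc`, not as the default clustering.
    """
    maps_n = normalize_maps(maps)
    n = maps_n.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    w2 = (np.ones(n) if weights is None else np.asarray(weights, float)) ** 2
    rng = np.random.default_rng(seed)
    best_gev, best_cent = -1.0, None
    for _ in range(n_init):
        cent = maps_n[rng.choice(n, size=k, replace=False)]
        assign = None
        for _ in range(max_iter):
            r = np.abs(maps_n @ cent.T)
            new_assign = np.argmax(r, axis=1)
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in range(k):
                m = maps_n[assign == c]
                if len(m):
                    cent[c] = _aligned_centroid(m, mode="pc1")
        r = np.abs(np.einsum("nc,nc->n", maps_n, cent[assign]))
        gev = float(np.sum(w2 * r**2) / w2.sum())
        if gev > best_gev:
            best_gev, best_cent = gev, cent.copy()
    return TemplateSet(
        maps=normalize_maps(best_cent),
        labels=[f"M{i+1}" for i in range(k)],
        gev_total=best_gev,
    )


def group_templates(
    subject_sets: list[TemplateSet], k: int = 4, centroid_mode: str = "pc1"
) -> TemplateSet:
    """Second-level T-AAHC across subjects' template maps.

    Subject-level templates (already one vote per subject per class) are
    pooled with equal weight and re-clustered to k group templates.
    """
    stacked = np.concatenate([normalize_maps(s.maps) for s in subject_sets])
    ts = taahc(stacked, k, centroid_mode=centroid_mode)
    ch = subject_sets[0].ch_names
    ts.ch_names = ch
    return ts
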