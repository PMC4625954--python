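"""Ward clustering of CGI+SS signatures with bootstrap stability.

Clustering is performed directly on the DTW dissimilarity matrix via the
Lance-Williams Ward update (scipy linkage on the condensed matrix), not on an
embedding.  Cut clusters are relabeled canonically by their members' mean
island methylation so that "cluster 1" is always the hypo-methylated group,
"cluster 2" the hyper-methylated one, and (at k >= 3) cluster 3, 4, ... the
intermediate, hemi-methylated groups in ascending order of methylation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import fowlkes_mallows_score

from .dtw import dissimilarity_matrix  # noqa: F401  (re-exported surface)
from .profiles import Signature


@dataclass
class ClusterAssignment:
    """Cluster labels for one condition plus the linkage merge history."""

    condition: str
    labels: dict[str, int]                 # cgi_id -> canonical cluster id
    sublabels: dict[str, str] = field(default_factory=dict)  # cgi_id -> 3up/3down/none
    linkage: np.ndarray | None = None

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]


def _canonical_relabel(raw: np.ndarray, order_values: np.ndarray | None) -> np.ndarray:
    """Map arbitrary cut labels to 1..k.

    With ``order_values`` (per-item mean island methylation): lowest-mean
    cluster -> 1, highest -> 2, remaining -> 3, 4, ... ascending.  Without
    them, clusters are numbered by descending size (ties by first occurrence).
    """
    uniq = np.unique(raw)
    k = len(uniq)
    if order_values is not None:
        means = np.array([order_values[raw == u].mean() for u in uniq])
        ascending = uniq[np.argsort(means, kind="stable")]
        new_ids = np.empty(k, dtype=int)
        if k == 1:
            new_ids[0] = 1
        else:
            order = [ascending[0], ascending[-1], *ascending[1:-1]]
            for rank, u in enumerate(order, start=1):
                new_ids[np.where(uniq == u)[0][0]] = rank
        mapping = dict(zip(uniq, new_ids))
    else:
        sizes = [-(raw == u).sum() for u in uniq]
        order = uniq[np.argsort(sizes, kind="stable")]
        mapping = {u: r for r, u in enumerate(order, start=1)}
    return np.array([mapping[u] for u in raw])


def ward_linkage(D: np.ndarray) -> np.ndarray:
    return linkage(squareform(D, checks=False), method="ward")


def ward_cluster(D: np.ndarray, k: int, cgi_ids: list[str] | None = None,
                 island_means: np.ndarray | None = None,
                 condition: str = "") -> ClusterAssignment:
    """Cut the Ward tree of a dissimilarity matrix at ``k`` clusters."""
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    Z = ward_linkage(D)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_relabel(raw, island_means)
    ids = cgi_ids if cgi_ids is not None else [str(i) for i in range(n)]
    return ClusterAssignment(condition=condition,
                             labels=dict(zip(ids, labels.tolist())),
                             linkage=Z)


@dataclass
class StabilityResult:
    scores: dict[int, float]          # k -> mean Fowlkes-Mallows over repeats
    selected_k: int
    threshold: float
    degenerate: bool = False          # all-identical input: splits are arbitrary


def bootstrap_stability(D: np.ndarray, k_range: range | list[int],
                        n_repeats: int = 100, subsample: float = 0.8,
                        seed: int = 0, threshold: float = 0.9) -> StabilityResult:
    """Model-order selection by subsampling concordance (Ben-Hur style).

    Per repeat, two independent ``subsample`` fractions of the items are
    clustered at each k; agreement is the Fowlkes-Mallows index of the two
    labelings restricted to the items both subsamples share.  The selected k
    is the largest one whose mean agreement exceeds ``threshold`` (falling
    back to the argmax when none does).
    """
    n = D.shape[0]
    m = int(round(subsample * n))
    ks = list(k_range)
    if any(k < 2 or k > m for k in ks):
        raise ValueError(f"k_range must lie within [2, {m}]")
    if np.allclose(D, 0.0):
        return StabilityResult(scores={k: float("nan") for k in ks},
                               selected_k=ks[0], threshold=threshold,
                               degenerate=True)
    rng = np.random.default_rng(seed)
    sums = {k: 0.0 for k in ks}
    for _ in range(n_repeats):
        a = np.sort(rng.choice(n, size=m, replace=False))
        b = np.sort(rng.choice(n, size=m, replace=False))
        common = np.intersect1d(a, b)
        if len(common) < 2:
            raise ValueError("subsample intersection too small")
        pos_a = {v: i for i, v in enumerate(a)}
        pos_b = {v: i for i, v in enumerate(b)}
        Za = ward_linkage(D[np.ix_(a, a)])
        Zb = ward_linkage(D[np.ix_(b, b)])
        for k in ks:
            la = fcluster(Za, t=k, criterion="maxclust")
            lb = fcluster(Zb, t=k, criterion="maxclust")
            ca = [la[pos_a[v]] for v in common]
            cb = [lb[pos_b[v]] for v in common]
            sums[k] += fowlkes_mallows_score(ca, cb)
    scores = {k: sums[k] / n_repeats for k in ks}
    passing = [k for k in ks if scores[k] > threshold]
    selected = max(passing) if passing else max(scores, key=lambda k: scores[k])
    return StabilityResult(scores=scores, selected_k=selected, threshold=threshold)


def medoid_profiles(D: np.ndarray, assignment: ClusterAssignment,
                    cgi_ids: list[str], n_medoids: int = 10
                    ) -> dict[int, list[str]]:
    """Per cluster, the members with smallest total within-cluster DTW distance.

    Clusters smaller than ``n_medoids`` return all members (still sorted).
    """
    index = {g: i for i, g in enumerate(cgi_ids)}
    out: dict[int, list[str]] = {}
    for cluster in sorted(set(assignment.labels.values())):
        members = assignment.members(cluster)
        idx = np.array([index[g] for g in members])
        row_sums = D[np.ix_(idx, idx)].sum(axis=1)
        order = np.argsort(row_sums, kind="stable")[:n_medoids]
        out[cluster] = [members[i] for i in order]
    return out


def derive_cancer_subclusters(normal: ClusterAssignment, cancer: ClusterAssignment
                              ) -> tuple[dict[str, str], pd.DataFrame]:
    """Split cancer cluster 3 into 3up/3down by the matched normal label.

    A cancer-specific hemi-methylated CGI+SS is "3up" when it sat in the
    hypo-methylated cluster 1 of the normal condition and "3down" when it
    came from the hyper-methylated cluster 2.  Also returns the normal x
    cancer contingency table of cluster labels.
    """
    if set(normal.labels) != set(cancer.labels):
        raise ValueError("normal and cancer assignments cover different CGI+SS")
    sublabels = {}
    for g, c_lab in cancer.labels.items():
        if c_lab == 3:
            n_lab = normal.labels[g]
            sublabels[g] = {1: "3up", 2: "3down"}.get(n_lab, "none")
        else:
            sublabels[g] = "none"
    cancer.sublabels = sublabels
    ids = sorted(normal.labels)
    table = pd.crosstab(
        pd.Series([normal.labels[g] for g in ids], name="normal"),
        pd.Series([cancer.labels[g] for g in ids], name="cancer"))
    return sublabels, table
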