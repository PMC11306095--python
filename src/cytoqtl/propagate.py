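"""Signal propagation across functionally related traits.

Validated genes are clustered by their LOD profiles across all assayed cell
types (k-means, k chosen by mean silhouette). A cluster is declared
associated with every cell type whose median LOD within the cluster reaches
at least a fixed fraction (default 40%) of the cluster's highest per-cell-
type median, and each member gene inherits those associations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


def cluster_genes(lod_matrix: pd.DataFrame, k_range=(2, 10), seed: int = 0,
                  n_init: int = 10, standardize: bool = False):
    """K-means over gene LOD profiles; k maximizes the mean silhouette.

    ``lod_matrix`` is genes x cell types. Returns (labels, chosen_k).
    Degenerate inputs (one gene, or all profiles identical) collapse to a
    single cluster with a warning.
    """
    X = lod_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n == 0:
        return pd.Series(dtype=int), 0
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    lo = max(2, int(k_range[0]))
    hi = min(int(k_range[1]), n - 1)
    if n < 3 or (X == X[0]).all():
        warnings.warn("degenerate LOD profiles: returning a single cluster")
        return pd.Series(np.zeros(n, dtype=int), index=lod_matrix.index), 1
    best = (-np.inf, None, None)
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        score = silhouette_score(X, km.labels_, metric="euclidean")
        if score > best[0]:
            best = (score, km.labels_, k)
    if best[1] is None:
        warnings.warn("silhouette undefined for every k: single cluster")
        return pd.Series(np.zeros(n, dtype=int), index=lod_matrix.index), 1
    return pd.Series(best[1], index=lod_matrix.index), best[2]


def propagate(labels: pd.Series, lod_matrix: pd.DataFrame,
              validated: pd.DataFrame,
              threshold_fraction: float = 0.4) -> dict:
    """Extend validated associations by the cluster-median rule.

    Per cluster, the median LOD is computed for every cell type; the cluster
    associates with cell type c iff median(c) >= threshold_fraction * max of
    the cluster's medians. Every member gene gains those associations. The
    final list is the union of validated and propagated pairs, origin-flagged.

    Returns a dict with cluster medians, cluster -> cell-type sets, and the
    final association DataFrame (gene, cell_type, origin).
    """
    cell_types = list(lod_matrix.columns)
    validated_pairs = {(r.gene, r.cell_type) for r in validated.itertuples()}
    cluster_medians: dict[int, pd.Series] = {}
    cluster_celltypes: dict[int, list[str]] = {}
    rows = [{"gene": g, "cell_type": ct, "origin": "validated"}
            for g, ct in sorted(validated_pairs)]

    for lab in sorted(labels.unique()):
        members = labels.index[labels == lab]
        med = lod_matrix.loc[members].median(axis=0)
        cluster_medians[int(lab)] = med
        top = med.max()
        if top <= 0:
            cluster_celltypes[int(lab)] = []
            continue
        hit = [ct for ct in cell_types if med[ct] >= threshold_fraction * top]
        cluster_celltypes[int(lab)] = hit
        for g in members:
            for ct in hit:
                if (g, ct) not in validated_pairs:
                    rows.append({"gene": g, "cell_type": ct, "origin": "propagated"})

    final = pd.DataFrame(rows, columns=["gene", "cell_type", "origin"])
    final = final.sort_values(["gene", "cell_type"]).reset_index(drop=True)
    return {"cluster_medians": cluster_medians,
            "cluster_celltypes": cluster_celltypes,
            "associations": final}
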