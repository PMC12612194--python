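"""Cell-level quality control, normalisation and cluster annotation.

QC keeps cells with strictly more than ``min_genes`` expressed genes,
strictly more than ``min_total`` total counts and strictly less than
``max_mito_frac`` of counts in mitochondrial genes (defaults 300 / 1000 /
0.15). The mitochondrial fraction is computed on raw counts before any
normalisation. Normalisation scales each cell to a common total (10,000 by
default) followed by log(1 + x); raw counts are preserved in
``layers['counts']``. No batch correction is applied.

Clustering is a pluggable backend ("kmeans" or "leiden") followed by
marker-based annotation: each cluster receives the label whose marker set
has the highest mean normalised expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

__all__ = ["QCThresholds", "QCReport", "qc_filter", "normalize_log",
           "cluster_and_annotate"]


@dataclass(frozen=True)
class QCThresholds:
    """Strict (exclusive) QC cutoffs; a cell at exactly a threshold fails."""

    min_genes: int = 300
    min_total: int = 1000
    max_mito_frac: float = 0.15

    def __post_init__(self):
        if self.min_genes <= 0 or self.min_total <= 0 or self.max_mito_frac <= 0:
            raise ValueError("QC thresholds must be strictly positive")
        if self.max_mito_frac > 1:
            raise ValueError("max_mito_frac must be <= 1")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    rejected_low_genes: int
    rejected_low_total: int
    rejected_high_mito: int

    def to_dict(self) -> dict:
        return asdict(self)


def _counts_matrix(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sparse.csr_matrix(X)


def qc_filter(adata: ad.AnnData, thr: QCThresholds = QCThresholds()
              ) -> tuple[ad.AnnData, QCReport]:
    """Filter cells by the three strict QC rules.

    Rejection counts are attributed with precedence low-genes -> low-total
    -> high-mito (a cell failing several rules is counted once, under the
    first), so retained + rejected always sums to the input cell count.
    If no gene is flagged mitochondrial a warning is emitted and the mito
    rule passes vacuously.
    """
    X = _counts_matrix(adata)
    if (X.data < 0).any() or not np.allclose(X.data, np.round(X.data)):
        raise ValueError("qc_filter expects non-negative integer counts")

    genes_expressed = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy() if "mito" in adata.var else np.zeros(adata.n_vars, bool)
    if not mito_mask.any():
        warnings.warn("no mito-flagged genes present; mito rule passes vacuously")
        mito_frac = np.zeros(adata.n_obs)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() / np.where(total > 0, total, 1)

    pass_genes = genes_expressed > thr.min_genes
    pass_total = total > thr.min_total
    pass_mito = mito_frac < thr.max_mito_frac
    keep = pass_genes & pass_total & pass_mito

    rej_genes = int((~pass_genes).sum())
    rej_total = int((pass_genes & ~pass_total).sum())
    rej_mito = int((pass_genes & pass_total & ~pass_mito).sum())
    report = QCReport(adata.n_obs, int(keep.sum()), rej_genes, rej_total, rej_mito)
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` counts and apply log1p (natural log).

    Stores the result in ``layers['lognorm']`` and preserves raw counts in
    ``layers['counts']``. Cells with zero total counts are an error — they
    cannot occur after QC.
    """
    X = _counts_matrix(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-count cell encountered; run qc_filter first")
    adata = adata.copy()
    adata.layers["counts"] = X.copy()
    scaled = sparse.diags(target_sum / total) @ X
    scaled = scaled.tocsr()
    scaled.data = np.log1p(scaled.data)
    adata.layers["lognorm"] = scaled
    adata.X = scaled.copy()
    return adata


def _cluster_kmeans(Z: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(Z)


def _cluster_leiden(adata: ad.AnnData, seed: int) -> np.ndarray:
    import scanpy as sc

    tmp = adata.copy()
    sc.pp.pca(tmp, n_comps=min(30, tmp.n_vars - 1, tmp.n_obs - 1), random_state=seed)
    sc.pp.neighbors(tmp, random_state=seed)
    sc.tl.leiden(tmp, random_state=seed, key_added="leiden", flavor="igraph",
                 n_iterations=2, directed=False)
    return tmp.obs["leiden"].astype(int).to_numpy()


def cluster_and_annotate(adata: ad.AnnData, markers: dict[str, list[str]],
                         backend: str = "kmeans", n_clusters: int | None = None,
                         seed: int = 0) -> ad.AnnData:
    """Cluster cells and annotate each cluster by its best-matching marker set.

    ``markers`` maps an annotation label (e.g. ``blast``, ``T``, ``NK``) to
    marker gene ids; per cluster the label whose markers have the highest
    mean normalised expression wins. The clustering backend is pluggable
    (``kmeans`` on PCA scores, or graph-community ``leiden``) because the
    downstream statistics only require cluster labels, not a particular
    algorithm. Cluster assignment and annotation are invariant to cell
    order up to cluster relabelling.
    """
    if not markers:
        raise ValueError("empty marker map")
    if "lognorm" not in adata.layers:
        raise ValueError("normalized layer missing; run normalize_log first")
    adata = adata.copy()
    Z = np.asarray(sparse.csr_matrix(adata.layers["lognorm"]).todense())

    if backend == "kmeans":
        from sklearn.decomposition import PCA

        k = n_clusters if n_clusters is not None else max(2, len(markers))
        ncomp = min(20, Z.shape[1] - 1, Z.shape[0] - 1)
        pcs = PCA(n_components=ncomp, random_state=seed).fit_transform(Z)
        labels = _cluster_kmeans(pcs, k, seed)
    elif backend == "leiden":
        labels = _cluster_leiden(adata, seed)
    else:
        raise ValueError(f"unknown clustering backend {backend!r}")

    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    marker_cols = {lab: [gene_index[g] for g in gs if g in gene_index]
                   for lab, gs in markers.items()}
    annotations = np.empty(adata.n_obs, dtype=object)
    for cl in np.unique(labels):
        mask = labels == cl
        best_lab, best_score = None, -np.inf
        for lab in sorted(marker_cols):
            cols = marker_cols[lab]
            score = float(Z[np.ix_(mask, cols)].mean()) if cols else -np.inf
            if score > best_score:
                best_lab, best_score = lab, score
        annotations[mask] = best_lab
    adata.obs["cluster"] = pd.Categorical([str(c) for c in labels])
    adata.obs["annotation"] = annotations
    return adata
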