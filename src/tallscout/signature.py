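"""Derivation and scoring of the ZBTB16+ blast gene module.

The module is the intersection of two pseudo-bulk DE analyses — genes that
increase linearly across the ordered sample groups (day-0 responsive,
day-0 failure, day-28 failure) and genes upregulated in ZBTB16+ versus
ZBTB16- blasts — followed by three filters:

1. specificity: expressed (raw count >= 1) in fewer than 3% of day-0 blasts
   in at least six responsive patients;
2. sensitivity: expressed in more than 2% of ZBTB16+ blasts in at least
   four induction-failure patients;
3. leave-one-out contribution: re-score cells with each gene excluded and
   retain genes whose exclusion reduces the ZBTB16+ vs ZBTB16- effect size
   (standardised mean difference of scores) by more than ``tau``
   (default 0: any reduction in separation means the gene contributes).

Single-cell scoring is the Scanpy module score (mean expression of module
genes minus the mean of expression-matched control genes drawn from
``n_bins`` average-expression bins, ``ctrl_per_gene`` controls per bin,
seeded). Bulk scoring is a singscore-style normalised mean rank: per
sample, all genes are ranked ascending with mid-rank ties and the mean
module-gene rank is mapped linearly onto [-0.5, 0.5] (+0.5 when the module
occupies the top ranks, -0.5 the bottom). Being rank-based, the bulk score
is invariant to any monotone transform of a sample's expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats

from .census import call_positive

__all__ = ["GeneModule", "derive_module", "derive_module_pipeline",
           "score_cells", "score_bulk", "similarity_module_check"]

_FLAGS = ["trend_significant", "zbtb16_contrast_significant",
          "passed_filter1", "passed_filter2", "passed_filter3"]


@dataclass
class GeneModule:
    """Ordered gene list with per-gene provenance of the filters passed."""

    genes: list[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty gene module")

    def to_tsv(self, path: str | Path) -> None:
        prov = self.provenance.reindex(self.genes)
        bitmask = np.zeros(len(self.genes), dtype=int)
        for b, flag in enumerate(_FLAGS):
            if flag in prov:
                bitmask |= prov[flag].fillna(False).astype(int).to_numpy() << b
        pd.DataFrame({"gene": self.genes, "provenance": bitmask}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneModule":
        df = pd.read_csv(path, sep="\t")
        prov = pd.DataFrame({flag: (df["provenance"].to_numpy() >> b) & 1
                             for b, flag in enumerate(_FLAGS)},
                            index=df["gene"]).astype(bool)
        return cls(genes=list(df["gene"]), provenance=prov)


def _expressed_frac_by_patient(adata: ad.AnnData, cell_mask: np.ndarray,
                               genes: list[str]) -> pd.DataFrame:
    """Per (patient, gene) fraction of masked cells with raw count >= 1."""
    X = sparse.csr_matrix(adata.layers["counts"] if "counts" in adata.layers
                          else adata.X)
    cols = [adata.var_names.get_loc(g) for g in genes]
    rows = {}
    patients = adata.obs["patient"].to_numpy()
    for pat in np.unique(patients[cell_mask]):
        idx = np.flatnonzero(cell_mask & (patients == pat))
        sub = X[idx][:, cols]
        rows[pat] = np.asarray((sub > 0).sum(axis=0)).ravel() / idx.size
    return pd.DataFrame(rows, index=genes).T  # patient x gene


def _smd(scores: np.ndarray, pos_mask: np.ndarray) -> float:
    a, b = scores[pos_mask], scores[~pos_mask]
    sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                 / (a.size + b.size - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


def derive_module(trend_results: pd.DataFrame, contrast_results: pd.DataFrame,
                  adata: ad.AnnData, *, zbtb16_gene: str = "ZBTB16",
                  resp_max_frac: float = 0.03, resp_quota: int = 6,
                  fail_min_frac: float = 0.02, fail_quota: int = 4,
                  tau: float = 0.0, n_bins: int = 25, ctrl_per_gene: int = 50,
                  seed: int = 0, blast_label: str = "blast") -> GeneModule:
    """Run the intersection-plus-three-filters cascade on annotated cells.

    ``trend_results`` and ``contrast_results`` are DE tables (indexed by
    gene, with ``logFC`` and ``padj``) computed on the same gene universe;
    significance means positive logFC with adjusted p < 0.05. The result is
    ordered by contrast logFC, descending.
    """
    obs = adata.obs
    resp_patients = obs.loc[obs["outcome"] == "responsive", "patient"].unique()
    fail_patients = obs.loc[obs["outcome"] == "induction_failure", "patient"].unique()
    if len(resp_patients) < resp_quota:
        raise ValueError(f"filter 1 quota of {resp_quota} responsive patients "
                         f"not met (have {len(resp_patients)})")
    if len(fail_patients) < fail_quota:
        raise ValueError(f"filter 2 quota of {fail_quota} induction-failure "
                         f"patients not met (have {len(fail_patients)})")

    trend_sig = set(trend_results.index[(trend_results["logFC"] > 0)
                                        & (trend_results["padj"] < 0.05)])
    contrast_sig = set(contrast_results.index[(contrast_results["logFC"] > 0)
                                              & (contrast_results["padj"] < 0.05)])
    universe = sorted(trend_sig | contrast_sig)
    candidates = sorted(trend_sig & contrast_sig)
    prov = pd.DataFrame(False, index=pd.Index(universe, name="gene"), columns=_FLAGS)
    prov.loc[sorted(trend_sig), "trend_significant"] = True
    prov.loc[sorted(contrast_sig), "zbtb16_contrast_significant"] = True
    if not candidates:
        raise ValueError("empty module: no gene significant in both analyses")

    is_blast = (obs["annotation"] == blast_label).to_numpy()
    zpos = call_positive(adata, zbtb16_gene)

    # filter 1: lowly expressed in day-0 responsive blasts
    resp_mask = (is_blast & (obs["outcome"] == "responsive").to_numpy()
                 & (obs["timepoint"] == "d0").to_numpy())
    fr = _expressed_frac_by_patient(adata, resp_mask, candidates)
    pass1 = [g for g in candidates if int((fr[g] < resp_max_frac).sum()) >= resp_quota]
    prov.loc[pass1, "passed_filter1"] = True

    # filter 2: expressed in ZBTB16+ induction-failure blasts
    fail_mask = (is_blast & (obs["outcome"] == "induction_failure").to_numpy() & zpos)
    ff = _expressed_frac_by_patient(adata, fail_mask, pass1) if pass1 else pd.DataFrame()
    pass2 = [g for g in pass1 if int((ff[g] > fail_min_frac).sum()) >= fail_quota]
    prov.loc[pass2, "passed_filter2"] = True
    if not pass2:
        raise ValueError("empty module after specificity/sensitivity filters")

    # filter 3: leave-one-out score-effect
    blasts = adata[is_blast]
    pos_mask = zpos[is_blast]
    full = score_cells(blasts, pass2, n_bins=n_bins,
                       ctrl_per_gene=ctrl_per_gene, seed=seed).to_numpy()
    full_effect = _smd(full, pos_mask)
    pass3 = []
    for g in pass2:
        rest = [x for x in pass2 if x != g]
        if not rest:
            pass3.append(g)
            continue
        loo = score_cells(blasts, rest, n_bins=n_bins,
                          ctrl_per_gene=ctrl_per_gene, seed=seed).to_numpy()
        if full_effect - _smd(loo, pos_mask) > tau:
            pass3.append(g)
    prov.loc[pass3, "passed_filter3"] = True
    if not pass3:
        raise ValueError("empty module after leave-one-out filter")

    order = contrast_results.loc[pass3, "logFC"].sort_values(ascending=False)
    return GeneModule(genes=list(order.index), provenance=prov)


def derive_module_pipeline(adata: ad.AnnData, *, zbtb16_gene: str = "ZBTB16",
                           blast_label: str = "blast", seed: int = 0,
                           tau: float = 0.0,
                           min_libsize: float = 100_000.0,
                           contrast_min_libsize: float = 50_000.0
                           ) -> tuple[GeneModule, pd.DataFrame, pd.DataFrame]:
    """Full module derivation from an annotated, normalised cohort.

    Runs the two pseudo-bulk analyses — the ordered-group trend over
    (day-0 responsive, day-0 failure, day-28 failure) blasts aggregated per
    sample, and the contrast of ZBTB16+ failure versus ZBTB16- responsive
    blast pseudo-bulks — then the intersection-plus-filters cascade.
    Returns ``(module, trend_results, contrast_results)``.

    ZBTB16+/- pseudo-bulks are smaller libraries than whole samples, so the
    contrast aggregation uses its own (lower) library-size floor.
    """
    from .pseudobulk import aggregate, filter_genes, de_test, trend_test

    obs = adata.obs
    blasts = adata[(obs["annotation"] == blast_label).to_numpy()].copy()

    sample_info = blasts.obs.groupby("sample_id", observed=True)[
        ["timepoint", "outcome"]].first()

    def _group(sid: str) -> str:
        row = sample_info.loc[sid]
        if row["timepoint"] == "d28":
            return "d28_failure"
        return ("d0_failure" if row["outcome"] == "induction_failure"
                else "d0_responsive")

    pb = aggregate(blasts, by=("sample_id",), min_libsize=min_libsize)
    pb.meta["group"] = [_group(s) for s in pb.meta["sample_id"]]
    trend = trend_test(filter_genes(pb),
                       ["d0_responsive", "d0_failure", "d28_failure"])

    pos = call_positive(blasts, zbtb16_gene)
    blasts.obs["zbtb16_call"] = np.where(pos, "zbtb16_pos", "zbtb16_neg")
    pb2 = aggregate(blasts, by=("sample_id", "zbtb16_call"),
                    min_libsize=contrast_min_libsize)
    outcome = sample_info["outcome"]

    def _zgroup(sid: str, zcall: str) -> str:
        if zcall == "zbtb16_pos" and outcome[sid] == "induction_failure":
            return "zbtb16_pos"
        if zcall == "zbtb16_neg" and outcome[sid] == "responsive":
            return "zbtb16_neg"
        return "other"

    pb2.meta["group"] = [_zgroup(s, z) for s, z in
                         zip(pb2.meta["sample_id"], pb2.meta["zbtb16_call"])]
    contrast = de_test(filter_genes(pb2), ("zbtb16_pos", "zbtb16_neg"))

    module = derive_module(trend, contrast, adata, zbtb16_gene=zbtb16_gene,
                           tau=tau, seed=seed, blast_label=blast_label)
    return module, trend, contrast


def score_cells(adata: ad.AnnData, genes: list[str] | GeneModule,
                n_bins: int = 25, ctrl_per_gene: int = 50,
                seed: int = 0) -> pd.Series:
    """Scanpy module score on the normalised layer (seeded control draw)."""
    import scanpy as sc

    genes = genes.genes if isinstance(genes, GeneModule) else list(genes)
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError("no module gene present in the matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} module gene(s) absent; dropped")
    tmp = ad.AnnData(X=sparse.csr_matrix(adata.layers["lognorm"]
                                         if "lognorm" in adata.layers else adata.X),
                     obs=adata.obs[[]].copy(),
                     var=pd.DataFrame(index=adata.var_names.copy()))
    sc.tl.score_genes(tmp, present, score_name="score", ctrl_size=ctrl_per_gene,
                      n_bins=n_bins, random_state=seed)
    return pd.Series(tmp.obs["score"].to_numpy(), index=adata.obs_names,
                     name="score")


def score_bulk(logcpm: pd.DataFrame, genes: list[str] | GeneModule) -> pd.Series:
    """singscore-style normalised mean-rank score per sample, in [-0.5, 0.5].

    ``logcpm`` is gene x sample. Module genes absent from the matrix are
    dropped with a warning; an empty effective module is an error.
    """
    genes = genes.genes if isinstance(genes, GeneModule) else list(genes)
    present = [g for g in genes if g in logcpm.index]
    if not present:
        raise ValueError("no module gene present in the expression matrix")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} module gene(s) absent; dropped")
    n = logcpm.shape[0]
    m = len(present)
    ranks = stats.rankdata(logcpm.to_numpy(), axis=0)  # mid-rank ties, ascending
    pos = [logcpm.index.get_loc(g) for g in present]
    mean_rank = ranks[pos, :].mean(axis=0)
    r_min = (m + 1) / 2.0
    r_max = (2 * n - m + 1) / 2.0
    score = (mean_rank - r_min) / (r_max - r_min) - 0.5
    return pd.Series(score, index=logcpm.columns, name="score")


def similarity_module_check(scores: pd.Series, zbtb16_logcpm: pd.Series,
                            labels: pd.Series) -> dict:
    """One-sided rank-sum p and AUC for module score and single-gene
    expression against a binary label (1 = expected-higher group)."""
    y = labels.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    out = {}
    for name, values in (("score", scores), ("zbtb16", zbtb16_logcpm)):
        v = values.loc[labels.index].to_numpy(float)
        a, b = v[y == 1], v[y == 0]
        u, p = stats.mannwhitneyu(a, b, alternative="greater")
        out[f"auc_{name}"] = float(u / (a.size * b.size))
        out[f"p_{name}"] = float(p)
    return out
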