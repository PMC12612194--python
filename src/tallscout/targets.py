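"""Candidate cell-surface antigen targets for blasts and ZBTB16+ blasts.

Starting from genes upregulated in blasts versus each patient's own normal
T cells (pseudo-bulk DE, adjusted p < 0.05), candidates must be annotated
cell-surface genes (GO:0009897 snapshot, overridable by file), expressed in
fewer than 10% of cells in at least 10 conventional reference T-cell types,
and pass the mode-specific fraction filters: for the pan-T-ALL list,
expressed in more than 15% of blasts; for the ZBTB16+ list, expressed in
fewer than 15% of day-0 responsive cells and more than 10% of ZBTB16+
cells. "Expressed in" means raw count >= 1 on the single-cell side and the
reference's own expressed-fraction field on the atlas side.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

from .census import call_positive

__all__ = ["find_targets", "load_surface_genes", "expressed_fraction"]


def load_surface_genes(path: str | Path | None = None) -> set[str]:
    """Gene symbols annotated to the external side of the plasma membrane.

    The default file is a synthetic stand-in snapshot: a hand-curated list
    of human genes genuinely annotated under GO:0009897 (curated 2025-09;
    no ontology service is queried). Pass ``path`` to use a real export.
    """
    if path is None:
        ref = resources.files("tallscout").joinpath(
            "data/surface_genes_go0009897_synthetic.txt")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return {line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}


def expressed_fraction(adata: ad.AnnData, cell_mask: np.ndarray,
                       genes: list[str]) -> pd.Series:
    """Fraction of masked cells with raw count >= 1, per gene."""
    X = sparse.csr_matrix(adata.layers["counts"] if "counts" in adata.layers
                          else adata.X)
    idx = np.flatnonzero(np.asarray(cell_mask, bool))
    if idx.size == 0:
        return pd.Series(np.nan, index=genes)
    cols = [adata.var_names.get_loc(g) for g in genes]
    frac = np.asarray((X[idx][:, cols] > 0).sum(axis=0)).ravel() / idx.size
    return pd.Series(frac, index=genes)


def find_targets(adata: ad.AnnData, de_results: pd.DataFrame,
                 reference: pd.DataFrame, surface_genes: set[str],
                 mode: str = "pan_TALL", *,
                 zbtb16_gene: str = "ZBTB16", blast_label: str = "blast",
                 max_frac_day0_responsive: float = 0.15,
                 min_frac_zbtb16_pos: float = 0.10,
                 min_frac_blasts: float = 0.15,
                 max_ref_frac: float = 0.10, min_conventional_types: int = 10
                 ) -> pd.DataFrame:
    """Apply the surface-target filter cascade; returns one row per candidate.

    ``de_results`` is a DE table (blasts vs own normal T cells) indexed by
    gene with ``logFC`` and ``padj``; ``reference`` needs columns
    ``cell_type``, ``class`` (``conventional_T`` among others), ``gene`` and
    ``expressed_fraction``. The output is independent of gene order.
    """
    if mode not in ("pan_TALL", "zbtb16_pos"):
        raise ValueError(f"unknown mode {mode!r}")
    conv = reference[reference["class"] == "conventional_T"]
    n_conv_types = conv["cell_type"].nunique()
    if n_conv_types < min_conventional_types:
        raise ValueError(f"reference has only {n_conv_types} conventional "
                         f"T-cell types; need >= {min_conventional_types}")

    upreg = de_results[(de_results["logFC"] > 0) & (de_results["padj"] < 0.05)]
    candidates = sorted(set(upreg.index) & surface_genes
                        & set(adata.var_names))
    if not candidates:
        return pd.DataFrame(columns=["gene", "list", "frac_blasts",
                                     "frac_zbtb16_pos", "frac_day0_responsive",
                                     "n_ref_types_low", "surface"])

    obs = adata.obs
    is_blast = (obs["annotation"] == blast_label).to_numpy()
    zpos = call_positive(adata, zbtb16_gene)
    day0_resp = ((obs["timepoint"] == "d0") & (obs["outcome"] == "responsive")).to_numpy()
    zpos_fail = is_blast & zpos & (obs["outcome"] == "induction_failure").to_numpy()

    frac_blasts = expressed_fraction(adata, is_blast, candidates)
    frac_zpos = expressed_fraction(adata, zpos_fail, candidates)
    frac_d0r = expressed_fraction(adata, day0_resp, candidates)

    # per gene: number of conventional reference types with low expression
    ref_low = (conv.assign(low=conv["expressed_fraction"] < max_ref_frac)
               .groupby("gene")["low"].sum())

    rows = []
    for g in candidates:
        n_low = int(ref_low.get(g, 0))
        if n_low < min_conventional_types:
            continue
        if mode == "pan_TALL":
            if not frac_blasts[g] > min_frac_blasts:
                continue
        else:
            if not (frac_d0r[g] < max_frac_day0_responsive
                    and frac_zpos[g] > min_frac_zbtb16_pos):
                continue
        rows.append({"gene": g, "list": mode,
                     "frac_blasts": float(frac_blasts[g]),
                     "frac_zbtb16_pos": float(frac_zpos[g]),
                     "frac_day0_responsive": float(frac_d0r[g]),
                     "n_ref_types_low": n_low, "surface": True})
    return pd.DataFrame(rows, columns=["gene", "list", "frac_blasts",
                                       "frac_zbtb16_pos", "frac_day0_responsive",
                                       "n_ref_types_low", "surface"])
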