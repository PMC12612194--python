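"""Reference-similarity mapping by regularised multinomial logistic regression.

A multinomial elastic-net model (mixing parameter alpha = 0.99, i.e. nearly
pure lasso for strong regularisation) is trained on log-normalised
single-cell transcriptomes of ZBTB16+ blasts, ZBTB16- blasts and a control
class; the penalty strength is chosen by seeded stratified
cross-validation minimising the multinomial deviance. Query cell types are
then scored by their mean predicted class probabilities, giving a
per-type similarity matrix whose rows sum to 1. The same machinery serves
the validation-cohort comparison by retargeting the training classes.

Features are all shared genes, unscaled log-normalised values; class
weights are uniform by default with an inverse-frequency option.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse

__all__ = ["SimilarityModel", "fit", "score_query"]


@dataclass
class SimilarityModel:
    classes: list[str]
    genes: list[str]
    coef: np.ndarray          # n_classes x n_genes
    intercept: np.ndarray     # n_classes
    alpha: float
    C: float
    seed: int

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        logits = Z @ self.coef.T + self.intercept[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def save(self, prefix: str | Path) -> None:
        """Persist as TSV of nonzero coefficients + JSON header."""
        prefix = Path(prefix)
        nz = np.abs(self.coef).sum(axis=0) > 0
        pd.DataFrame(self.coef[:, nz].T, index=np.asarray(self.genes)[nz],
                     columns=self.classes).to_csv(
            prefix.with_suffix(".coef.tsv"), sep="\t")
        header = {"classes": self.classes, "alpha": self.alpha, "C": self.C,
                  "seed": self.seed,
                  "intercept": self.intercept.tolist()}
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))


def _dense_lognorm(adata: ad.AnnData) -> np.ndarray:
    layer = adata.layers["lognorm"] if "lognorm" in adata.layers else adata.X
    return np.asarray(sparse.csr_matrix(layer).todense())


def fit(adata: ad.AnnData, label_col: str = "class", alpha: float = 0.99,
        k_folds: int = 10, seed: int = 0,
        Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
        class_weight: str | None = None, tol: float = 1e-3,
        max_iter: int = 2000) -> SimilarityModel:
    """Fit the elastic-net multinomial model with cross-validated penalty.

    Every class must have at least ``k_folds`` cells. ``class_weight`` may
    be ``"balanced"`` for inverse-frequency weighting (default uniform).
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    y = adata.obs[label_col].astype(str).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    small = classes[counts < k_folds]
    if small.size:
        raise ValueError(f"class(es) {list(small)} have fewer than "
                         f"k_folds={k_folds} cells")
    Z = _dense_lognorm(adata)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=list(Cs), cv=cv, penalty="elasticnet", solver="saga",
        l1_ratios=[alpha], scoring="neg_log_loss", tol=tol,
        max_iter=max_iter, class_weight=class_weight, random_state=seed,
        n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    return SimilarityModel(classes=[str(c) for c in model.classes_],
                           genes=list(adata.var_names),
                           coef=np.asarray(model.coef_, float),
                           intercept=np.asarray(model.intercept_, float),
                           alpha=alpha, C=float(np.ravel(model.C_)[0]),
                           seed=seed)


def score_query(model: SimilarityModel, query: ad.AnnData,
                type_col: str = "query_type") -> pd.DataFrame:
    """Mean predicted class probability per query type (rows sum to 1).

    Query genes are aligned to the training genes; genes missing from the
    query are imputed as zero with a warning. Empty query types are simply
    absent from the grouping.
    """
    Zq = _dense_lognorm(query)
    qgenes = list(query.var_names)
    if qgenes != model.genes:
        aligned = np.zeros((query.n_obs, len(model.genes)))
        lookup = {g: i for i, g in enumerate(qgenes)}
        missing = 0
        for j, g in enumerate(model.genes):
            if g in lookup:
                aligned[:, j] = Zq[:, lookup[g]]
            else:
                missing += 1
        if missing:
            warnings.warn(f"{missing} training gene(s) missing from query; "
                          "imputed as zero")
        Zq = aligned
    proba = model.predict_proba(Zq)
    df = pd.DataFrame(proba, columns=model.classes, index=query.obs_names)
    df[type_col] = query.obs[type_col].to_numpy()
    out = df.groupby(type_col, observed=True).mean()
    return out.div(out.sum(axis=1), axis=0)
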