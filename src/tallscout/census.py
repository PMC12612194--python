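"""ZBTB16 positivity calls, per-sample blast census and proportion testing.

Positivity is detection-based: a cell is ZBTB16+ iff its raw count for the
gene is at least 1 (the assumption-free reading of "fraction of blasts
expressing ZBTB16"). The census reports, per (sample, blast cluster), the
number of blasts, the number positive, the median normalised expression and
the positive fraction — raw-count based fractions are invariant to any
normalisation choice.

Group differences in per-sample ZBTB16+ blast proportions are tested with a
propeller-style moderated t on logit-transformed proportions: each sample's
proportion is transformed as logit((x + 0.5) / (n + 1)) (the offset handles
0% and 100% samples), and the two-sample t statistic uses an
empirical-Bayes posterior variance in which the prior degrees of freedom
and prior variance are moment-matched on the distribution of log sample
variances across cell states (the limma fit). With a single cell state
there is no across-unit variance distribution and the test reduces to the
ordinary pooled-variance t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, special, stats

from .pseudobulk import bh_adjust

__all__ = ["call_positive", "census", "proportion_test", "logit_proportion",
           "ProportionTestResult"]


def _raw_counts(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sparse.csr_matrix(X)


def call_positive(adata: ad.AnnData, gene: str = "ZBTB16") -> np.ndarray:
    """Per-cell boolean: raw count >= 1 for ``gene``."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent from the count matrix")
    j = adata.var_names.get_loc(gene)
    col = np.asarray(_raw_counts(adata)[:, j].todense()).ravel()
    return col >= 1


def census(adata: ad.AnnData, gene: str = "ZBTB16",
           blast_label: str = "blast") -> pd.DataFrame:
    """One row per (sample, blast cluster): counts, positives, median, fraction.

    Median expression is computed on the normalised layer when present,
    otherwise on raw counts. Samples with zero blasts are omitted with a
    warning.
    """
    if "cluster" not in adata.obs:
        adata = adata.copy()
        adata.obs["cluster"] = "0"
    pos = call_positive(adata, gene)
    j = adata.var_names.get_loc(gene)
    if "lognorm" in adata.layers:
        expr = np.asarray(sparse.csr_matrix(adata.layers["lognorm"])[:, j].todense()).ravel()
    else:
        expr = np.asarray(_raw_counts(adata)[:, j].todense()).ravel().astype(float)

    is_blast = (adata.obs["annotation"] == blast_label).to_numpy()
    rows = []
    for sample_id, idx in adata.obs.groupby("sample_id", observed=True).indices.items():
        idx = np.asarray(idx)
        bidx = idx[is_blast[idx]]
        if bidx.size == 0:
            warnings.warn(f"sample {sample_id} has zero blasts; omitted from census")
            continue
        for cl in sorted(set(adata.obs["cluster"].iloc[bidx])):
            cidx = bidx[(adata.obs["cluster"].iloc[bidx] == cl).to_numpy()]
            n = int(cidx.size)
            npos = int(pos[cidx].sum())
            rows.append((sample_id, str(cl), n, npos,
                         float(np.median(expr[cidx])), npos / n))
    return pd.DataFrame(rows, columns=["sample_id", "cluster", "n_blasts",
                                       "n_zbtb16_pos", "median_zbtb16",
                                       "fraction_pos"])


def logit_proportion(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """propeller-compatible transform: logit((x + 0.5) / (n + 1))."""
    p = (np.asarray(x, float) + 0.5) / (np.asarray(n, float) + 1.0)
    return np.log(p / (1.0 - p))


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (limma's trigammaInverse)
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s^2 ~ s0^2 F(df, d0) on log variances -> (d0, s0^2)."""
    s2 = np.maximum(np.asarray(variances, float), 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


@dataclass
class ProportionTestResult:
    state: str
    groups: tuple[str, str]
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    padj: float


def proportion_test(counts: pd.DataFrame, group_a: set[str], group_b: set[str],
                    prior_df: float | None = None,
                    group_names: tuple[str, str] = ("A", "B")
                    ) -> list[ProportionTestResult]:
    """Moderated t on logit-transformed per-sample proportions, per cell state.

    ``counts`` needs columns ``state``, ``sample_id``, ``x`` (cells of the
    state, e.g. ZBTB16+ blasts) and ``n`` (total cells, e.g. blasts).
    ``prior_df`` overrides the estimated empirical-Bayes prior degrees of
    freedom; 0 gives the ordinary pooled-variance two-sample t.

    Swapping the two groups flips the sign of t and leaves p unchanged.
    """
    for col in ("state", "sample_id", "x", "n"):
        if col not in counts.columns:
            raise ValueError(f"counts is missing column {col!r}")
    states = sorted(counts["state"].unique())
    per_state = {}
    for state in states:
        sub = counts[counts["state"] == state]
        ya = logit_proportion(sub[sub["sample_id"].isin(group_a)]["x"].to_numpy(),
                              sub[sub["sample_id"].isin(group_a)]["n"].to_numpy())
        yb = logit_proportion(sub[sub["sample_id"].isin(group_b)]["x"].to_numpy(),
                              sub[sub["sample_id"].isin(group_b)]["n"].to_numpy())
        if ya.size < 2 or yb.size < 2:
            raise ValueError(f"state {state!r}: each group needs >=2 samples "
                             "(variance undefined otherwise)")
        df_res = ya.size + yb.size - 2
        s2 = (((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()) / df_res
        per_state[state] = (ya, yb, s2, df_res)

    df_res = per_state[states[0]][3]
    s2_all = np.array([per_state[s][2] for s in states])
    if prior_df is None:
        if len(states) >= 2 and np.ptp(np.log(np.maximum(s2_all, 1e-12))) > 0:
            d0, s0_sq = _fit_f_dist(s2_all, df_res)
        else:
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(np.maximum(s2_all, 1e-12))))) if d0 > 0 else 0.0

    results = []
    for state in states:
        ya, yb, s2, dfr = per_state[state]
        if np.isinf(d0):
            s2_post, df_total = s0_sq, np.inf
        elif d0 > 0:
            s2_post = (d0 * s0_sq + dfr * s2) / (d0 + dfr)
            df_total = dfr + d0
        else:
            s2_post, df_total = s2, dfr
        se = np.sqrt(s2_post * (1.0 / ya.size + 1.0 / yb.size))
        delta = ya.mean() - yb.mean()
        if se == 0:
            t = 0.0 if delta == 0 else np.inf * np.sign(delta)
        else:
            t = delta / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            p = 2.0 * stats.t.sf(abs(t), df_total)
        results.append(ProportionTestResult(state, group_names,
                                            float(ya.mean()), float(yb.mean()),
                                            float(t), float(df_total),
                                            float(min(p, 1.0)), np.nan))
    padj = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results
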