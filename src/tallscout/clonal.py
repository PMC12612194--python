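"""Clonal projection: variant filtering, per-cell copy-number posteriors,
cancer cell fractions and clone assignment.

Substitutions pass quality filtering iff the median alignment score of
supporting reads (ASMD) is >= 140, no supporting read is clipped
(CLPM = 0), the site is not within 10 bp of an insertion/deletion, the
depth lies within configured bounds, and a one-sided binomial test rejects
the site-specific background error rate at BH-adjusted q < 0.05.

Per-cell copy-number states are called from phased major/minor allele
counts: P(state | counts) is proportional to
Binomial(major; total, BAF_state) under a uniform prior over the state
hypothesis set (expected BAF 0.5 diploid, 1 - epsilon for copy-neutral
LOH, 2/3 for a 2:1 gain); a state is called when its posterior reaches the
call threshold (default 0.95), otherwise the cell is "uncalled".

The cancer cell fraction of a variant is
``CCF = VAF * (purity * cn + (1 - purity) * 2) / (purity * m)`` with local
tumour copy number ``cn`` and ``m`` mutated copies, clipped to [0, 1.05].
Clone assignment thresholds per-sample presence (CCF >= 0.10 and >= 3 alt
reads by default), partitions variants into shared/precursor and private
sets, selects the phylogeny (linear, independent, shared precursor) that
the presence pattern satisfies, and labels single cells from their
clone-informative variant reads and copy-number calls; conflicting
evidence is flagged "ambiguous", never silently assigned.

Coordinates: variants are 1-based (VCF-style); segments are 0-based
half-open (BED-style).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pseudobulk import bh_adjust

__all__ = ["filter_substitutions", "cell_cn_posterior", "pseudobulk_baf",
           "compute_ccf", "choose_mutated_copies", "assign_clones", "CloneModel"]


# ---------------------------------------------------------------------------
# substitution filtering
# ---------------------------------------------------------------------------

def _alt_total_columns(variants: pd.DataFrame) -> tuple[list[str], list[str]]:
    if "alt_count" in variants.columns and "depth" in variants.columns:
        return ["alt_count"], ["depth"]
    alts = sorted(c for c in variants.columns if c.startswith("alt_"))
    totals = ["total_" + c[len("alt_"):] for c in alts]
    if not alts or any(t not in variants.columns for t in totals):
        raise ValueError("variants need alt_count/depth or alt_*/total_* columns")
    return alts, totals


def filter_substitutions(variants: pd.DataFrame,
                         error_rate: float | pd.Series = 1e-3,
                         asmd_min: float = 140.0,
                         depth_bounds: tuple[float, float] = (8, 1000),
                         q_threshold: float = 0.05) -> pd.DataFrame:
    """Apply the substitution quality filters; returns the table with a
    ``filter_reason`` column ("pass" for retained variants).

    Evidence for the background-noise test is pooled across samples: a
    one-sided binomial test of the total alt count against the site error
    rate, BH-adjusted across variants. Records with missing annotations
    are rejected with reason "unannotated".
    """
    v = variants.copy()
    alts, totals = _alt_total_columns(v)
    alt = v[alts].sum(axis=1).to_numpy(float)
    depth = v[totals].sum(axis=1).to_numpy(float)
    per_sample_depth = v[totals].to_numpy(float)

    reason = np.full(len(v), "pass", dtype=object)
    ann = v[["ASMD", "CLPM", "near_indel"]]
    unann = ann.isna().any(axis=1).to_numpy()
    reason[unann] = "unannotated"
    ok = ~unann
    reason[ok & (v["ASMD"].to_numpy(float) < asmd_min)] = "low_ASMD"
    ok = reason == "pass"
    reason[ok & (v["CLPM"].to_numpy(float) != 0)] = "clipped_reads"
    ok = reason == "pass"
    reason[ok & v["near_indel"].astype(bool).to_numpy()] = "near_indel"
    ok = reason == "pass"
    lo, hi = depth_bounds
    bad_depth = ((per_sample_depth < lo) | (per_sample_depth > hi)).any(axis=1)
    reason[ok & bad_depth] = "depth_out_of_bounds"
    ok = reason == "pass"

    err = (error_rate.reindex(v.index).to_numpy(float)
           if isinstance(error_rate, pd.Series)
           else np.full(len(v), float(error_rate)))
    # P(X >= alt) under Binomial(depth, err); alt = 0 gives p = 1
    p_noise = stats.binom.sf(alt - 1, np.maximum(depth, 1).astype(int), err)
    p_noise = np.where(alt <= 0, 1.0, p_noise)
    q = bh_adjust(p_noise)
    reason[ok & (q >= q_threshold)] = "background_noise"

    v["p_noise"] = p_noise
    v["q_noise"] = q
    v["filter_reason"] = reason
    return v


# ---------------------------------------------------------------------------
# copy-number posteriors and BAF
# ---------------------------------------------------------------------------

DEFAULT_STATE_BAF = {"diploid": 0.5, "cnloh": 0.99, "gain21": 2.0 / 3.0}


def cell_cn_posterior(table: pd.DataFrame,
                      states: dict[str, float] | None = None,
                      prior: dict[str, float] | None = None,
                      call_threshold: float = 0.95) -> pd.DataFrame:
    """Per (cell, segment) posterior over copy-number states and the call.

    ``states`` maps state name to expected major-allele frequency (the
    default encodes epsilon = 0.01 for cnloh). Adding reads consistent with
    a state never lowers its posterior; zero total reads give "uncalled".
    """
    states = states or DEFAULT_STATE_BAF
    names = sorted(states)
    bafs = np.array([states[s] for s in names])
    if prior is None:
        pri = np.full(len(names), 1.0 / len(names))
    else:
        pri = np.array([prior[s] for s in names], float)
        pri = pri / pri.sum()

    major = table["major_count"].to_numpy(float)
    minor = table["minor_count"].to_numpy(float)
    with np.errstate(divide="ignore"):
        loglik = (major[:, None] * np.log(bafs)[None, :]
                  + minor[:, None] * np.log1p(-bafs)[None, :])
    loglik = np.where(np.isfinite(loglik), loglik, -np.inf)
    logpost = loglik + np.log(pri)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)

    out = table[["cell_id", "segment_id"]].copy()
    for i, s in enumerate(names):
        out[f"post_{s}"] = post[:, i]
    best = post.argmax(axis=1)
    call = np.array([names[i] for i in best], dtype=object)
    called = post[np.arange(len(best)), best] >= call_threshold
    zero = (major + minor) == 0
    out["call"] = np.where(called & ~zero, call, "uncalled")
    return out


def pseudobulk_baf(table: pd.DataFrame, cells: set[str] | None = None
                   ) -> pd.DataFrame:
    """Aggregate allele counts over a cell group; per-segment pooled BAF
    (and per-SNP when a ``snp_id`` column is present)."""
    sub = table if cells is None else table[table["cell_id"].isin(cells)]
    if sub.empty:
        raise ValueError("empty cell group")
    keys = ["segment_id"] + (["snp_id"] if "snp_id" in sub.columns else [])
    agg = sub.groupby(keys, as_index=False)[["major_count", "minor_count"]].sum()
    agg["baf"] = agg["major_count"] / (agg["major_count"] + agg["minor_count"])
    return agg


# ---------------------------------------------------------------------------
# cancer cell fractions
# ---------------------------------------------------------------------------

def compute_ccf(vaf: float, tumour_cn: int = 2, mutated_copies: int = 1,
                purity: float = 1.0) -> float:
    """CCF from VAF, local copy number and sample purity; linear in VAF."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if mutated_copies < 1:
        raise ValueError("mutated_copies must be >= 1")
    ccf = vaf * (purity * tumour_cn + (1.0 - purity) * 2.0) / (purity * mutated_copies)
    return float(np.clip(ccf, 0.0, 1.05))


def choose_mutated_copies(vaf: float, depth: int, tumour_cn: int,
                          purity: float) -> int:
    """Pick m in {1, ..., cn - 1} maximising the binomial likelihood of the
    observed VAF (m = 1 for diploid segments)."""
    if tumour_cn <= 2:
        return 1
    alt = int(round(vaf * depth))
    best_m, best_ll = 1, -np.inf
    for m in range(1, tumour_cn):
        exp_vaf = purity * m / (purity * tumour_cn + (1 - purity) * 2.0)
        ll = stats.binom.logpmf(alt, depth, min(exp_vaf, 1.0))
        if ll > best_ll:
            best_m, best_ll = m, ll
    return best_m


# ---------------------------------------------------------------------------
# clone assignment
# ---------------------------------------------------------------------------

@dataclass
class CloneModel:
    topology: str
    samples: list[str]
    variant_clones: pd.Series            # variant_id -> precursor/A/B/undetected
    clone_ccf: pd.DataFrame              # clone x sample mean CCF
    cell_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    tcr_consistency: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "topology": self.topology,
            "samples": self.samples,
            "clones": {c: sorted(self.variant_clones.index[self.variant_clones == c])
                       for c in ("precursor", "A", "B")},
            "clone_ccf": {c: self.clone_ccf.loc[c].to_dict()
                          for c in self.clone_ccf.index},
            "tcr_consistency": self.tcr_consistency,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def assign_clones(ccf: pd.DataFrame, alt_counts: pd.DataFrame,
                  cell_hits: pd.DataFrame | None = None,
                  cn_calls: pd.DataFrame | None = None,
                  segment_clone_map: dict[tuple[str, str], str] | None = None,
                  tcr_labels: pd.Series | None = None,
                  min_ccf: float = 0.10, min_alt_reads: int = 3) -> CloneModel:
    """Partition variants into precursor / sample-private clones and select
    the phylogeny the presence pattern satisfies.

    ``ccf`` and ``alt_counts`` are variant x sample (exactly two samples;
    clone A is private to the first, clone B to the second). A variant is
    present in a sample iff its CCF >= ``min_ccf`` and its alt reads >=
    ``min_alt_reads``. Optional per-cell evidence (``cell_hits`` long table
    cell_id/variant_id/alt_count, ``cn_calls`` cell_id/segment_id/call with
    ``segment_clone_map``) yields per-cell clone labels; cells carrying
    private evidence of both clones are "ambiguous".
    """
    if ccf.shape[1] < 2:
        raise ValueError("need >= 2 samples to relate clones")
    s1, s2 = list(ccf.columns[:2])
    present = (ccf >= min_ccf) & (alt_counts.loc[ccf.index, ccf.columns] >= min_alt_reads)
    in1, in2 = present[s1].to_numpy(bool), present[s2].to_numpy(bool)
    clone = np.where(in1 & in2, "precursor",
                     np.where(in1, "A", np.where(in2, "B", "undetected")))
    variant_clones = pd.Series(clone, index=ccf.index, name="clone")

    n_pre = int((clone == "precursor").sum())
    n_a = int((clone == "A").sum())
    n_b = int((clone == "B").sum())
    if n_a and n_b:
        topology = "shared_precursor" if n_pre else "independent"
    elif n_pre and (n_a or n_b):
        topology = "linear"
    elif n_pre:
        topology = "linear_or_undistinguished"
    else:
        topology = "single_clone" if (n_a or n_b) else "no_clones"

    rows = {}
    for c in ("precursor", "A", "B"):
        members = variant_clones.index[variant_clones == c]
        rows[c] = (ccf.loc[members, [s1, s2]].mean(axis=0)
                   if len(members) else pd.Series({s1: 0.0, s2: 0.0}))
    clone_ccf = pd.DataFrame(rows).T

    cell_labels = pd.Series(dtype=object)
    if cell_hits is not None or cn_calls is not None:
        votes: dict[str, set[str]] = {}

        def _vote(cell, c):
            votes.setdefault(cell, set()).add(c)

        if cell_hits is not None:
            vc = variant_clones.to_dict()
            for _, row in cell_hits.iterrows():
                c = vc.get(row["variant_id"], "undetected")
                if c in ("precursor", "A", "B") and row["alt_count"] >= 1:
                    _vote(row["cell_id"], c)
        if cn_calls is not None and segment_clone_map:
            for _, row in cn_calls.iterrows():
                c = segment_clone_map.get((row["segment_id"], row["call"]))
                if c:
                    _vote(row["cell_id"], c)
        labels = {}
        for cell, vs in votes.items():
            desc = vs & {"A", "B"}
            if len(desc) == 2:
                labels[cell] = "ambiguous"
            elif len(desc) == 1:
                labels[cell] = desc.pop()
            else:
                labels[cell] = "precursor"
        cell_labels = pd.Series(labels, name="clone", dtype=object)

    tcr_consistency = None
    if tcr_labels is not None and not cell_labels.empty:
        both = cell_labels[cell_labels.isin(["A", "B"])].to_frame("clone").join(
            tcr_labels.rename("tcr"), how="inner").dropna()
        if not both.empty:
            # majority mapping tcr label -> clone, then agreement fraction
            mapping = (both.groupby("tcr")["clone"]
                       .agg(lambda s: s.value_counts().idxmax()))
            tcr_consistency = float((both["clone"]
                                     == both["tcr"].map(mapping)).mean())
    return CloneModel(topology=topology, samples=[s1, s2],
                      variant_clones=variant_clones, clone_ccf=clone_ccf,
                      cell_labels=cell_labels, tcr_consistency=tcr_consistency)
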