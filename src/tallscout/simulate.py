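"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generators emulate the study design of a refractory childhood T-ALL
cohort profiled by single-cell mRNA sequencing: multi-patient blast/normal
mixtures carrying a planted ZBTB16+ ("non-canonical") subpopulation whose
frequency depends on induction outcome and timepoint, bulk cohorts whose
module signal rises across minimal-residual-disease (MRD) categories and
whose survival hazard depends on the true score tertile, per-cell allele
counts under diploid / copy-neutral-LOH / gain copy-number states, and a
two-clone (shared-precursor) variant structure.

Counts are negative-binomial (gamma-Poisson) with gene-level means scaled by
per-cell size factors and a shared dispersion; mitochondrial genes are the
first ``n_mito_genes`` identifiers, flagged ``MT-``, so the QC filter can be
exercised without a genome annotation. Each generator draws from its own
RNG stream derived from the root seed, so adding a generator does not
perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.io import mmwrite

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_sc_cohort",
    "simulate_bulk_cohort",
    "simulate_allele_counts",
    "simulate_clonal_structure",
    "write_sc_cohort",
    "write_bulk_cohort",
    "MRD_CATEGORIES",
    "CN_STATE_BAF",
]

#: Ordered day-28 MRD categories (lowest residual disease first).
MRD_CATEGORIES = ("<0.01%", "0.01-0.1%", "0.1-1%", "1-5%", ">=5%")

#: Expected major-allele frequency per copy-number state (epsilon applied at
#: draw time for cnloh).
CN_STATE_BAF = {"diploid": 0.5, "cnloh": 1.0, "gain21": 2.0 / 3.0}


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults mirror the discovery-cohort structure: 8 responsive and 13
    induction-failure children, day-28 samples for 8 of the failures, a
    ZBTB16+ blast fraction that is rare at diagnosis of responsive disease
    (0.67%), common at diagnosis of refractory disease, and dominant
    (97.6%) in refractory day-28 blasts. Cell and gene counts are scaled
    down from the real cohort so simulations stay tractable.
    """

    n_patients_responsive: int = 8
    n_patients_failure: int = 13
    n_failure_day28: int = 8
    cells_per_sample: int = 300
    n_genes: int = 1500
    n_mito_genes: int = 10
    module_size: int = 30
    n_marker_genes: int = 10
    zbtb16_frac_responsive: float = 0.0067
    zbtb16_frac_failure_day0: float = 0.30
    zbtb16_frac_failure_day28: float = 0.976
    frac_normal_cells: float = 0.26
    module_log2_fc: float = 6.0
    zbtb16_base_rate: float = 0.007
    zbtb16_pos_rate: float = 11.0
    nb_dispersion: float = 0.5
    libsize_lognormal_params: tuple[float, float] = (8.5, 0.35)
    mito_beta_params: tuple[float, float] = (2.5, 47.5)
    qc_violator_frac: tuple[float, float, float] = (0.02, 0.02, 0.02)
    bulk_n_samples: int = 1175
    bulk_libsize: float = 5e5
    bulk_nb_dispersion: float = 0.1
    survival_hazard_ratio_per_tertile: float = 2.0
    baseline_hazard: float = 0.08
    censoring_hazard: float = 0.04
    followup_years: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        props = {
            "zbtb16_frac_responsive": self.zbtb16_frac_responsive,
            "zbtb16_frac_failure_day0": self.zbtb16_frac_failure_day0,
            "zbtb16_frac_failure_day28": self.zbtb16_frac_failure_day28,
            "frac_normal_cells": self.frac_normal_cells,
        }
        for name, value in props.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name}={value} not in [0, 1]")
        for f in self.qc_violator_frac:
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("qc_violator_frac entries must be in [0, 1]")
        if self.module_size >= self.n_genes:
            raise ConfigurationError("module_size must be < n_genes")
        if self.nb_dispersion <= 0 or self.bulk_nb_dispersion <= 0:
            raise ConfigurationError("NB dispersions must be positive")
        if self.survival_hazard_ratio_per_tertile <= 0:
            raise ConfigurationError("hazard ratio must be positive")
        if self.n_failure_day28 > self.n_patients_failure:
            raise ConfigurationError("n_failure_day28 exceeds n_patients_failure")

    def rng(self, stream: str) -> np.random.Generator:
        """One independent RNG stream per generator, derived from the root seed.

        Stream names are mapped through CRC32 (stable across processes,
        unlike the builtin string hash) so every generator gets its own
        reproducible stream.
        """
        import zlib

        ss = np.random.SeedSequence([int(self.seed), zlib.crc32(stream.encode())])
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Latent labels used by oracle tests, never by the pipeline itself."""

    cell_truth: pd.DataFrame  # index cell_id: latent_state, clone_id
    module_genes: list[str] = field(default_factory=list)
    blast_marker_genes: list[str] = field(default_factory=list)
    normal_marker_genes: list[str] = field(default_factory=list)
    sample_truth: pd.DataFrame | None = None  # per sample: true fractions etc.


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam)


def _gene_profiles(cfg: SimConfig, rng: np.random.Generator):
    """Baseline / ZBTB16+ / normal-cell expression profiles (proportions).

    Module genes (ZBTB16 first) are lowly expressed at baseline so that
    fewer than ~3% of canonical blasts detect them, and elevated by
    ``module_log2_fc`` in ZBTB16+ cells, emulating the near on/off
    behaviour of the non-canonical state. Marker genes give clustering
    something to separate blasts from normal cells on.
    """
    n = cfg.n_genes
    k = cfg.n_mito_genes
    genes = [f"MT-{i + 1}" for i in range(k)]
    genes += ["ZBTB16"] + [f"G{i:04d}" for i in range(1, n - k)]

    base = rng.lognormal(0.0, 1.2, size=n)
    base[:k] = 0.0  # mito handled by the per-cell mito fraction

    module_idx = np.arange(k, k + cfg.module_size)  # ZBTB16 first
    # low baseline: mean ~0.01 counts/cell at the median library size, so
    # canonical blasts detect module genes in only ~1% of cells (well below
    # the 3% specificity filter, as for the real module's genes)
    median_lib = float(np.exp(cfg.libsize_lognormal_params[0]))
    base[module_idx] = 0.0
    base[module_idx] = (0.01 / median_lib) * base.sum() * rng.uniform(0.6, 1.4, cfg.module_size)
    # ZBTB16 itself behaves near on/off: rare detection in canonical blasts,
    # near-universal detection in the non-canonical state
    base[k] = (cfg.zbtb16_base_rate / median_lib) * base.sum()

    m0 = k + cfg.module_size
    blast_marker_idx = np.arange(m0, m0 + cfg.n_marker_genes)
    normal_marker_idx = np.arange(m0 + cfg.n_marker_genes, m0 + 2 * cfg.n_marker_genes)

    p_zneg = base.copy()
    p_zneg[blast_marker_idx] = np.percentile(base[base > 0], 95)
    p_zneg[normal_marker_idx] = 0.0

    p_zpos = p_zneg.copy()
    # the ZBTB16+ state switches the module on as a coherent programme:
    # members share a common on-state level (narrow jitter) so each is a
    # comparable contributor to the module score, as the maximal-impact
    # filter demands of real module members
    p_zpos[module_idx] = ((0.01 * 2.0 ** cfg.module_log2_fc) / median_lib
                          * base.sum() * rng.uniform(0.85, 1.15, cfg.module_size))
    p_zpos[k] = (cfg.zbtb16_pos_rate / median_lib) * base.sum()

    p_norm = base.copy()
    p_norm[module_idx] = 0.0
    p_norm[blast_marker_idx] = 0.0
    p_norm[normal_marker_idx] = np.percentile(base[base > 0], 95)
    # distinct background for normal cells
    perturb = rng.choice(np.arange(k + cfg.module_size + 2 * cfg.n_marker_genes, n),
                         size=(n - m0 - 2 * cfg.n_marker_genes) // 5, replace=False)
    p_norm[perturb] *= rng.lognormal(0.0, 1.0, size=perturb.size)

    profiles = {s: p / p.sum() for s, p in
                [("zbtb16_neg", p_zneg), ("zbtb16_pos", p_zpos), ("normal", p_norm)]}
    return (genes, profiles, module_idx, blast_marker_idx, normal_marker_idx)


def simulate_sc_cohort(cfg: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the single-cell discovery-style cohort.

    Returns an AnnData (cells x genes, raw integer counts in ``X``) with
    per-cell metadata (patient, sample, timepoint, outcome, annotation —
    left ``unassigned``) and a :class:`GroundTruth` with latent cell states,
    planted module genes and per-sample true ZBTB16+ fractions.
    """
    cfg.validate()
    rng = cfg.rng("sc_cohort")
    genes, profiles, module_idx, bm_idx, nm_idx = _gene_profiles(cfg, rng)
    k = cfg.n_mito_genes
    mu_lib, sd_lib = cfg.libsize_lognormal_params
    a_mt, b_mt = cfg.mito_beta_params

    samples = []  # (sample_id, patient, timepoint, outcome, zbtb16_frac)
    for i in range(cfg.n_patients_responsive):
        pat = f"R{i + 1:03d}"
        samples.append((f"{pat}_d0", pat, "d0", "responsive", cfg.zbtb16_frac_responsive))
    for i in range(cfg.n_patients_failure):
        pat = f"F{i + 1:03d}"
        samples.append((f"{pat}_d0", pat, "d0", "induction_failure", cfg.zbtb16_frac_failure_day0))
        if i < cfg.n_failure_day28:
            samples.append((f"{pat}_d28", pat, "d28", "induction_failure",
                            cfg.zbtb16_frac_failure_day28))

    blocks, obs_rows, truth_rows = [], [], []
    sample_truth = []
    for sample_id, pat, tp, outcome, zfrac in samples:
        n_cells = cfg.cells_per_sample
        is_normal = rng.random(n_cells) < cfg.frac_normal_cells
        is_zpos = (~is_normal) & (rng.random(n_cells) < zfrac)
        state = np.where(is_normal, "normal", np.where(is_zpos, "zbtb16_pos", "zbtb16_neg"))

        libs = rng.lognormal(mu_lib, sd_lib, size=n_cells)
        mito = rng.beta(a_mt, b_mt, size=n_cells)

        # planted QC violators (disjoint; applied after drawing)
        order = rng.permutation(n_cells)
        n_lo_genes = int(round(cfg.qc_violator_frac[0] * n_cells))
        n_lo_count = int(round(cfg.qc_violator_frac[1] * n_cells))
        n_hi_mito = int(round(cfg.qc_violator_frac[2] * n_cells))
        lo_genes = order[:n_lo_genes]
        lo_count = order[n_lo_genes:n_lo_genes + n_lo_count]
        hi_mito = order[n_lo_genes + n_lo_count:n_lo_genes + n_lo_count + n_hi_mito]
        mito[hi_mito] = rng.uniform(0.30, 0.50, size=hi_mito.size)
        libs[lo_count] = rng.uniform(200, 900, size=lo_count.size)

        counts = np.empty((n_cells, cfg.n_genes), dtype=np.int64)
        for state_name, prof in profiles.items():
            mask = state == state_name
            if not mask.any():
                continue
            mean = libs[mask, None] * (1.0 - mito[mask, None]) * prof[None, :]
            mean[:, :k] = (libs[mask, None] * mito[mask, None]) / k
            counts[mask] = _nb_draw(rng, mean, cfg.nb_dispersion)

        # low-gene violators: keep only their 250 largest entries expressed
        for ci in lo_genes:
            row = counts[ci]
            nz = np.flatnonzero(row)
            if nz.size > 250:
                drop = nz[np.argsort(row[nz])[: nz.size - 250]]
                row[drop] = 0

        blocks.append(sparse.csr_matrix(counts))
        for ci in range(n_cells):
            cell_id = f"{sample_id}:c{ci:05d}"
            obs_rows.append((cell_id, pat, sample_id, tp, outcome, "unassigned"))
            truth_rows.append((cell_id, state[ci],
                               "none" if state[ci] == "normal"
                               else ("B" if state[ci] == "zbtb16_pos" else "A")))
        n_blast = int((~is_normal).sum())
        sample_truth.append((sample_id, pat, tp, outcome, n_blast,
                             int(is_zpos.sum()),
                             float(is_zpos.sum() / n_blast) if n_blast else np.nan))

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["cell_id", "patient", "sample_id",
                                          "timepoint", "outcome", "annotation"]
                       ).set_index("cell_id")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    adata = ad.AnnData(X=X, obs=obs, var=var)

    truth = GroundTruth(
        cell_truth=pd.DataFrame(truth_rows, columns=["cell_id", "latent_state", "clone_id"]
                                ).set_index("cell_id"),
        module_genes=[genes[i] for i in module_idx],
        blast_marker_genes=[genes[i] for i in bm_idx],
        normal_marker_genes=[genes[i] for i in nm_idx],
        sample_truth=pd.DataFrame(sample_truth, columns=[
            "sample_id", "patient", "timepoint", "outcome",
            "n_blasts", "n_zbtb16_pos", "true_zbtb16_frac"]).set_index("sample_id"),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# bulk survival cohort
# ---------------------------------------------------------------------------

#: Mean ZBTB16+ mixing weight per MRD category (rises with residual disease).
_MRD_PROBS = (0.55, 0.15, 0.12, 0.08, 0.10)
_MRD_MIX_MEAN = (0.01, 0.03, 0.07, 0.15, 0.45)


def simulate_bulk_cohort(cfg: SimConfig, mixing_zero: bool = False):
    """Generate a bulk RNA cohort with MRD-graded module signal and survival.

    Gene counts per sample are NB draws around a mixture of the ZBTB16+ and
    ZBTB16- pseudo-profiles; the mixing weight rises with the sample's MRD
    category. Overall/event-free survival times are exponential with the
    hazard multiplied by ``survival_hazard_ratio_per_tertile`` for each step
    of the *true* mixing-weight tertile; censoring is an independent
    exponential truncated at ``followup_years``.

    Returns ``(counts, samples, truth)``: a gene x sample integer DataFrame,
    a per-sample metadata DataFrame, and a per-sample truth DataFrame.
    """
    cfg.validate()
    rng = cfg.rng("bulk_cohort")
    genes, profiles, module_idx, _, _ = _gene_profiles(cfg, rng)
    p_pos, p_neg = profiles["zbtb16_pos"], profiles["zbtb16_neg"]
    # bulk profiles ignore the mito budget split
    p_pos = p_pos / p_pos.sum()
    p_neg = p_neg / p_neg.sum()

    n = cfg.bulk_n_samples
    cat_idx = rng.choice(len(MRD_CATEGORIES), size=n, p=_MRD_PROBS)
    if mixing_zero:
        w = np.zeros(n)
    else:
        mean_w = np.asarray(_MRD_MIX_MEAN)[cat_idx]
        w = rng.beta(mean_w * 20, (1 - mean_w) * 20)

    libs = rng.lognormal(np.log(cfg.bulk_libsize), 0.2, size=n)
    mix = w[:, None] * p_pos[None, :] + (1 - w[:, None]) * p_neg[None, :]
    counts = _nb_draw(rng, libs[:, None] * mix, cfg.bulk_nb_dispersion).T  # gene x sample

    # true tertiles of the mixing weight define the hazard groups
    q1, q2 = np.quantile(w, [1 / 3, 2 / 3]) if not mixing_zero else (0.0, 0.0)
    tert = np.digitize(w, [q1, q2], right=True) if not mixing_zero else np.zeros(n, int)
    hr = cfg.survival_hazard_ratio_per_tertile
    haz_os = cfg.baseline_hazard * hr ** tert
    haz_efs = 1.6 * cfg.baseline_hazard * hr ** tert
    t_os = rng.exponential(1.0 / haz_os)
    t_efs = rng.exponential(1.0 / haz_efs)
    cens = np.minimum(rng.exponential(1.0 / cfg.censoring_hazard, size=n),
                      cfg.followup_years)

    blast_pct = np.clip(rng.beta(8, 2, size=n) * 100, 0, 100)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "blast_percent": blast_pct,
        "mrd_category": [MRD_CATEGORIES[i] for i in cat_idx],
        "os_time": np.minimum(t_os, cens),
        "os_status": (t_os <= cens).astype(int),
        "efs_time": np.minimum(t_efs, cens),
        "efs_status": (t_efs <= cens).astype(int),
        "etp_status": rng.choice(["ETP", "near-ETP", "non-ETP"], size=n,
                                 p=[0.12, 0.15, 0.73]),
    }).set_index("sample_id")
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "true_mixing_weight": w,
        "true_tertile": tert,
        "true_mrd_category": [MRD_CATEGORIES[i] for i in cat_idx],
    }).set_index("sample_id")
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# allele counts and clonal structure
# ---------------------------------------------------------------------------

def simulate_allele_counts(cfg: SimConfig, states: list[str], depth: float,
                           n_cells: int | None = None, epsilon: float = 0.01
                           ) -> pd.DataFrame:
    """Per-cell phased major/minor allele counts for one segment per state.

    Major-allele counts are binomial with expected B-allele frequency 0.5
    (diploid), 1 - epsilon (copy-neutral LOH) or 2/3 (2:1 gain), over a
    Poisson total read count per cell with the given mean depth.
    """
    cfg.validate()
    for s in states:
        if s not in CN_STATE_BAF:
            raise ValueError(f"unknown copy-number state: {s!r}")
    rng = cfg.rng("allele_counts")
    n_cells = n_cells if n_cells is not None else cfg.cells_per_sample
    rows = []
    for si, state in enumerate(states):
        baf = CN_STATE_BAF[state]
        if state == "cnloh":
            baf = 1.0 - epsilon
        total = rng.poisson(depth, size=n_cells)
        major = rng.binomial(total, baf)
        for ci in range(n_cells):
            rows.append((f"c{ci:05d}", f"seg{si}", f"chr{si + 1}",
                         state, int(major[ci]), int(total[ci] - major[ci])))
    return pd.DataFrame(rows, columns=["cell_id", "segment_id", "chrom",
                                       "true_state", "major_count", "minor_count"])


def simulate_clonal_structure(cfg: SimConfig, n_precursor: int = 20,
                              n_private_a: int = 15, n_private_b: int = 15,
                              n_cells_a: int = 150, n_cells_b: int = 150,
                              depth_day0: int = 60, depth_day28: int = 429,
                              depth_cell: float = 1.0,
                              purity_a: float = 0.9, purity_b: float = 0.05,
                              topology: str = "shared_precursor"):
    """Two-sample, two-clone variant structure mirroring a shared-precursor
    phylogeny (clone A at day 0, clone B at day 28, common precursor).

    Returns ``(variants, cell_hits, cell_clones)``:

    * ``variants`` — per-variant table with per-sample alt/total counts and
      quality annotations (ASMD, CLPM, near-indel flags) suitable for
      :func:`tallscout.clonal.filter_substitutions`;
    * ``cell_hits`` — long table (cell_id, variant_id, alt_count) of
      clone-informative variant reads detected in single cells;
    * ``cell_clones`` — latent clone of every cell.

    ``topology`` may be ``shared_precursor``, ``linear`` (clone B carries
    all clone-A variants) or ``independent`` (no shared variants).

    The day-28 sample is sequenced deep (429x by default) because its
    tumour purity is low (~5% blasts): at standard depth the refractory
    clone's variants would fall below any sensible alt-read threshold.
    """
    cfg.validate()
    rng = cfg.rng("clonal")
    if topology == "linear":
        groups = [("precursor", n_precursor), ("B", n_private_b)]
    elif topology == "independent":
        groups = [("A", n_private_a), ("B", n_private_b)]
    elif topology == "shared_precursor":
        groups = [("precursor", n_precursor), ("A", n_private_a), ("B", n_private_b)]
    else:
        raise ValueError(f"unknown topology {topology!r}")

    # clone CCF per sample: A dominates sample day0, B dominates day28
    ccf = {"precursor": {"day0": 1.0, "day28": 1.0},
           "A": {"day0": 1.0, "day28": 0.0},
           "B": {"day0": 0.02, "day28": 1.0}}
    if topology == "linear":
        ccf["B"] = {"day0": 0.02, "day28": 1.0}
    purity = {"day0": purity_a, "day28": purity_b}

    rows, vid = [], 0
    for clone, n_vars in groups:
        for _ in range(n_vars):
            vid += 1
            row = {"variant_id": f"v{vid:03d}", "chrom": f"chr{rng.integers(1, 23)}",
                   "pos": int(rng.integers(1_000_000, 100_000_000)),
                   "ref": "C", "alt": "T", "clone": clone,
                   "ASMD": float(rng.integers(140, 255)), "CLPM": 0.0,
                   "near_indel": False}
            depth_by_sample = {"day0": depth_day0, "day28": depth_day28}
            for smp in ("day0", "day28"):
                vaf = 0.5 * ccf[clone][smp] * purity[smp]
                total = int(rng.poisson(depth_by_sample[smp]))
                row[f"alt_{smp}"] = int(rng.binomial(total, min(vaf, 1.0)))
                row[f"total_{smp}"] = total
            rows.append(row)
    variants = pd.DataFrame(rows)

    # single cells: day0 mostly clone A (plus minor B), day28 clone B
    cells = []
    for smp, n_cells in (("day0", n_cells_a), ("day28", n_cells_b)):
        for ci in range(n_cells):
            if smp == "day0":
                clone = "B" if rng.random() < 0.02 else "A"
            else:
                clone = "B"
            cells.append((f"{smp}:c{ci:04d}", smp, clone))
    cell_clones = pd.DataFrame(cells, columns=["cell_id", "sample", "clone"]
                               ).set_index("cell_id")

    carries = {"precursor": {"A", "B"}, "A": {"A"}, "B": {"B"}}
    if topology == "linear":
        carries = {"precursor": {"A", "B"}, "B": {"B"}}
    hit_rows = []
    for _, v in variants.iterrows():
        carriers = carries[v["clone"]]
        for cell_id, rec in cell_clones.iterrows():
            if rec["clone"] in carriers:
                alt = rng.poisson(depth_cell * 0.5)
                if alt > 0:
                    hit_rows.append((cell_id, v["variant_id"], int(alt)))
    cell_hits = pd.DataFrame(hit_rows, columns=["cell_id", "variant_id", "alt_count"])
    return variants, cell_hits, cell_clones


# ---------------------------------------------------------------------------
# writers (MTX + TSV sidecars; all plain text)
# ---------------------------------------------------------------------------

def write_sc_cohort(adata: ad.AnnData, truth: GroundTruth, outdir: str | Path) -> None:
    """Write genes x cells MTX with genes.tsv / barcodes.tsv / cells_meta.tsv
    sidecars plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(adata.X).T.astype(int))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "cells_meta.tsv", sep="\t")
    truth.cell_truth.to_csv(outdir / "truth.tsv", sep="\t")
    if truth.sample_truth is not None:
        truth.sample_truth.to_csv(outdir / "sample_truth.tsv", sep="\t")
    pd.Series(truth.module_genes).to_csv(outdir / "module_genes.tsv", sep="\t",
                                         index=False, header=False)


def write_bulk_cohort(counts: pd.DataFrame, samples: pd.DataFrame,
                      outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    samples.to_csv(outdir / "samples.tsv", sep="\t")


def read_sc_cohort(indir: str | Path) -> ad.AnnData:
    """Read a cohort written by :func:`write_sc_cohort` back into AnnData."""
    from scipy.io import mmread

    indir = Path(indir)
    X = sparse.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "cells_meta.tsv", sep="\t", index_col=0)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    return ad.AnnData(X=X, obs=obs, var=var)


def config_to_yaml(cfg: SimConfig, path: str | Path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("libsize_lognormal_params", "mito_beta_params", "qc_violator_frac"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
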