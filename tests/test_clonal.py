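"""Variant filters, CN posteriors, CCF arithmetic and clone assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tallscout as ts
from tallscout import clonal as cl


def _variant(**kw):
    base = dict(variant_id="v1", chrom="chr1", pos=1000, ref="C", alt="T",
                ASMD=200.0, CLPM=0.0, near_indel=False,
                alt_count=20, depth=60)
    base.update(kw)
    return base


def test_filter_quality_annotations():
    df = pd.DataFrame([
        _variant(variant_id="ok"),
        _variant(variant_id="asmd139", ASMD=139.0),
        _variant(variant_id="clipped", CLPM=1.0),
        _variant(variant_id="indel", near_indel=True),
        _variant(variant_id="shallow", depth=5),
        _variant(variant_id="deep", depth=5000),
        _variant(variant_id="noalt", alt_count=0),
        _variant(variant_id="unann", ASMD=np.nan),
    ])
    out = cl.filter_substitutions(df, error_rate=1e-3).set_index("variant_id")
    assert out.loc["ok", "filter_reason"] == "pass"
    assert out.loc["asmd139", "filter_reason"] == "low_ASMD"
    assert out.loc["clipped", "filter_reason"] == "clipped_reads"
    assert out.loc["indel", "filter_reason"] == "near_indel"
    assert out.loc["shallow", "filter_reason"] == "depth_out_of_bounds"
    assert out.loc["deep", "filter_reason"] == "depth_out_of_bounds"
    assert out.loc["noalt", "filter_reason"] == "background_noise"
    assert out.loc["noalt", "p_noise"] == pytest.approx(1.0)
    assert out.loc["unann", "filter_reason"] == "unannotated"


def test_filter_binomial_noise_oracle():
    """True VAF-0.25 variants at depth 40 survive; pure-error sites do not."""
    rng = np.random.default_rng(0)
    err = 1e-3
    rows = []
    for i in range(300):
        alt = rng.binomial(40, 0.25)
        rows.append(_variant(variant_id=f"t{i}", alt_count=alt, depth=40))
    for i in range(300):
        alt = rng.binomial(40, err)
        rows.append(_variant(variant_id=f"e{i}", alt_count=alt, depth=40))
    out = cl.filter_substitutions(pd.DataFrame(rows), error_rate=err)
    out = out.set_index("variant_id")
    true_kept = (out.loc[[f"t{i}" for i in range(300)],
                         "filter_reason"] == "pass").mean()
    err_kept = (out.loc[[f"e{i}" for i in range(300)],
                        "filter_reason"] == "pass").mean()
    assert true_kept >= 0.99
    assert err_kept <= 0.05


def _seg_table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "segment_id",
                                       "major_count", "minor_count"])


def test_cn_posterior_direct_bayes_cases():
    states = {"diploid": 0.5, "cnloh": 0.99}
    # 20 reads all major: cnloh posterior overwhelming
    t = _seg_table([("c1", "seg1", 20, 0)])
    out = cl.cell_cn_posterior(t, states=states)
    lik_d, lik_c = 0.5 ** 20, 0.99 ** 20
    assert out.loc[0, "post_cnloh"] == pytest.approx(lik_c / (lik_c + lik_d))
    assert out.loc[0, "post_cnloh"] > 0.999
    assert out.loc[0, "call"] == "cnloh"
    # one read cannot reach 0.95 for BAFs {0.5, 0.99}
    t = _seg_table([("c1", "seg1", 1, 0)])
    out = cl.cell_cn_posterior(t, states=states)
    assert out.loc[0, "post_cnloh"] == pytest.approx(0.99 / 1.49)
    assert out.loc[0, "call"] == "uncalled"
    # symmetric 10/10 favours diploid
    t = _seg_table([("c1", "seg1", 10, 10)])
    out = cl.cell_cn_posterior(t, states=states)
    assert out.loc[0, "post_diploid"] > out.loc[0, "post_cnloh"]
    # zero total reads -> uncalled
    t = _seg_table([("c1", "seg1", 0, 0)])
    assert cl.cell_cn_posterior(t, states=states).loc[0, "call"] == "uncalled"


@given(st.integers(min_value=0, max_value=30), st.integers(min_value=0, max_value=8))
@settings(max_examples=60, deadline=None)
def test_cn_posterior_monotone_in_consistent_evidence(major, extra):
    """Adding major-allele reads never lowers the cnloh posterior."""
    states = {"diploid": 0.5, "cnloh": 0.99}
    t1 = _seg_table([("c", "s", major, 3)])
    t2 = _seg_table([("c", "s", major + extra, 3)])
    p1 = cl.cell_cn_posterior(t1, states=states).loc[0, "post_cnloh"]
    p2 = cl.cell_cn_posterior(t2, states=states).loc[0, "post_cnloh"]
    assert p2 >= p1 - 1e-12


def test_pseudobulk_baf_mixture_and_additivity():
    cfg = ts.SimConfig(seed=13)
    eps = 0.01
    a = ts.simulate_allele_counts(cfg, ["cnloh"], depth=30, n_cells=900,
                                  epsilon=eps)
    b = ts.simulate_allele_counts(cfg, ["diploid"], depth=30, n_cells=100)
    b["cell_id"] = "d_" + b["cell_id"]
    b["segment_id"] = "seg0"
    mix = pd.concat([a, b], ignore_index=True)
    pooled = cl.pseudobulk_baf(mix)
    expect = 0.9 * (1 - eps) + 0.1 * 0.5
    assert pooled.loc[0, "baf"] == pytest.approx(expect, abs=0.01)
    # additive over disjoint groups
    g1 = cl.pseudobulk_baf(mix, set(a["cell_id"]))
    g2 = cl.pseudobulk_baf(mix, set(b["cell_id"]))
    assert (g1["major_count"].sum() + g2["major_count"].sum()
            == pooled["major_count"].sum())


@pytest.mark.parametrize("vaf,cn,m,purity,expected", [
    (0.5, 2, 1, 1.0, 1.0),
    (0.25, 2, 1, 1.0, 0.5),
    (0.025, 2, 1, 0.05, 1.0),   # refractory regime: 5% blasts
])
def test_ccf_hand_computed_values(vaf, cn, m, purity, expected):
    assert cl.compute_ccf(vaf, cn, m, purity) == pytest.approx(expected)


def test_ccf_linearity_and_errors():
    vals = [cl.compute_ccf(v, 2, 1, 0.5) for v in (0.05, 0.10, 0.15)]
    assert np.diff(vals) == pytest.approx([vals[0]] * 2)
    with pytest.raises(ValueError, match="purity"):
        cl.compute_ccf(0.2, 2, 1, 0.0)
    with pytest.raises(ValueError, match="mutated_copies"):
        cl.compute_ccf(0.2, 2, 0, 1.0)
    assert cl.compute_ccf(0.9, 2, 1, 1.0) == pytest.approx(1.05)  # clipped


def test_choose_mutated_copies_matches_expected_vaf():
    # pure tumour, cn 3: VAF 1/3 -> one copy; VAF 2/3 -> two copies
    assert cl.choose_mutated_copies(1 / 3, 90, 3, 1.0) == 1
    assert cl.choose_mutated_copies(2 / 3, 90, 3, 1.0) == 2
    assert cl.choose_mutated_copies(0.5, 90, 2, 1.0) == 1


def _presence_frames(pattern):
    """Build CCF/alt tables from {variant: (ccf_day0, ccf_day28)}."""
    ccf = pd.DataFrame(pattern, index=["day0", "day28"]).T
    alts = (ccf * 100).astype(int)
    return ccf, alts


def test_assign_clones_topologies():
    # all variants shared: linear/undistinguished, no private clones
    ccf, alts = _presence_frames({f"v{i}": (1.0, 1.0) for i in range(5)})
    m = cl.assign_clones(ccf, alts)
    assert m.topology == "linear_or_undistinguished"
    assert (m.variant_clones == "precursor").all()
    # disjoint variant sets: completely independent
    pattern = {f"a{i}": (1.0, 0.0) for i in range(4)}
    pattern.update({f"b{i}": (0.0, 1.0) for i in range(4)})
    ccf, alts = _presence_frames(pattern)
    m = cl.assign_clones(ccf, alts)
    assert m.topology == "independent"
    # shared + A-private only: linear
    pattern = {f"p{i}": (1.0, 1.0) for i in range(4)}
    pattern.update({f"b{i}": (0.0, 1.0) for i in range(4)})
    ccf, alts = _presence_frames(pattern)
    assert cl.assign_clones(ccf, alts).topology == "linear"


def test_assign_clones_shared_precursor_recovery_with_cells():
    cfg = ts.SimConfig(seed=17)
    variants, hits, cell_clones = ts.simulate_clonal_structure(cfg)
    filt = cl.filter_substitutions(variants, error_rate=1e-3)
    keep = filt[filt["filter_reason"] == "pass"].set_index("variant_id")
    ccf = pd.DataFrame({
        "day0": [cl.compute_ccf(a / t, 2, 1, 0.9)
                 for a, t in zip(keep["alt_day0"], keep["total_day0"])],
        "day28": [cl.compute_ccf(a / t, 2, 1, 0.05)
                  for a, t in zip(keep["alt_day28"], keep["total_day28"])],
    }, index=keep.index)
    alts = keep[["alt_day0", "alt_day28"]].rename(
        columns={"alt_day0": "day0", "alt_day28": "day28"})
    model = cl.assign_clones(ccf, alts, cell_hits=hits)
    assert model.topology == "shared_precursor"
    truthmap = variants.set_index("variant_id")["clone"]
    assert (model.variant_clones == truthmap.loc[model.variant_clones.index]
            ).mean() >= 0.95
    desc = cell_clones.join(model.cell_labels.rename("called"), how="inner")
    desc = desc[desc["called"].isin(["A", "B"])]
    assert len(desc) > 0
    assert (desc["called"] == desc["clone"]).mean() >= 0.95
    # precursor containment: precursor CCF covers both samples
    assert (model.clone_ccf.loc["precursor"] >= 0.5).all()


def test_assign_clones_ambiguous_cells_flagged():
    pattern = {"p1": (1.0, 1.0), "a1": (1.0, 0.0), "b1": (0.0, 1.0)}
    ccf, alts = _presence_frames(pattern)
    hits = pd.DataFrame({"cell_id": ["cx", "cx", "cy"],
                         "variant_id": ["a1", "b1", "a1"],
                         "alt_count": [2, 1, 3]})
    m = cl.assign_clones(ccf, alts, cell_hits=hits)
    assert m.cell_labels["cx"] == "ambiguous"
    assert m.cell_labels["cy"] == "A"


def test_assign_clones_cn_evidence_and_tcr_consistency():
    pattern = {"p1": (1.0, 1.0), "a1": (1.0, 0.0), "b1": (0.0, 1.0)}
    ccf, alts = _presence_frames(pattern)
    cn_calls = pd.DataFrame({"cell_id": ["c1", "c2"],
                             "segment_id": ["seg17", "seg17"],
                             "call": ["gain21", "diploid"]})
    seg_map = {("seg17", "gain21"): "A", ("seg17", "diploid"): "B"}
    tcr = pd.Series({"c1": "TRBV1", "c2": "TRBV9"})
    m = cl.assign_clones(ccf, alts, cn_calls=cn_calls,
                         segment_clone_map=seg_map, tcr_labels=tcr)
    assert m.cell_labels["c1"] == "A" and m.cell_labels["c2"] == "B"
    assert m.tcr_consistency == pytest.approx(1.0)


def test_clone_model_json_roundtrip(tmp_path):
    pattern = {"p1": (1.0, 1.0), "a1": (1.0, 0.0), "b1": (0.0, 1.0)}
    ccf, alts = _presence_frames(pattern)
    m = cl.assign_clones(ccf, alts)
    m.to_json(tmp_path / "clones.json")
    import json

    data = json.loads((tmp_path / "clones.json").read_text())
    assert data["topology"] == "shared_precursor"
    assert data["clones"]["precursor"] == ["p1"]
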