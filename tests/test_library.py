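"""Library initialization: phenotypes, interactions, efficacies, frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import truncnorm

from dkosim import (
    SimConfig,
    build_library,
    init_gene_panel,
    init_guide_efficacies,
    init_interaction_map,
    sample_truncated_normal,
)
from dkosim.library import allocate_frequencies


# ------------------------------------------------------------------ #
# truncated-normal sampler
# ------------------------------------------------------------------ #
def test_truncated_normal_support_and_degenerate_sigma(rng):
    x = sample_truncated_normal(0.0, 0.25, -0.025, 0.025, 500, rng)
    assert np.all((-0.025 <= x) & (x <= 0.025))
    x = sample_truncated_normal(-0.75, 1e-9, -1, -0.025, 10, rng)
    np.testing.assert_allclose(x, -0.75, atol=1e-6)


def test_truncated_normal_mean_matches_analytic(rng):
    mu, sigma, lo, hi = -0.75, 0.1, -1.0, -0.025
    n = 10**5
    x = sample_truncated_normal(mu, sigma, lo, hi, n, rng)
    dist = truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)
    se = dist.std() / np.sqrt(n)
    assert abs(x.mean() - dist.mean()) < 3 * se


def test_truncated_normal_errors(rng):
    with pytest.raises(ValueError):
        sample_truncated_normal(0, 1, 1.0, 0.0, 5, rng)
    with pytest.raises(ValueError):
        sample_truncated_normal(0, 1e-3, 5.0, 6.0, 5, rng)  # no mass in interval


# ------------------------------------------------------------------ #
# gene panel
# ------------------------------------------------------------------ #
def test_gene_panel_class_counts_baseline(rng):
    panel = init_gene_panel(SimConfig(), rng)
    counts = panel["gene_class"].value_counts()
    assert counts["negative"] == 18
    assert counts["positive"] == 6
    assert counts["wild_type"] == 90
    assert counts["control"] == 6


def test_gene_panel_phenotype_supports(rng, small_config):
    panel = init_gene_panel(small_config, rng)
    cls, p = panel["gene_class"], panel["p"]
    assert np.all(p[cls == "control"] == 0.0)
    assert np.all((p[cls == "negative"] >= -1) & (p[cls == "negative"] <= -0.025))
    assert np.all((p[cls == "positive"] >= 0.025) & (p[cls == "positive"] <= 1))
    assert np.all(np.abs(p[cls == "wild_type"]) <= 0.025)
    assert np.all(panel["f0_prime"] > 0)


def test_gene_panel_tiny_dispersion_gives_unit_seeds(rng):
    cfg = SimConfig(sigma_f=1e-12)
    panel = init_gene_panel(cfg, rng)
    np.testing.assert_allclose(panel["f0_prime"], 1.0, atol=1e-9)


def test_gene_panel_override(rng):
    cfg = SimConfig(n=3, pct_neg=1 / 3, pct_pos=0, pct_wt=1 / 3, pct_ctrl=1 / 3)
    ov = pd.DataFrame(
        {"gene_id": [1, 2, 3],
         "class": ["negative", "wild_type", "control"],
         "p": [-0.4, np.nan, np.nan]}
    )
    panel = init_gene_panel(cfg, rng, override=ov)
    assert panel.loc[0, "p"] == -0.4
    assert abs(panel.loc[1, "p"]) <= 0.025
    assert panel.loc[2, "p"] == 0.0


# ------------------------------------------------------------------ #
# interaction map
# ------------------------------------------------------------------ #
def test_no_interactions_when_pct_gi_zero(rng, toy_config):
    panel = init_gene_panel(toy_config, rng)
    imap = init_interaction_map(panel, toy_config, rng)
    assert len(imap) == 3
    assert (imap["I"] == 0).all()
    assert (imap["pi"] == 0).all()
    assert (imap["category"] == "none").all()
    # pair frequency seed is the mean of the two gene seeds
    f0 = panel.set_index("gene_id")["f0_prime"]
    np.testing.assert_allclose(
        imap["f_pair"], (f0.loc[imap["k1"]].to_numpy() + f0.loc[imap["k2"]].to_numpy()) / 2
    )


def test_full_gi_flags_only_control_free_pair(rng, toy_config):
    cfg = toy_config.replace(pct_gi=1.0)
    panel = init_gene_panel(cfg, rng)
    imap = init_interaction_map(panel, cfg, rng)
    ctrl = set(panel.loc[panel["gene_class"] == "control", "gene_id"])
    flagged = imap[imap["I"] == 1]
    assert len(flagged) == 1  # one eligible pair among three genes with one control
    assert not (set(flagged["k1"]) | set(flagged["k2"])) & ctrl


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    n=st.integers(min_value=4, max_value=20),
    pct_gi=st.floats(min_value=0.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=10**6),
)
def test_gi_flag_count_exact_and_avoids_controls(n, pct_gi, seed):
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n=n, pct_gi=pct_gi, pct_neg=0.25, pct_pos=0.25,
                    pct_wt=0.25, pct_ctrl=0.25)
    panel = init_gene_panel(cfg, rng)
    imap = init_interaction_map(panel, cfg, rng)
    ctrl = set(panel.loc[panel["gene_class"] == "control", "gene_id"])
    eligible = imap[~imap["k1"].isin(ctrl) & ~imap["k2"].isin(ctrl)]
    assert imap["I"].sum() == int(np.rint(pct_gi * len(eligible)))
    touched = imap[imap["I"] == 1]
    assert not (set(touched["k1"]) | set(touched["k2"])) & ctrl
    # unflagged pairs carry their base phenotypes and a zero interaction
    off = imap[imap["I"] == 0]
    assert (off["p1_I"] == off["p1"]).all()
    assert (off["pi"] == 0).all()


def test_degenerate_jiggle_gives_zero_interaction(rng, small_config):
    cfg = small_config.replace(sigma_gi=1e-9)
    panel = init_gene_panel(cfg, rng)
    imap = init_interaction_map(panel, cfg, rng)
    flagged = imap[imap["I"] == 1]
    assert len(flagged) > 0
    np.testing.assert_allclose(flagged["p1_I"], flagged["p1"], atol=1e-6)
    np.testing.assert_allclose(flagged["pi"], 0.0, atol=1e-5)


# ------------------------------------------------------------------ #
# guide efficacies
# ------------------------------------------------------------------ #
def test_full_efficacy_mode(rng):
    eff = init_guide_efficacies(SimConfig(), rng)
    assert (eff["eff"] == 1.0).all()


def test_crisprn_mode_separates_high_and_low(rng):
    cfg = SimConfig(mode="CRISPRn", pct_heg=0.5)
    eff = init_guide_efficacies(cfg, rng)
    high = eff[eff["eff_category"] == "high"]["eff"]
    low = eff[eff["eff_category"] == "low"]["eff"]
    assert len(high) == int(np.rint(0.5 * 360))
    assert high.min() >= 0.6 and high.max() <= 1.0
    assert low.min() >= 0.0 and low.max() <= 0.6


def test_crisprn_all_low_mean_matches_truncated_normal(rng):
    cfg = SimConfig(mode="CRISPRn", pct_heg=0.0, n=40, n_guides=5)
    eff = init_guide_efficacies(cfg, rng)["eff"]
    dist = truncnorm((0 - 0.05) / 0.07, (0.6 - 0.05) / 0.07, loc=0.05, scale=0.07)
    assert abs(eff.mean() - dist.mean()) < 4 * dist.std() / np.sqrt(len(eff))


# ------------------------------------------------------------------ #
# frequency allocation / construct table
# ------------------------------------------------------------------ #
@settings(max_examples=20, derandomize=True, deadline=None)
@given(n=st.integers(min_value=2, max_value=10), ng=st.integers(min_value=1, max_value=5))
def test_construct_count_formula(n, ng):
    rng = np.random.default_rng(17)
    cfg = SimConfig(n=n, n_guides=ng, coverage=5, pct_gi=0,
                    pct_neg=0, pct_pos=0, pct_wt=1.0, pct_ctrl=0)
    *_, table = build_library(cfg, rng)
    assert len(table) == n * ng + (n * (n - 1) // 2) * ng**2


def test_toy_library_shape_and_size(rng, toy_config):
    *_, table = build_library(toy_config, rng)
    assert len(table) == 18
    assert (table["kind"] == "SKO").sum() == 6
    L0 = toy_config.library_size
    assert L0 == 1800
    assert abs(int(table["c0"].sum()) - L0) <= len(table) / 2  # rounding slack


def test_frequencies_normalize_and_balance(rng, small_config):
    panel, imap, eff, table = build_library(small_config, rng)
    assert table["f_rel0"].sum() == pytest.approx(1.0, abs=1e-9)
    probs = table[["p_div0", "p_div1", "p_div2", "p_div3"]].to_numpy()
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    # per gene, guide frequencies add to the gene seed; per pair, the mean
    # SKO guide frequency equals the mean DKO guide-pair frequency
    ng = small_config.n_guides
    sko = table[table["kind"] == "SKO"]
    gene_sums = sko.groupby("k1")["fg"].sum()
    np.testing.assert_allclose(
        gene_sums.to_numpy(), panel.set_index("gene_id")["f0_prime"].loc[gene_sums.index],
        rtol=1e-12,
    )
    dko = table[table["kind"] == "DKO"]
    pair_sums = dko.groupby(["k1", "k2"])["fg"].sum()
    for (k1, k2), s in pair_sums.items():
        lhs = (gene_sums.loc[k1] + gene_sums.loc[k2]) / (2 * ng)
        assert s / ng**2 == pytest.approx(lhs, rel=1e-12)


def test_high_alpha_equalizes_guides(rng):
    cfg = SimConfig(n=4, n_guides=3, pct_gi=0, pct_neg=0, pct_pos=0,
                    pct_wt=0.75, pct_ctrl=0.25, dirichlet_alpha=1e8)
    *_, table = build_library(cfg, rng)
    rel = table[table["kind"] == "SKO"].groupby("k1")["fg"].transform(lambda s: s / s.mean())
    np.testing.assert_allclose(rel, 1.0, rtol=1e-3)


def test_sko_rows_ignore_interaction_jiggle(rng, small_config):
    cfg = small_config.replace(pct_gi=1.0, sigma_gi=2.0)
    panel, imap, eff, table = build_library(cfg, rng)
    sko = table[table["kind"] == "SKO"]
    p = panel.set_index("gene_id")["p"]
    np.testing.assert_allclose(sko["p1"], p.loc[sko["k1"]].to_numpy())
    np.testing.assert_allclose(sko["p1_eff"], sko["p1"] * sko["eff1"])


def test_control_partner_dko_matches_sko_distribution(rng, toy_config):
    # with full efficacy and no interactions, a DKO with a control partner
    # divides exactly like its non-control partner's SKO
    panel, imap, eff, table = build_library(toy_config, rng)
    ctrl = set(panel.loc[panel["gene_class"] == "control", "gene_id"])
    cols = ["p_div0", "p_div1", "p_div2", "p_div3"]
    sko = table[table["kind"] == "SKO"].set_index(["k1", "j1"])
    dko = table[table["kind"] == "DKO"]
    checked = 0
    for row in dko.itertuples(index=False):
        if row.k2 in ctrl and row.k1 not in ctrl:
            partner = sko.loc[(row.k1, row.j1)]
            np.testing.assert_allclose(
                [getattr(row, c) for c in cols],
                partner[cols].to_numpy(dtype=float),
                atol=1e-12,
            )
            checked += 1
    assert checked > 0
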