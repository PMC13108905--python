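"""Initial cell-library construction.

Builds, in order: the gene panel (class labels, theoretical phenotypes and
log-normal initial-frequency seeds), the gene-pair interaction map (which
pairs interact, their jiggled phenotypes and ground-truth interaction
values), the per-guide efficacy table, and finally the construct table —
one row per single-knockout guide and per double-knockout guide pair — with
Dirichlet-allocated initial frequencies, integer initial counts, and the
cell-division probability vector of every construct.

All tables are plain pandas DataFrames so they serialize losslessly to CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import SimConfig
from .growth import dko_division_probs, true_gi

__all__ = [
    "sample_truncated_normal",
    "init_gene_panel",
    "init_interaction_map",
    "init_guide_efficacies",
    "allocate_frequencies",
    "build_library",
]

# phenotype support per gene class
CLASS_SUPPORT = {
    "negative": (-1.0, -0.025),
    "positive": (0.025, 1.0),
    "wild_type": (-0.025, 0.025),
    "unknown": (-0.5, 0.5),
}


def sample_truncated_normal(mu, sigma, lo, hi, size, rng) -> np.ndarray:
    """Exact i.i.d. draws from N(mu, sigma^2) conditioned on [lo, hi].

    Sampling is by inverse CDF on the truncated range (uniform between the
    CDF values of the bounds), which is exact and reproducible — not
    clip-after-draw.  ``mu`` may be an array (per-draw centers).
    ``sigma = 0`` degenerates to the clipped mean.
    """
    if np.any(np.asarray(lo) >= np.asarray(hi)):
        raise ValueError("require lo < hi")
    mu = np.asarray(mu, dtype=float)
    if sigma == 0:
        return np.broadcast_to(np.clip(mu, lo, hi), np.broadcast_shapes(mu.shape, (size,))).copy()
    a = norm.cdf((lo - mu) / sigma)
    b = norm.cdf((hi - mu) / sigma)
    if np.any(b - a < 1e-300):
        raise ValueError("truncation interval carries vanishing probability mass")
    u = rng.uniform(a, b, size=size)
    return mu + sigma * norm.ppf(u)


def init_gene_panel(
    config: SimConfig, rng, override: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Gene panel: one row per gene with class, phenotype p and frequency seed.

    Classes are assigned to gene indices by a seeded shuffle with exactly
    ``round(fraction * n)`` genes per class (remainder to wild type).
    Phenotypes are drawn from the class-specific truncated normals; controls
    have p = 0 exactly.  The initial-frequency seed satisfies
    ``log10(f0') ~ N(0, sigma_f^2)``.

    ``override`` optionally fixes gene classes and/or phenotypes: a frame
    with columns ``gene_id``, ``class`` and optional ``p`` (NaN p => sampled).
    """
    n = config.n
    if override is not None:
        if len(override) != n:
            raise ValueError("override panel must have one row per gene")
        ov = override.sort_values("gene_id").reset_index(drop=True)
        classes = ov["class"].to_numpy()
        fixed_p = ov["p"].to_numpy(dtype=float) if "p" in ov else np.full(n, np.nan)
    else:
        counts = config.class_counts()
        classes = np.repeat(
            ["negative", "positive", "wild_type", "control", "unknown"],
            [counts["negative"], counts["positive"], counts["wild_type"],
             counts["control"], counts["unknown"]],
        )
        rng.shuffle(classes)
        fixed_p = np.full(n, np.nan)

    params = {
        "negative": (config.mu_neg, config.sigma_neg),
        "positive": (config.mu_pos, config.sigma_pos),
        "wild_type": (0.0, config.sigma_wt),
        "unknown": (0.0, config.sigma_unknown),
    }
    p = np.zeros(n)
    for cls, (mu, sigma) in params.items():
        mask = (classes == cls) & np.isnan(fixed_p)
        if mask.any():
            lo, hi = CLASS_SUPPORT[cls]
            p[mask] = sample_truncated_normal(mu, sigma, lo, hi, int(mask.sum()), rng)
    p[classes == "control"] = 0.0
    keep = ~np.isnan(fixed_p) & (classes != "control")
    p[keep] = fixed_p[keep]

    f0_prime = 10.0 ** rng.normal(0.0, config.sigma_f, size=n)
    return pd.DataFrame(
        {"gene_id": np.arange(1, n + 1), "gene_class": classes, "p": p, "f0_prime": f0_prime}
    )


def init_interaction_map(panel: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    """All unordered gene pairs with interaction flags, jiggled phenotypes,
    ground-truth interaction pi and pair frequency seeds.

    Exactly ``round(pct_gi * n_eligible)`` pairs are flagged interacting,
    drawn uniformly without replacement from the pairs that contain no
    non-targeting control.  Flagged pairs get phenotypes re-drawn from
    N(p_i, sigma_gi^2) truncated to [-1, 1]; unflagged pairs keep their base
    phenotypes and have pi = 0.
    """
    if len(panel) < 2:
        raise ValueError("need at least two genes to form pairs")
    n = len(panel)
    k1, k2 = np.triu_indices(n, 1)
    p = panel["p"].to_numpy()
    cls = panel["gene_class"].to_numpy()
    p1, p2 = p[k1], p[k2]
    eligible = (cls[k1] != "control") & (cls[k2] != "control")

    n_flag = int(np.rint(config.pct_gi * eligible.sum()))
    if config.pct_gi > 0 and eligible.sum() == 0:
        raise ValueError("pct_gi > 0 but no pairs without a control gene exist")
    flag = np.zeros(len(k1), dtype=np.int64)
    if n_flag > 0:
        chosen = rng.choice(np.flatnonzero(eligible), size=n_flag, replace=False)
        flag[chosen] = 1

    p1_i, p2_i = p1.copy(), p2.copy()
    hit = flag == 1
    if hit.any():
        m = int(hit.sum())
        p1_i[hit] = sample_truncated_normal(p1[hit], config.sigma_gi, -1.0, 1.0, m, rng)
        p2_i[hit] = sample_truncated_normal(p2[hit], config.sigma_gi, -1.0, 1.0, m, rng)

    pi = true_gi(p1, p2, p1_i, p2_i)
    pi[~hit] = 0.0
    f0 = panel["f0_prime"].to_numpy()
    category = np.where(pi < 0, "negative", np.where(pi > 0, "positive", "none"))
    return pd.DataFrame(
        {
            "k1": k1 + 1,
            "k2": k2 + 1,
            "I": flag,
            "p1": p1,
            "p2": p2,
            "p1_I": p1_i,
            "p2_I": p2_i,
            "pi": pi,
            "category": category,
            "f_pair": (f0[k1] + f0[k2]) / 2.0,
        }
    )


def init_guide_efficacies(config: SimConfig, rng) -> pd.DataFrame:
    """Per-guide knockout efficacy in [0, 1] with a high/low category label.

    Exactly ``round(pct_heg * n * n_g)`` guides are labeled high efficacy
    (assignment uniform at random over all guides).  In CRISPRn mode high
    guides draw from N(mu_high, sigma_high^2) truncated to [0.6, 1] and low
    guides from N(mu_low, sigma_low^2) truncated to [0, 0.6], so every high
    guide outperforms every low guide; in CRISPRn-100%Eff mode all
    efficacies are exactly 1.
    """
    total = config.n * config.n_guides
    n_high = int(np.rint(config.pct_heg * total))
    category = np.array(["low"] * total, dtype=object)
    if n_high > 0:
        category[rng.choice(total, size=n_high, replace=False)] = "high"
    eff = np.ones(total)
    if config.mode == "CRISPRn":
        high = category == "high"
        if high.any():
            eff[high] = sample_truncated_normal(
                config.mu_high, config.sigma_high, 0.6, 1.0, int(high.sum()), rng
            )
        if (~high).any():
            eff[~high] = sample_truncated_normal(
                config.mu_low, config.sigma_low, 0.0, 0.6, int((~high).sum()), rng
            )
    gene = np.repeat(np.arange(1, config.n + 1), config.n_guides)
    guide = np.tile(np.arange(1, config.n_guides + 1), config.n)
    return pd.DataFrame(
        {"gene_id": gene, "guide_id": guide, "eff_category": category, "eff": eff}
    )


def allocate_frequencies(
    panel: pd.DataFrame,
    interaction_map: pd.DataFrame,
    efficacies: pd.DataFrame,
    config: SimConfig,
    rng,
) -> pd.DataFrame:
    """Construct table: frequencies, counts and division probabilities.

    Within each gene the n_g SKO guide frequencies split the gene seed f_k
    by a symmetric Dirichlet(alpha); within each pair the n_g^2 DKO guide
    pairs split ``f_pair * n_g`` by a Dirichlet(alpha) over n_g^2 cells, so
    that for every pair the average SKO and DKO guide frequency coincide.
    Relative frequencies normalize by the global sum; initial counts are
    ``round(f_rel * L0)`` (half-to-even, counts of 0 permitted) with
    L0 = coverage x number of constructs.

    Effective phenotypes scale by guide efficacy: SKO rows use the base gene
    phenotype (interaction jiggles are a pair-level concept); DKO rows use
    the pair's jiggled phenotypes.  Division probabilities come from the DKO
    distribution, with the second phenotype 0 for SKO rows.
    """
    n, ng = config.n, config.n_guides
    alpha = config.dirichlet_alpha
    n_pairs = len(interaction_map)

    f_gene = panel["f0_prime"].to_numpy()
    p_gene = panel["p"].to_numpy()
    cls = panel["gene_class"].to_numpy()
    eff = efficacies["eff"].to_numpy().reshape(n, ng)
    eff_cat = efficacies["eff_category"].to_numpy().reshape(n, ng)

    # Dirichlet splits via normalized gamma draws (vectorized across groups)
    g = rng.gamma(alpha, size=(n, ng))
    fg_sko = f_gene[:, None] * g / g.sum(axis=1, keepdims=True)
    g = rng.gamma(alpha, size=(n_pairs, ng * ng))
    fg_dko = (interaction_map["f_pair"].to_numpy() * ng)[:, None] * g / g.sum(
        axis=1, keepdims=True
    )

    # --- SKO rows -----------------------------------------------------
    sko_k = np.repeat(np.arange(n), ng)
    sko_j = np.tile(np.arange(ng), n)
    sko = pd.DataFrame(
        {
            "kind": "SKO",
            "k1": sko_k + 1,
            "j1": sko_j + 1,
            "k2": 0,
            "j2": 0,
            "class1": cls[sko_k],
            "class2": "",
            "eff1": eff[sko_k, sko_j],
            "eff2": np.nan,
            "eff_cat1": eff_cat[sko_k, sko_j],
            "eff_cat2": "",
            "p1": p_gene[sko_k],
            "p2": np.nan,
            "p1_eff": p_gene[sko_k] * eff[sko_k, sko_j],
            "p2_eff": 0.0,
            "I": 0,
            "pi": 0.0,
            "fg": fg_sko.ravel(),
        }
    )

    # --- DKO rows (pair-major, then j1-major guide order) -------------
    im = interaction_map
    pair_k1 = im["k1"].to_numpy() - 1
    pair_k2 = im["k2"].to_numpy() - 1
    rk1 = np.repeat(pair_k1, ng * ng)
    rk2 = np.repeat(pair_k2, ng * ng)
    j1 = np.tile(np.repeat(np.arange(ng), ng), n_pairs)
    j2 = np.tile(np.tile(np.arange(ng), ng), n_pairs)
    p1_i = np.repeat(im["p1_I"].to_numpy(), ng * ng)
    p2_i = np.repeat(im["p2_I"].to_numpy(), ng * ng)
    e1 = eff[rk1, j1]
    e2 = eff[rk2, j2]
    dko = pd.DataFrame(
        {
            "kind": "DKO",
            "k1": rk1 + 1,
            "j1": j1 + 1,
            "k2": rk2 + 1,
            "j2": j2 + 1,
            "class1": cls[rk1],
            "class2": cls[rk2],
            "eff1": e1,
            "eff2": e2,
            "eff_cat1": eff_cat[rk1, j1],
            "eff_cat2": eff_cat[rk2, j2],
            "p1": np.repeat(im["p1"].to_numpy(), ng * ng),
            "p2": np.repeat(im["p2"].to_numpy(), ng * ng),
            "p1_eff": p1_i * e1,
            "p2_eff": p2_i * e2,
            "I": np.repeat(im["I"].to_numpy(), ng * ng),
            "pi": np.repeat(im["pi"].to_numpy(), ng * ng),
            "fg": fg_dko.ravel(),
        }
    )

    table = pd.concat([sko, dko], ignore_index=True)
    probs = dko_division_probs(table["p1_eff"].to_numpy(), table["p2_eff"].to_numpy())
    for i, col in enumerate(["p_div0", "p_div1", "p_div2", "p_div3"]):
        table[col] = probs[:, i]
    total = table["fg"].to_numpy().sum()
    table["f_rel0"] = table["fg"] / total
    L0 = config.library_size
    table["c0"] = np.rint(table["f_rel0"].to_numpy() * L0).astype(np.int64)
    table.insert(0, "construct_id", np.arange(len(table)))
    return table


def build_library(config: SimConfig, rng, override: pd.DataFrame | None = None):
    """Run the four initialization stages; returns (panel, interaction_map,
    efficacies, construct_table)."""
    panel = init_gene_panel(config, rng, override=override)
    imap = init_interaction_map(panel, config, rng)
    eff = init_guide_efficacies(config, rng)
    table = allocate_frequencies(panel, imap, eff, config, rng)
    return panel, imap, eff, table
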