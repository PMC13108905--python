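"""Seed-averaged benchmark measurements of simulated screens.

Convenience wrappers that run full screens under a given configuration for
several seeds and average the evaluation metrics — the building blocks for
profiling library designs (coverage, guide quality, dispersion, interaction
magnitude, doubling schedules).
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .scoring import (
    compute_dlfc,
    fraction_reads_top5,
    pearson_r,
    precision_recall_at_k,
    replicate_correlation,
)
from .simulate import simulate

__all__ = [
    "derive_seeds",
    "gi_recovery",
    "replicate_agreement",
    "read_concentration",
    "count_histogram_comparison",
]


def derive_seeds(root_seed: int, n: int) -> list[int]:
    """``n`` independent 31-bit seeds derived deterministically from one root."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def gi_recovery(config: SimConfig, seeds, n_replicates: int = 2) -> dict:
    """How well dLFC recovers the simulated interactions, averaged over seeds.

    Each seed runs a fresh library with ``n_replicates`` grown replicates and
    scores the replicate-mean LFC.  Returns mean Pearson r of dLFC against
    the true interaction values, and precision/recall of the 80 strongest
    negative dLFC calls against the strongest negative true interactions.
    """
    rs, precs, recs = [], [], []
    for seed in seeds:
        run = simulate(config, n_replicates=n_replicates, seed=seed)
        scores = compute_dlfc(run.result)
        rs.append(pearson_r(scores["dlfc"], scores["pi"]))
        p, r = precision_recall_at_k(scores)
        precs.append(p)
        recs.append(r)
    return {
        "pearson_r": float(np.mean(rs)),
        "precision_at_80": float(np.mean(precs)),
        "recall_at_80": float(np.mean(recs)),
        "n_pairs": len(scores),
        "n_seeds": len(list(seeds)),
    }


def replicate_agreement(config: SimConfig, seeds) -> dict:
    """Mean Pearson correlation of per-construct LFC between two replicates
    sharing one initialized library with independent growth noise."""
    rs = []
    for seed in seeds:
        run = simulate(config, n_replicates=2, seed=seed)
        rs.append(replicate_correlation(run.replicates[0], run.replicates[1], "lfc"))
    return {
        "pearson_r": float(np.mean(rs)),
        "n_constructs": config.n_constructs,
        "n_seeds": len(list(seeds)),
    }


def count_histogram_comparison(sim_counts, other_counts, bins: int = 30):
    """Shared-bin log10 count-density histograms of a simulated library
    against any external count vector (e.g. a published screen's t0 counts).

    Zero counts are dropped (log scale).  Returns a DataFrame with columns
    ``log10_count`` (bin centers), ``sim_density`` and ``other_density`` —
    ready for plotting or distribution-overlap summaries.
    """
    import pandas as pd

    a = np.log10(np.asarray(sim_counts, dtype=float)[np.asarray(sim_counts) > 0])
    b = np.log10(np.asarray(other_counts, dtype=float)[np.asarray(other_counts) > 0])
    if a.size == 0 or b.size == 0:
        raise ValueError("need positive counts on both sides")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi, bins + 1)
    da, _ = np.histogram(a, bins=edges, density=True)
    db, _ = np.histogram(b, bins=edges, density=True)
    return pd.DataFrame(
        {
            "log10_count": (edges[:-1] + edges[1:]) / 2,
            "sim_density": da,
            "other_density": db,
        }
    )


def read_concentration(config: SimConfig, seeds) -> dict:
    """Mean fraction of final reads held by the top 5% of constructs."""
    fracs, doublings = [], []
    for seed in seeds:
        run = simulate(config, n_replicates=1, seed=seed)
        fracs.append(fraction_reads_top5(run.replicates[0]["c2"].to_numpy()))
        doublings.append(run.outcomes[0].total_doublings)
    return {
        "top5_fraction": float(np.mean(fracs)),
        "total_doublings": doublings,
        "n_constructs": config.n_constructs,
        "n_seeds": len(list(seeds)),
    }
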