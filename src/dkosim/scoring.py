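"""Genetic-interaction scoring (dLFC, zdLFC) and evaluation metrics.

The GI score of a gene pair is the delta log fold change: the mean LFC of
the pair's double-knockout constructs minus the sum of the two single-mutant
fitnesses (each gene's mean single-knockout LFC).  Under additivity of the
single-knockout effects the dLFC is 0; negative dLFC flags synthetic-sick /
lethal pairs.  zdLFC is the z-standardized dLFC across all scored pairs.

Evaluation metrics compare scores against the simulator's ground-truth
interaction values: Pearson correlation, precision/recall of the strongest
negative calls, area under the precision-recall curve for negative
interactions, read concentration, and replicate agreement.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

__all__ = [
    "compute_dlfc",
    "pearson_r",
    "precision_recall_at_k",
    "aucpr_negative",
    "fraction_reads_top5",
    "replicate_correlation",
    "compute_metrics",
]


def compute_dlfc(result: pd.DataFrame) -> pd.DataFrame:
    """Gene-pair score table from a per-construct screen result.

    ``result`` needs columns ``kind`` (SKO/DKO), ``k1``, ``k2``, ``lfc``,
    ``pi`` and ``I``.  Single-mutant fitness (SMF) of a gene is the
    unweighted mean LFC over its SKO guides; the pair DKO LFC is the
    unweighted mean over its guide-pair constructs.  Returns one row per
    pair with dko_lfc, smf1, smf2, dlfc, zdlfc (sample-SD standardized),
    the true interaction pi and the interaction flag.
    """
    sko = result[result["kind"] == "SKO"]
    dko = result[result["kind"] == "DKO"]
    if sko.empty or dko.empty:
        raise ValueError("result must contain both SKO and DKO rows")
    smf = sko.groupby("k1")["lfc"].mean()
    pairs = (
        dko.groupby(["k1", "k2"])
        .agg(dko_lfc=("lfc", "mean"), pi=("pi", "first"), I=("I", "first"))
        .reset_index()
    )
    missing = set(pairs["k1"]).union(pairs["k2"]) - set(smf.index)
    if missing:
        raise ValueError(f"genes without SKO rows: {sorted(missing)}")
    pairs["smf1"] = smf.loc[pairs["k1"]].to_numpy()
    pairs["smf2"] = smf.loc[pairs["k2"]].to_numpy()
    pairs["dlfc"] = pairs["dko_lfc"] - pairs["smf1"] - pairs["smf2"]
    d = pairs["dlfc"].to_numpy()
    pairs["zdlfc"] = (d - d.mean()) / d.std(ddof=1)
    return pairs


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def precision_recall_at_k(
    scores: pd.DataFrame, k_pred: int = 80, k_truth: int = 100
) -> tuple[float, float]:
    """Precision and recall of the ``k_pred`` most-negative dLFC pairs
    against the ``k_truth`` most-negative true interactions.

    The truth set is the ``k_truth`` pairs with the most negative pi,
    restricted to pi < 0 (it can be smaller than ``k_truth`` when fewer
    truly negative pairs exist).  Ties are broken by stable pair order.
    Precision divides by ``k_pred`` and recall by ``k_truth``.
    """
    pi = scores["pi"].to_numpy()
    dlfc = scores["dlfc"].to_numpy()
    neg = np.flatnonzero(pi < 0)
    truth = set(neg[np.argsort(pi[neg], kind="stable")][:k_truth])
    if not truth:
        raise ValueError("no pairs with negative true interaction")
    pred = np.argsort(dlfc, kind="stable")[:k_pred]
    hits = sum(1 for i in pred if i in truth)
    return hits / k_pred, hits / k_truth


def aucpr_negative(scores: pd.DataFrame) -> float:
    """Area under the precision-recall curve for negative interactions,
    ranking pairs by increasing dLFC (positives are pairs with pi < 0);
    step-wise integration (average precision)."""
    labels = (scores["pi"].to_numpy() < 0).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need both negative-interaction and other pairs")
    return float(average_precision_score(labels, -scores["dlfc"].to_numpy()))


def fraction_reads_top5(counts) -> float:
    """Fraction of reads in the top 5% of constructs (m = ceil(0.05 * n),
    sorted by count descending)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("library is extinct: all construct counts are zero")
    m = math.ceil(0.05 * counts.size)
    top = np.sort(counts)[::-1][:m]
    return float(top.sum() / total)


def replicate_correlation(
    rep1: pd.DataFrame, rep2: pd.DataFrame, quantity: str = "lfc"
) -> float:
    """Pearson correlation of a per-construct quantity (``lfc`` or
    ``f_rel2``) between two replicates of the same library."""
    if quantity not in ("lfc", "f_rel2"):
        raise ValueError("quantity must be 'lfc' or 'f_rel2'")
    if len(rep1) != len(rep2) or not rep1["construct_id"].equals(rep2["construct_id"]):
        raise ValueError("replicates must share the same construct table")
    return pearson_r(rep1[quantity].to_numpy(), rep2[quantity].to_numpy())


def compute_metrics(run, k_pred: int = 80, k_truth: int = 100) -> dict:
    """All evaluation metrics of a :class:`~dkosim.simulate.SimulationRun`.

    Truth-dependent metrics are None when the run has no negative
    interactions (e.g. an interaction-free library)."""
    scores = compute_dlfc(run.result)
    has_negatives = bool((scores["pi"] < 0).any())
    if has_negatives:
        precision, recall = precision_recall_at_k(scores, k_pred=k_pred, k_truth=k_truth)
    else:
        precision = recall = None
    pi_sd = float(np.std(scores["pi"]))
    metrics = {
        "r_dlfc_vs_gi": pearson_r(scores["dlfc"], scores["pi"]) if pi_sd > 0 else None,
        "precision_at_80": precision,
        "recall_at_80": recall,
        "aucpr_negative": aucpr_negative(scores) if has_negatives else None,
        "top5_read_fraction": fraction_reads_top5(run.replicates[0]["c2"].to_numpy()),
        "total_doublings": run.outcomes[0].total_doublings,
    }
    if len(run.replicates) >= 2:
        metrics["replicate_lfc_r"] = replicate_correlation(
            run.replicates[0], run.replicates[1], "lfc"
        )
        metrics["replicate_freq_r"] = replicate_correlation(
            run.replicates[0], run.replicates[1], "f_rel2"
        )
    return metrics
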