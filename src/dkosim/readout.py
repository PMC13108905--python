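"""Count read-out: relative frequencies, log2 fold change, replicate means.

Reads equal cells in this model (no sequencing-depth resampling), so the
final count vector is read out directly.  The log2 fold change compares the
relative frequency of each construct between the final and initial time
points with a pseudocount on the frequency scale, which keeps the LFC
finite for constructs that drop out and centers control constructs at 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .dynamics import ScreenOutcome

__all__ = [
    "relative_frequencies",
    "compute_lfc",
    "aggregate_replicates",
    "build_screen_result",
    "resolve_pseudocount",
]


def relative_frequencies(counts) -> np.ndarray:
    """Counts normalized by the library size; sums to 1."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("library is extinct: all construct counts are zero")
    return counts / total


def compute_lfc(f_rel0, f_rel2, pseudocount: float) -> np.ndarray:
    """Per-construct log2((f_rel2 + pseudo) / (f_rel0 + pseudo)); finite
    everywhere for pseudocount > 0."""
    f_rel0 = np.asarray(f_rel0, dtype=float)
    f_rel2 = np.asarray(f_rel2, dtype=float)
    if f_rel0.shape != f_rel2.shape:
        raise ValueError("frequency vectors must have equal length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2((f_rel2 + pseudocount) / (f_rel0 + pseudocount))


def aggregate_replicates(lfc_per_replicate) -> np.ndarray:
    """Elementwise mean LFC across replicates."""
    lfcs = [np.asarray(x, dtype=float) for x in lfc_per_replicate]
    if not lfcs:
        raise ValueError("need at least one replicate")
    if len({x.shape for x in lfcs}) > 1:
        raise ValueError("replicate LFC vectors must have equal length")
    return np.mean(lfcs, axis=0)


def resolve_pseudocount(config: SimConfig, L0: int) -> float:
    """Configured pseudocount, defaulting to 1 / L0 (one cell's worth of
    relative frequency in the realized initial library)."""
    if config.pseudocount is not None:
        return config.pseudocount
    if L0 <= 0:
        raise ValueError("cannot derive pseudocount from an empty library")
    return 1.0 / L0


def build_screen_result(
    table: pd.DataFrame, outcome: ScreenOutcome, config: SimConfig
) -> pd.DataFrame:
    """Join one replicate's final counts onto the construct table and add
    relative frequencies and LFC columns."""
    result = table.copy()
    c0 = table["c0"].to_numpy(dtype=np.int64)
    result["c2"] = outcome.counts
    result["f_rel2"] = relative_frequencies(outcome.counts)
    pseudo = resolve_pseudocount(config, int(c0.sum()))
    result["lfc"] = compute_lfc(
        result["f_rel0"].to_numpy(), result["f_rel2"].to_numpy(), pseudo
    )
    return result
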