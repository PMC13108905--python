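"""Growth and bottleneck loop of the simulated screen.

Each doubling cycle every construct's cells divide independently according
to the construct's division-probability vector (a multinomial draw over 0,
1, 2 or 3 divisions).  Whenever the library exceeds ``n_b`` times its
initial size, a bottleneck fires: the library is downsampled without
replacement (multivariate hypergeometric) to the fraction of cells expected
to carry exactly one viral integration at the configured multiplicity of
infection.  The loop stops after ``n_e`` bottleneck encounters or at the
doubling-cycle cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "retention_count",
    "grow_one_cycle",
    "bottleneck_downsample",
    "run_screen",
    "ScreenOutcome",
]

_DESC_INT = np.array([0, 2, 4, 8], dtype=np.int64)


def retention_count(D: int, moi_lambda: float) -> int:
    """Cells retained at a bottleneck: the single-infection fraction of a
    Poisson(lambda) transduction, ``round(lambda * exp(-lambda) * D)``.
    At lambda = 0.3 this keeps about 22% of the current library."""
    if D < 0:
        raise ValueError("library size must be non-negative")
    return int(np.rint(moi_lambda * math.exp(-moi_lambda) * D))


def grow_one_cycle(counts: np.ndarray, div_matrix: np.ndarray, rng) -> np.ndarray:
    """One doubling cycle: per construct, multinomially split its cells over
    0/1/2/3 divisions and return the descendant counts (2, 4 or 8 per
    dividing cell).  Constructs with zero cells stay at zero."""
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    outcome = rng.multinomial(counts, div_matrix)
    return outcome @ _DESC_INT


# population size up to which the exact without-replacement sampler is used
_EXACT_HYPERGEOMETRIC_LIMIT = 10**9 - 1


def bottleneck_downsample(counts: np.ndarray, n_r: int, rng) -> np.ndarray:
    """Draw ``n_r`` cells without replacement from the library: a
    multivariate hypergeometric sample over constructs (colors).

    For library sizes beyond the exact sampler's integer range the draw
    falls back to independent binomial thinning of each construct at the
    retention fraction ``n_r / total`` — at such population sizes the
    between-construct dependence of without-replacement sampling is
    negligible, each construct still never gains cells, and the realized
    total differs from ``n_r`` only by sampling noise of relative order
    ``1/sqrt(n_r)``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if not 0 <= n_r <= total:
        raise ValueError(f"cannot retain {n_r} cells from a library of {total}")
    if total <= _EXACT_HYPERGEOMETRIC_LIMIT:
        return rng.multivariate_hypergeometric(counts, n_r, method="marginals")
    return rng.binomial(counts, n_r / total)


@dataclass
class ScreenOutcome:
    """Final state and trajectory log of one grown replicate."""

    counts: np.ndarray           # final per-construct cell counts C2
    total_doublings: int         # doubling cycles executed (t)
    n_bottlenecks: int           # bottleneck encounters (ie)
    log: pd.DataFrame            # per-cycle: t, ie, D, bottleneck fired, n_r
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())


def run_screen(
    table: pd.DataFrame,
    config: SimConfig,
    rng,
    record_snapshots: bool = False,
) -> ScreenOutcome:
    """Run the transfection/selection loop on an initialized construct table.

    Starting from the initial counts ``c0``, iterate while fewer than
    ``n_e`` bottlenecks have fired and fewer than ``max_doublings`` cycles
    have run: (a) if the library size exceeds ``n_b * L0`` (L0 the realized
    initial size, strict inequality), count a bottleneck and downsample to
    the MOI retention fraction of the current size; (b) grow one cycle;
    (c) advance the cycle counter.  A growth step always follows the
    bottleneck check within the same iteration, so the final bottleneck is
    itself followed by one doubling.

    With ``record_snapshots`` the count vector after every cycle is kept
    (keyed by t), which supports trajectory read-outs such as the read
    concentration across doublings.
    """
    counts = table["c0"].to_numpy(dtype=np.int64).copy()
    div_matrix = table[["p_div0", "p_div1", "p_div2", "p_div3"]].to_numpy()
    L0 = int(counts.sum())
    threshold = config.n_b * L0
    t, ie = 0, 0
    rows = []
    snapshots: dict[int, np.ndarray] = {0: counts.copy()} if record_snapshots else {}

    while ie < config.n_e and t < config.max_doublings:
        D = int(counts.sum())
        fired = D > threshold
        n_r = None
        if fired:
            ie += 1
            n_r = retention_count(D, config.moi_lambda)
            counts = bottleneck_downsample(counts, n_r, rng)
        counts = grow_one_cycle(counts, div_matrix, rng)
        t += 1
        rows.append({"t": t, "ie": ie, "D_before": D, "bottleneck": fired,
                     "n_r": n_r if fired else 0})
        if record_snapshots:
            snapshots[t] = counts.copy()

    log = pd.DataFrame(rows, columns=["t", "ie", "D_before", "bottleneck", "n_r"])
    return ScreenOutcome(
        counts=counts, total_doublings=t, n_bottlenecks=ie, log=log, snapshots=snapshots
    )
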