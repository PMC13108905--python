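"""Tunable-parameter set of the simulator, with validation and (de)serialization.

``SimConfig`` holds every knob of the simulation: library design (number of
genes ``n``, guides per gene, coverage), gene-class mixture and phenotype
distributions, guide-efficacy model, initial-count dispersion, genetic
interaction prevalence and magnitude, and the growth/bottleneck schedule.
Defaults correspond to the systematic baseline screen (120 genes, 3 guides
per gene, 100x coverage, 3% interacting pairs, 100%-efficacy mode, one
bottleneck at twice the initial library size).

Configs are read from YAML or JSON files whose keys match the field names;
percentage-style fields accept either fractions (0.03) or percent values
(3), normalized internally to fractions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "GENE_CLASSES",
    "load_config",
    "sigma_f_from_confidence",
]

#: gene classes, in the order class counts are reported
GENE_CLASSES = ("negative", "positive", "wild_type", "control", "unknown")

MODES = ("CRISPRn", "CRISPRn-100%Eff")

# fields holding a fraction that users may also write as a percentage
_PCT_FIELDS = ("pct_gi", "pct_neg", "pct_pos", "pct_wt", "pct_ctrl", "pct_unknown", "pct_heg")


@dataclass
class SimConfig:
    """Full tunable-parameter set of one simulated screen."""

    # library design
    n: int = 120                 # number of unique genes
    coverage: int = 100          # cells per construct in the initial library
    n_guides: int = 3            # guides per gene

    # genetic interactions
    pct_gi: float = 0.03         # fraction of eligible DKO pairs flagged interacting
    sigma_gi: float = 1.5        # SD of the interaction jiggle of phenotypes

    # gene-class mixture (fractions summing to 1)
    pct_neg: float = 0.15
    pct_pos: float = 0.05
    pct_wt: float = 0.75
    pct_ctrl: float = 0.05
    pct_unknown: float = 0.0

    # phenotype distributions (normal, truncated to the class support)
    mu_neg: float = -0.75
    sigma_neg: float = 0.1
    mu_pos: float = 0.75
    sigma_pos: float = 0.1
    sigma_wt: float = 0.25
    sigma_unknown: float = 0.25

    # initial-frequency dispersion: log10 f0' ~ N(0, sigma_f^2)
    sigma_f: float = 1 / 3.29

    # guide efficacy
    pct_heg: float = 1.0         # fraction of high-efficacy guides
    mu_high: float = 0.9
    sigma_high: float = 0.1
    mu_low: float = 0.05
    sigma_low: float = 0.07
    mode: str = "CRISPRn-100%Eff"

    # growth / bottleneck schedule
    n_b: int = 2                 # bottleneck threshold, as a multiple of L0
    n_e: int = 1                 # number of bottleneck encounters before stopping
    moi_lambda: float = 0.3      # multiplicity of infection for bottleneck retention
    max_doublings: int = 30      # hard cap on doubling cycles

    # readout / allocation
    pseudocount: float | None = None   # None -> 1 / L0, resolved at readout time
    dirichlet_alpha: float = 100.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if v is not None and v > 1:
                setattr(self, name, v / 100.0)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_guides < 1 or self.coverage < 1:
            raise ValueError("n_guides and coverage must be >= 1")
        if self.n_b < 1 or self.n_e < 0:
            raise ValueError("n_b must be >= 1 and n_e >= 0")
        if not (0 <= self.pct_gi <= 1) or not (0 <= self.pct_heg <= 1):
            raise ValueError("pct_gi and pct_heg must lie in [0, 1]")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.moi_lambda <= 0:
            raise ValueError("moi_lambda must be positive")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive (or None for 1/L0)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        total = self.pct_neg + self.pct_pos + self.pct_wt + self.pct_ctrl + self.pct_unknown
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene-class fractions must sum to 1, got {total}")
        for s in (self.sigma_neg, self.sigma_pos, self.sigma_wt, self.sigma_unknown,
                  self.sigma_gi, self.sigma_high, self.sigma_low):
            if s < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.max_doublings < 0:
            raise ValueError("max_doublings must be >= 0")

    # ------------------------------------------------------------------ #
    @property
    def class_fractions(self) -> dict[str, float]:
        return {
            "negative": self.pct_neg,
            "positive": self.pct_pos,
            "wild_type": self.pct_wt,
            "control": self.pct_ctrl,
            "unknown": self.pct_unknown,
        }

    def class_counts(self) -> dict[str, int]:
        """Integer genes per class: round(fraction * n) per non-wild-type
        class (round-half-to-even), remainder assigned to wild type."""
        counts: dict[str, int] = {}
        for cls in ("negative", "positive", "control", "unknown"):
            frac = self.class_fractions[cls]
            c = int(np.rint(frac * self.n))
            if frac > 0 and c == 0:
                raise ValueError(
                    f"n={self.n} too small to realize nonzero {cls} fraction {frac}"
                )
            counts[cls] = c
        wt = self.n - sum(counts.values())
        if wt < 0:
            raise ValueError("class fractions cannot be realized: counts exceed n")
        if self.pct_wt > 0 and wt == 0:
            raise ValueError("n too small to realize nonzero wild-type fraction")
        counts["wild_type"] = wt
        return counts

    @property
    def n_constructs(self) -> int:
        """n * n_g single-knockout plus C(n,2) * n_g^2 double-knockout rows."""
        return self.n * self.n_guides + (self.n * (self.n - 1) // 2) * self.n_guides**2

    @property
    def library_size(self) -> int:
        """Requested initial library size L0 = coverage x number of constructs."""
        return self.coverage * self.n_constructs

    # ------------------------------------------------------------------ #
    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> SimConfig:
    """Read a YAML or JSON config file; unset fields take baseline defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return SimConfig.from_dict(data)


def sigma_f_from_confidence(conf: float) -> float:
    """Initial-count dispersion sigma_f from a two-sided confidence level.

    ``sigma_f = 1 / (2 * z)`` with ``z`` the standard-normal quantile at
    ``(1 + conf) / 2``.  At 90% confidence z = 1.645, giving sigma_f = 1/3.29
    and a 10-fold gap between the 95th and 5th percentiles of the log10-normal
    initial frequency distribution.
    """
    if not 0 < conf < 1:
        raise ValueError("confidence level must lie strictly between 0 and 1")
    z = norm.ppf((1 + conf) / 2)
    return 1.0 / (2.0 * z)
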