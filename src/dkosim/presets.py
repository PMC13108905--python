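"""Named parameterizations: the systematic baseline and the three
published-screen mimicking designs.

Mimicking presets encode only the design values those screens print (gene
panel size, guides per gene, interaction prevalence, initial-count
dispersion confidence, coverage); everything else inherits the baseline.
"""

from __future__ import annotations

from .config import SimConfig, sigma_f_from_confidence

__all__ = ["preset", "PRESETS"]


def _baseline() -> SimConfig:
    return SimConfig()


def _mimic_shen() -> SimConfig:
    # 120 genes, 3 guides/gene, 3% GIs, 80%-confidence count dispersion
    return SimConfig(n=120, n_guides=3, pct_gi=0.03, sigma_f=1 / 2.56)


def _mimic_doench() -> SimConfig:
    # 28 genes, 5 guides/gene, 3% GIs, 90%-confidence count dispersion
    return SimConfig(n=28, n_guides=5, pct_gi=0.03, sigma_f=1 / 3.29)


def _mimic_fong() -> SimConfig:
    # 246 genes: 64 essential (negative), 178 unknown, 4 non-targeting
    # controls; 3 guides/gene, 1000x coverage, moi 0.3, one bottleneck
    # (3 total doublings), two replicates at run time
    return SimConfig(
        n=246,
        n_guides=3,
        coverage=1000,
        pct_gi=0.03,
        pct_neg=64 / 246,
        pct_pos=0.0,
        pct_wt=0.0,
        pct_ctrl=4 / 246,
        pct_unknown=178 / 246,
        sigma_f=1 / 2.56,
        moi_lambda=0.3,
        n_b=2,
        n_e=1,
    )


PRESETS = {
    "baseline": _baseline,
    "mimic_shen": _mimic_shen,
    "mimic_doench": _mimic_doench,
    "mimic_fong": _mimic_fong,
}


def preset(name: str) -> SimConfig:
    """Return a fresh config for a named preset."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
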