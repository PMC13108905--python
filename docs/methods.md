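# Methods

## Growth model

The unit of simulated time is one wild-type population doubling cycle. A
cell whose knocked-out gene has theoretical phenotype p ∈ [−1, 1] divides
x ∈ {0, 1, 2} times in one cycle with probabilities ((−p)₊, 1 − |p|, (p)₊):
p = 0 is exact wild-type behavior (one division, deterministically), p < 0
adds a death outcome, p > 0 adds a double-division outcome. "Does not
divide but stays viable" is deliberately not an outcome; this keeps the
discrete model consistent with exponential growth. For a double knockout
the per-gene division counts are independent and combine as
y = 1(x₁x₂ ≠ 0)(x₁ + x₂ − 1), so death by either knockout kills the cell
and a non-targeting partner (p ≡ 0, x ≡ 1) leaves the other gene's
distribution unchanged. A cell leaves 1(y ≠ 0)·2ʸ ∈ {0, 2, 4, 8}
descendants; expected descendants factorize as 2(1 + p₁)(1 + p₂), which the
test suite uses as an independent closed-form oracle.

The ground-truth interaction of a pair is
π = E[C_y | perturbed] − E[C_y | base], where the perturbed phenotypes of an
interacting pair are re-drawn from N(pᵢ, σ²_GI) truncated to [−1, 1].
π is a gene-level quantity: guide efficacy never enters it. Phenotypes at
exactly ±1 are legal boundary inputs (probabilities hit 0/1 exactly); no
epsilon clipping is applied.

## Library initialization

Classes are assigned by a seeded shuffle with round(fraction·n) genes per
non-wild-type class (round half to even, as everywhere in the package) and
the remainder wild type. Class phenotype supports: negative [−1, −0.025],
positive [0.025, 1], wild type [−0.025, 0.025], optional unknown
[−0.5, 0.5] (default SD 0.25, used by the lab-mimicking presets), controls
exactly 0. Truncated normals are sampled by inverse CDF on the truncated
range — exact and platform-reproducible, not clip-after-draw or rejection.

Interaction flags: exactly round(pct_gi · #eligible) pairs drawn uniformly
from the pairs without a control gene. The perturbed phenotypes are drawn
per *pair*, so a gene can carry different perturbed values in different
pairs. SKO constructs always use base phenotypes — the perturbation is a
pair-level concept.

Frequencies: gene seeds satisfy log₁₀ f₀′ ~ N(0, σ_f²); σ_f = 1/3.29 by
default so the 95th/5th percentile ratio of initial SKO frequencies is
10-fold (`sigma_f_from_confidence` maps a two-sided confidence level to
σ_f = 1/(2z)). Pair seeds are the mean of the two gene seeds. Within a gene
the n_g guide frequencies split the gene seed by a symmetric
Dirichlet(α = 100); within a pair the n_g² guide pairs split (pair seed)·n_g,
which makes the mean SKO guide frequency equal the mean DKO guide-pair
frequency for every pair — an identity the tests check exactly. Initial
counts are round(f_rel·L0) with L0 = coverage × constructs; counts of 0 are
allowed (dropout at low coverage is a real phenomenon the simulator must
show), so no floor of 1 is applied.

Guide efficacy: exactly round(pct_heg·n·n_g) guides are high-efficacy.
CRISPRn mode draws high efficacies from N(0.9, 0.1²) on [0.6, 1] and low
from N(0.05, 0.07²) on [0, 0.6]; the disjoint supports guarantee every high
guide outperforms every low guide. CRISPRn-100%Eff sets all efficacies
to 1. Effective phenotypes are p·Eff.

## Population dynamics

Each cycle, every construct's cells divide by a multinomial draw over its
division-probability vector. The loop runs while fewer than n_e bottlenecks
have fired and fewer than max_doublings (default 30) cycles have run. The
order inside an iteration is: bottleneck check (strictly D > n_b·L0, with
L0 the *realized* initial library size), then growth, then the cycle
counter — the only ordering that executes exactly 3 total doublings under
the default schedule (n_b = 2, n_e = 1), as the tests verify. The retention
at a bottleneck is recomputed from the current library size:
n_r = round(λe^(−λ)·D), the expected single-infection fraction of a
Poisson(λ) transduction (≈22% at the default λ = 0.3); multiple infections
are not modeled.

Bottleneck downsampling is an exact multivariate hypergeometric draw
(sequential-conditional algorithm via numpy). Beyond numpy's 10⁹-cell
integer range — reachable only in long schedules where fast-growing
constructs dominate and net growth outruns the bottleneck — the draw falls
back to per-construct binomial thinning at the retention fraction; at such
population sizes the between-construct dependence of without-replacement
sampling is far below sampling noise, and each construct still never gains
cells.

## Readout and scoring

Relative frequencies at t0 come from the exact Dirichlet frequencies
(pre-rounding) and at t2 from final counts. LFC = log₂((f₂ + C_pseudo) /
(f₀ + C_pseudo)). The pseudocount defaults to 1/L0 — one cell's worth of
relative frequency — keeping LFC finite for dropouts and centered at 0 for
constructs that keep pace with the library. A sensitivity scan showed this
default is not a knife edge in the direction of smaller values but that
frequency-scale pseudocounts of the order of the mean construct frequency
(1/n_constructs) collapse the dynamic range of depleted constructs and
destroy negative-GI ranking; 1/L0 is both the principled and the robust
choice. It is configurable.

Replicates share one initialized library (same panel, interactions,
efficacies and initial counts — one seed stream) and grow with independent
RNG streams; replicate LFCs are aggregated by elementwise mean before
scoring, matching the two-replicate design of the screens the simulator
emulates.

dLFC of a pair is the unweighted mean LFC of its guide-pair constructs
minus the two single-mutant fitnesses (each gene's unweighted mean SKO
LFC); zdLFC standardizes with the sample (n−1) SD. Precision/recall@80
compares the 80 most-negative dLFC pairs against the (at most) 100
most-negative pairs with π < 0. Under the default 3%-interaction baseline
the number of strictly negative-π pairs fluctuates around ~98, so the truth
set is simply all negative pairs when fewer than 100 exist; the recall
denominator stays 100. Ties in any top-k selection break by stable pair
order. Control-containing pairs are scored (they are natural nulls with
π = 0) but can never enter the truth set. AUC-PR uses step-wise
(average-precision) integration with positives = pairs with π < 0, ranked
by increasing dLFC. The top-5% read fraction is computed over constructs,
with the 5% count rounded up.

## Default parameterization and problem sizes

The defaults describe the systematic baseline screen: n = 120 genes
(15% negative N(−0.75, 0.1²), 5% positive N(0.75, 0.1²), 75% wild type
(SD 0.25), 5% controls), 3 guides per gene, 100x coverage, 3% interacting
pairs with σ_GI = 1.5, σ_f = 1/3.29, all-efficient guides, n_b = 2,
n_e = 1, λ = 0.3 — 64,620 constructs and ≈6.5M cells, one bottleneck,
3 doublings. A full baseline screen simulates in well under a second, so
the benchmark reproductions average each condition over five seeds with
two replicates each. The 19-doubling read-concentration condition is run
with n_e = 19 and the doubling cap at 19: once fast-growing constructs
dominate, the bottleneck cadence under n_b = 2 is emergent and the cycle
cap is the clean way to pin the doubling count.

Lab-mimicking presets (`mimic_shen`, `mimic_doench`, `mimic_fong`) encode
only the published design values (panel size, guides per gene, interaction
prevalence, dispersion confidence, coverage, class composition) and inherit
baseline defaults otherwise.

## What the generator does and does not emulate

Synthetic screens here have reads equal to cells (no sequencing-depth
resampling), no off-target effects, no guide-sequence model, equal-interval
division times, and strictly zero-phenotype controls (real non-targeting
controls show residual variability). Passing benchmarks therefore
demonstrates correct recovery of growth-encoded interactions under
sampling, bottleneck and efficacy noise — not robustness to off-target
activity or sequencing artifacts.

## Known limitations

- dLFC compares a log-scale score to a linear-scale truth (π), so even a
  noise-free screen has Pearson r < 1 against π (≈0.77 asymptotically at
  the baseline interaction magnitude).
- Depleted constructs censor at the LFC floor set by the pseudocount; at
  low coverage this biases dLFC of pairs containing strongly negative
  genes and is the dominant error mode for precision@80 at 100x.
- Long doubling schedules let positive-interaction constructs outgrow the
  bottleneck, inflating the population; beyond 10⁹ cells downsampling
  switches to the binomial approximation described above.
- Replicates model independent growth of a shared library; independent
  re-transduction (fresh initial counts per replicate) is not modeled.
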