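# Methods

This note documents the models and procedures implemented in `chromofold`,
their assumptions, the parameters that matter, and the numerical and
design choices made where the design was genuinely open.

## Polymer representation and energy function

A chromatin segment is represented as beads on a string: one bead per 5 kb
of sequence, diameter 30 nm. All computations use reduced units — length
in units of 30 nm, energy in units of k<sub>B</sub>T, unit bead mass. The
potential has three parts.

**Generic polymer `U(r)`.** Connectivity and excluded volume:

- Harmonic bonds `k_b (r − r_0)²` with `k_b = 20`, rest length `r_0 = 1.0`
  (one bead diameter). A 60 nm segment length can be selected by setting
  `bond_r0 = 2.0` if the user prefers the alternative bead geometry.
- Soft-core repulsion `ε_ev (1 − (r/σ_ev)²)²` for `r < σ_ev`, with
  `ε_ev = 10`, `σ_ev = 1.0`. The potential is finite (ε_ev) at full
  overlap, so the chain can cross itself — deliberate, and standard in
  effective-equilibrium chromatin models, because topological hindrance is
  not part of the effective energy landscape being learned.
- Spherical confinement: a half-harmonic wall `k_c (ρ − R)²` outside
  radius R, with `k_c = 20` and R set so the bead volume fraction is 0.1
  by default (`R = 0.5 (N/φ)^{1/3}`).

All of these constants are configuration fields on `EnergyParameters`.

**Chromatin-state term `U_CS`.** Every bead pair (i, j) with
`|j − i| ≥ 2` interacts through `α^{IJ}(b) f(r_ij)` where I, J are the
beads' chromatin states and b is the separation bin. The default binning
is 15 log-spaced bins spanning separations 2–2000 beads (10 kb–10 Mb);
pairs beyond the last edge use the last bin. On top of the state-pair
term, a homogeneous "ideal-chain" energy `α_ideal(s)` applies to every
pair at separations s = 2..81 regardless of state, absorbing the strong
state-independent distance dependence at short range. With 15 states this
yields 120 unordered state pairs × 15 bins + 80 ideal energies + 3 CTCF
energies = **1883 adjustable parameters**, matching the published total.
The exact bin-edge placement and the 1800 + 80 + 3 decomposition are a
reconstruction: the published account gives the total and the ingredients
but not the edges, so the binning is exposed as configuration.

**CTCF term `U_CTCF`.** Anchors are convergent CTCF pairs: a forward
(5'–3') flagged bead before a reverse (3'–5') flagged bead with at most 4
intervening forward-oriented beads *and* at most 4 reverse-oriented beads
(finite cohesin processivity). Beads with dual orientation are eligible
as either anchor and count toward both tallies — the permissive,
deterministic reading. Every pair (k, l) inside an eligible span [K, L]
receives `α_CC` (the anchor pair itself), `α_CCh` (exactly one of k, l is
CTCF-flagged) or `α_ChCh` (otherwise) times f(r). Nested and overlapping
spans contribute independently (the energy is a plain double sum).

**Contact indicator.** `f(r) = ½[1 + tanh(σ(r_c − r))]` for `r ≤ r_c`,
`½ (r_c/r)⁴` beyond, with `r_c = 1.76`, `σ = 3.72`. Both branches equal ½
at `r_c`; the derivative at exactly `r = r_c` uses the short-range branch
(a measure-zero convention fixed for reproducibility). The r⁻⁴ tail makes
f integrable against the distance–probability power law seen in imaging
data.

## Langevin sampling

The Boltzmann ensemble of `U_chrom` is sampled with the BAOAB splitting of
Langevin dynamics (timestep 0.01, friction 0.5, k_BT = 1 by default),
chosen for its configurational sampling accuracy per step among standard
schemes. Initial configurations are self-avoiding random walks inside the
confinement sphere. Random streams are Philox counter-based generators
keyed by (seed, run index), so multi-run ensembles are reproducible
regardless of scheduling; identical seed and configuration give
bit-identical trajectories.

For force evaluation the infinite-range α·f terms are truncated at
`r_cut = 5.0` reduced units (where f < 0.1% of f(0)) and shifted to zero.
An optional neighbor-list path (k-d tree, rebuilt every few steps)
evaluates the same truncated terms over a candidate pair list; because
the per-pair loop runs in lexicographic order and out-of-range pairs
contribute exact zeros, the neighbor-list and dense paths produce
bit-identical trajectories whenever the list cutoff covers the truncation
radius plus the skin — asserted in the test suite.

Ensemble contact maps are `P_ij = ⟨f(r_ij)⟩` over saved frames (untruncated
f), so `P ∈ (0, f(0)]` with `P_ii = f(0) ≈ 1`.

## Maximum-entropy parameterization

Each adjustable energy has exactly one constraint class: the set of bead
pairs it multiplies (a state pair at one separation bin; all pairs at one
ideal separation; the three CTCF contact classes over loop spans). The
bijection between classes and parameters is asserted at construction.
Training alternates sampling with the gradient step
`α_c ← α_c + η (⟨f⟩_sim,c − ⟨f⟩_target,c)`: over-represented contacts
become more repulsive. Empty classes are frozen; target probabilities
above f(0) — unreachable by the contact model — are clipped with a
warning. Each round restarts from the previous round's last frame to
amortize equilibration. If a round diverges, η is halved and the round
retried a bounded number of times. The learning rate has no momentum or
schedule beyond this halving; η = 0.5 is robust at toy scale.

**Self-consistency experiment** (`recovery_experiment`): a fixed 60-bead,
3-state toy with block states, one convergent CTCF pair (beads 5–50) and
planted energies (within-state attraction −0.5 weakening with separation
bin, +0.3 cross-class repulsion, CTCF triple −1.0/−0.2/−0.05). The
"experimental" target map comes from a 2×10⁵-step simulation of the
planted model. Training runs from zero energies in two phases: 20 short
rounds (1.2×10⁴ steps, η = 1.0) to approach the optimum through sampling
noise, then up to 8 long rounds (1.2×10⁵ steps, η = 0.5) whose class
averages are accurate enough for a meaningful residual; the per-class
residual noise floor scales with the inverse square root of the sampled
frames, which motivates the two-phase schedule. The toy deliberately
omits the ideal-separation term: at a fixed separation the ideal class
and the state-pair classes cover the same pairs, creating a gauge freedom
(a constant can shift between them without changing the energy of any
configuration) that would make parameter-recovery correlations
ill-defined. The full default model keeps the ideal term — the published
parameter count requires it — and inherits that gauge freedom, which is
harmless for prediction because only the sums enter the energy.

## Chromatin-state inference

States are inferred with a multivariate hidden Markov model: hidden chain
over 15 states (configurable), independent Bernoulli emission per
histone mark. Fitting is Baum–Welch EM with log-space forward–backward
(10⁵-bin sequences underflow otherwise); the log-likelihood is asserted
non-decreasing every iteration. Emissions initialize uniform in
[0.2, 0.8] from the seed and transitions near-diagonal (0.9
self-transition) — reproducible, and avoids the symmetric saddle point of
a uniform start. Several sequences (e.g. different cell types) can be
fitted jointly with shared parameters so a single state alphabet is
learned. Decoding maximizes the per-bin posterior; ties break toward the
lowest state index. Real-valued tracks can be binarized against a Poisson
background (threshold p < 1e-4 at the track mean) as a documented
pre-step — the published method assumes binarized input.

CTCF sites: a CTCF peak center is loop-forming when a Rad21 center lies
within 50 bp (inclusive). Orientation comes from the nearest motif within
100 bp when available, else from the nearest Rad21 center (downstream →
forward, upstream → reverse). Equidistant ties resolve downstream — the
published account is silent and the choice must be deterministic. Peak
centers are floored midpoints of 0-based half-open BED intervals. Sites
are binned onto 5 kb beads; unanimous beads take the shared orientation,
mixed beads take dual orientation.

## Contact-map metrics

- **Probability conversion**: balanced counts divided by the short-range
  diagonal level `C_ii` (1035 for the reference genome-wide 5 kb dataset;
  estimated from the data diagonal when absent), capped at 1.
- **PCC** over unmasked off-diagonal upper-triangle entries, globally or
  per separation stratum.
- **SCC**: 2D mean-filter smoothing (half-width h = 2 bins, exposed
  because the score is sensitive to it), per-stratum Pearson combined
  with weights `N_s · sqrt(var_s(a) var_s(b))`. The exact
  variance-stabilised rank weighting of the original stratum-adjusted
  method lives in its supplement; this size-and-spread weighting is the
  documented reconstruction.
- **Insulation**: mean contact in a 500 kb × 500 kb square sliding along
  the diagonal (`score(b)` = mean over `[b−w, b) × [b, b+w)`); the first
  and last w bins are masked. TAD boundaries are prominence-filtered
  local minima, plateau ties reporting the left-most bin.
- **Matching score**: greedy one-to-one matching in rank order; default
  boundary tolerance 10 bins (50 kb), exposed.
- **Contact enhancement**: P_ij over the mean of the 11×11 background
  window centered on (i, j), center excluded, clipped at edges (the
  published background geometry is in an unavailable supplement; this is
  the reconstruction). Significance thresholds come from random pairs
  with separations resampled from the reference pairs' multiset (90th
  percentile by default). The default "significant pair" extraction is
  top-N by probability at separations ≥ 2 bins; externally ranked lists
  (e.g. from dedicated Hi-C significance callers) are accepted in the
  same form.
- **Eigen-analysis**: symmetric eigendecomposition of log(P + pseudocount)
  (pseudocount = smallest positive entry by default), vectors ordered by
  |λ|, rank-k reconstruction, |PCC| comparison after sign alignment.
- **Interaction-matrix inspection**: per-separation 15×15 α matrices
  (mean-subtracted for display), average-linkage clustering of rows,
  leading eigenvectors, pairwise PCC across separations, and the spectral
  complexity `Σ_{top n}|λ| / Σ|λ|`.

Masked bins (failed normalization) propagate by exclusion: windows and
strata drop masked bins, never whole windows.

## Ensemble structure metrics

Radius of gyration and power-law fits are least squares on log–log axes.
Loop end-to-end distributions are reported in nm (reduced × 30 exactly).
Diffusion maps embed sampled frames: the distance between frames is the
mean *absolute* difference of their instantaneous contact maps ("mean
difference" alone would cancel to near zero; mean absolute difference is
the metric-valid reading, with squared difference exposed as an option);
kernel `K_ij = exp(−d_ij²/(ε_i ε_j))` with self-tuned local scales ε_i =
median distance to the 10 nearest neighbors (the cited self-tuning
estimator is reconstructed as k-NN median; k exposed); α = 1 density
normalization then Markov row normalization; eigenvectors via the
symmetric conjugate for stability. The trivial constant mode is dropped
by index after sorting, with a warning if it deviates from constant
(which signals a disconnected kernel). At most 2000 frames enter the
dense eigenproblem (stride subsampling). Free-energy surfaces are
−ln(histogram density), global minimum shifted to exactly 0, empty bins
+∞.

## Synthetic data

Fixtures are pure functions of spec + seed. The toy Hi-C generator
composes `P_ij = base · s^(−γ)` (γ = 1, the typical decay regime) with a
planted-TAD block factor, a compartment checkerboard over state classes,
Gaussian loop peaks at planted anchors, and multiplicative log-normal
noise, clipped to (0, 1]. The default alphabet maps 3 state classes onto
the 15-state alphabet (5 states per class), mirroring the
active/repressive partition while keeping the full state machinery
exercised. What these fixtures deliberately do **not** emulate: realistic
mark co-occurrence structure, Hi-C noise spectra (ligation artifacts,
coverage bias), or unbalanced count statistics — so passing tests
demonstrate correctness of the algorithms on planted truth, not
end-to-end accuracy on real genomes.

## Problem sizes and test scale

The published workflow runs 8 × 4×10⁷ Langevin steps on ~4000-bead
systems; that scale is available through the `production` preset but the
package's own experiments use desk-scale systems chosen to give stable
statistics on one CPU: ≤ 500-bin synthetic maps, 60-bead recovery
experiments, 10⁵-step sampler checks, 100-frame diffusion maps. Headline
numbers tied to genome-scale data (map correlations against experimental
Hi-C, loop false-negative rates, per-chromatin-type scaling exponents)
require those full-scale inputs and are out of scope here; the structural
parameter count (1883) is the one data-free published quantity the
package reproduces directly.

## Known limitations

- No cohesin-extrusion kinetics: the CTCF term is an effective static
  surrogate, so loop dynamics are equilibrium fluctuations.
- No topology enforcement (soft cores permit chain crossing).
- KR balancing itself is not implemented — only application of a provided
  normalization vector; balancing belongs to standard Hi-C tooling.
- Maximum-entropy training at genome scale needs cluster resources; the
  implementation is correct but not performance-tuned beyond the numba
  pair kernel.
- The ideal-term/state-pair gauge freedom means individual α values are
  identified only up to per-separation constants when both terms are
  active; constraints and predictions are unaffected.
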