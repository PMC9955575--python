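# Methods

## Model

A tissue is a population of `N = nx·ny·nz` identical cells on a 3D lattice
of cubic voxels (side `H`, volume `Vc = H³`), periodic on all three axes so
every cell has the same neighborhood structure.  Cells are static: no
division, death or migration.  Each cell is a Boolean network over
`n_reg + 2` binary nodes — `n_reg` regulatory nodes, one signal node and one
receptor node.  Regulatory nodes and the signal node update via k-input
truth tables; the receptor thresholds the local concentration of a single
diffusible molecule.  The signal node is never wired as an input of any
other node, keeping secretion separate from internal regulation (a
self-loop on the signal node itself is the one sanctioned exception,
used by the constant-signal probe cell).

Random networks follow the classic NK construction: each updatable node
draws k **distinct** inputs uniformly from the regulatory nodes plus the
receptor, and each truth-table bit is 1 with probability `p`.  Distinct
inputs is a modeling choice (sampling with replacement is equally
defensible); it fixes the probability that a network ignores its receptor
entirely at `[C(n_reg, k)/C(n_reg+1, k)]^(n_reg+1)` ≈ 3.0% for the default
10-regulatory-node, k=3 networks, and the test suite checks that closed
form.  Truth-table rows are indexed by reading the input tuple as a
big-endian binary integer (first wired input = most significant bit); this
convention is arbitrary but must be fixed for reproducible network files.

Criticality: the bias is the smaller root of the sensitivity condition
`2kp(1−p) = 1`, i.e. `p = (1 − sqrt(1 − 2/k))/2`; for k=3, `p ≈ 0.2113`.
The criticality statement applies to the closed (non-communicating) cell;
coupling through the field can shift the effective regime.

## Signal field

Secretion is `η₀` (signal OFF) or `αη₀` (signal ON), α > 1.  Diffusion is
assumed fast relative to regulation, so the field is the steady state of
the diffusion–degradation equation: `(γ − DΔ_h)C = η/Vc` with the 7-point
discrete Laplacian `Δ_h` at spacing `H`.  Under periodic boundaries the FFT
diagonalizes `Δ_h`, so the solve is exact for the discrete operator (no
iterative tolerance); the Fourier symbol `γ − D·eig` is bounded below by
`γ > 0`, so the problem is always well posed.  Exact identities —
linearity, positivity/monotonicity of the Green's function, and the
conservation law `Vc·γ·ΣC = Ση` — are asserted in tests against a sparse
direct solve of the same operator.

**Units and calibration.**  Only λ and θ are varied; everything else is
fixed: `H = 20`, `R = H/2 = 10` (cell inscribed in its voxel), `α = 5`,
`η₀ = 1`, and `D = R²/Vc = 0.0125` in model units.  λ is realized by
varying the degradation rate, `γ = D/(λR)²`, at fixed D.  This calibration
makes the uniform basal concentration `C00(λ) = η₀λ²`, so thresholds of
order 1–200 straddle the basal-to-active range over λ ∈ [0.3, 6] — but the
absolute θ scale is a calibration artifact, which is why every structural
result (region counts, curve ordering, sweep placement) is expressed
relative to the computed curves, never to absolute θ values.

## Regions

The two-node probe (constant signal + receptor) measures the receptor
response after one step under the four extreme configurations of (own,
all-others') signal.  By linearity only one Green's-function solve per λ is
needed: `C00 = η₀/(γVc)`, `C11 = αC00`, `C10 = C00 + (α−1)η₀G(0)`,
`C01 = C00 + C11 − C10`.  Thresholding these four values yields exactly six
admissible (monotone) response vectors, hence six regions; the bands
ordered in θ at fixed λ are A1, S1, (A2 or S2), S3, A3.  The middle band is
A2 (self-talk) when the self contribution `G(0)` exceeds half the total
Green's-function mass `1/(γVc)` and S2 (neighbor-dominant) otherwise; the
crossover λ\* is found by Brent's method on the scale-free difference
`(C10 − C01)/C00` (≈ 0.858 on the default 16³ lattice).  The classification
by curves is required (and tested) to agree exactly with literal one-step
tissue simulation of the four initial conditions — both threshold the same
discrete field.

Inside each asocial region the receptor rule is *exactly* configuration-
independent, not just at the extremes: in A1, every reachable concentration
is ≥ C00 > θ; in A3, ≤ C11 < θ; in A2, self-ON implies C ≥ C10 > θ and
self-OFF implies C ≤ C01 ≤ θ.  Consequently (a) asocial dynamics are
invariant to θ within the region and to λ entirely, and (b) the three
asocial reference runs can be computed in closed mode (receptor forced ON,
OFF, or mirroring the own signal) without field solves.  The test suite
asserts this equivalence against full coupled runs placed inside each
region.

## Attractors

One step = field solve from signal bits at `t`, receptor thresholding
(strict `C > θ`), then one synchronous truth-table update of all cells.
Attractor detection hashes the packed global bit matrix each step and stops
at the first exact revisit (online detection; a fixed-horizon trace mode is
not needed because hashing is cheap relative to the solve).  Exceeding the
step budget returns a flagged timeout result rather than raising.  The
cellular attractor of a cell is the *set* of its states over the global
cycle; order is discarded when comparing CAs, and unique CAs are
deduplicated by set equality (checked against a quadratic pairwise oracle).

Initial states draw every node of every cell 0/1 with probability 1/2; the
same initial condition is reused across all (λ, θ) samples of a tissue so
that differences are attributable to communication alone.  The receptor's
initial bit is drawn like any other node; it is overwritten from step 1 on.

## Metrics

All metrics operate on per-cell CA assignments into the tissue's global
catalogue (its M unique CAs across all samples), so distribution vectors
from different samples are aligned.

- `b`: fraction of cells occupying a different CA than in the most similar
  of the three asocial references (minimum normalized Hamming distance).
- `D̂_KL`: minimum symmetric KL divergence (natural log) between the
  sample's CA distribution and the three reference distributions.  Both
  vectors are smoothed by adding ε (default 1e−6) to every entry and
  renormalizing; renormalization is our choice (pure additive smoothing
  without renormalization changes values negligibly for ε ≪ 1/M but is not
  a probability vector).  The attainable maximum depends on ε and M, so
  absolute divergence magnitudes are not comparable across ε choices.
- Diversity: Shannon entropy of the CA distribution (nats, 0·log 0 = 0);
  a sample is homogeneous iff exactly one CA carries all cells (entropy 0).
- λ-profiles: per tissue and λ, the max of a metric over θ normalized by
  the tissue-wide max (tissues with an identically-zero metric contribute
  zero), averaged across tissues.

Taxonomy: asocial and social CA catalogues are pooled over the respective
regions (including the SELF region on the asocial side); lost/novel are the
two set differences.  A novel CA overlapping exactly one asocial CA is
*modified* (equality is impossible by novelty), more than one *combined*,
none *true novel*.  Within any one asocial regime distinct CAs are provably
disjoint (a closed cell's next state is a function of its own state), which
the tests assert; pooled asocial CAs from different regimes may overlap,
and the overlap counts above use the pooled catalogue.

## Experiment designs and problem sizes

The sweep generates `n_tissues` random critical networks; each tissue runs
3 closed-mode references plus one coupled run per (λ, θ) sample.  θ samples
are placed curve-relative per λ: half of C00 (A1), the geometric mean of
C00 and the lower middle curve (S1), five values uniformly spaced strictly
inside the C01/C10 band (A2 or S2 depending on the side of λ\*), the
geometric mean of the upper middle curve and C11 (S3), and twice C11 (A3).
Defaults are 12 λ values in steps of 0.5 and 9 θ values — the canonical
design — with the ensemble size at a desk-scale default of 10 tissues on
16³ (the 100-tissue ensemble runs behind `bn-tissue sweep --full`).  The
attractor-horizon ensemble (also used by `scripts/acceptance.py`) uses 10
tissues × 6 samples, one sample per region, with A2/S2 taken at the nearest
0.5-grid λ on either side of λ\* and the remaining four regions at λ = 1.5.

Reproducibility: a master seed is spawned (`numpy.random.SeedSequence`)
into one child stream per tissue, used for wiring, truth tables and initial
states in a fixed order; manifests embed the full configuration.

## Known limitations

- The coupled dynamics can enter extremely long-period regimes: rarely
  (roughly one sample in a few hundred at the default scale) a tissue
  sample fails to revisit a global state within any practical horizon.
  Such samples are reported as flagged timeouts and excluded from metrics;
  the maximum-recurrence statistic then reports a lower bound.
- The synthetic tissues are maximally idealized — identical networks,
  static cells, a single signal species, synchronous updates, one initial
  condition per tissue.  Passing tests therefore demonstrates properties
  of this model class, not of any real tissue: no stochastic expression,
  cell cycle, mechanics, or evolved network structure is represented.
- Absolute θ units (and thus absolute region-boundary positions) depend on
  the D/R/Vc calibration; only the relative geometry of the regions is
  calibration-free, and only it is asserted.
- Spatial-pattern statistics (autocorrelations, cluster sizes) are out of
  scope; the attractor store retains what would be needed to add them.
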