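# bntissue

Simulation and analysis of 3D tissues of communicating Boolean-network
cells.

## The problem

How much can cell–cell communication alone reshape what cells do and what a
population looks like, absent any evolved signaling circuitry?  `bntissue`
studies this with a deliberately abstract multiscale model: a tissue is a
population of identical cells, one per voxel of a periodic 3D lattice, each
cell an internal Boolean network.  Cells interact through a single diffusible
molecule — a *signal* node sets each cell's secretion rate, and a *receptor*
node switches on when the local concentration exceeds a threshold.  Two
signaling parameters are the knobs of interest:

- **λ**, the effective interaction distance, `λ = sqrt(D/γ)/R` — the decay
  length of the steady-state field in units of the cell radius `R` (`D`
  diffusion coefficient, `γ` degradation rate);
- **θ**, the receptor activation threshold.

The package is aimed at researchers in systems/computational biology who
want a tested, reproducible implementation of this model class: the coupled
dynamics, the classification of communication regimes, and the population
metrics that quantify communication's effect.

## The model

**Cells.** Each cell is a Boolean network on `n` nodes: regulatory nodes and
the signal node update synchronously through k-input truth functions,
`x_j(t+1) = f_j(x_{j1}(t), …, x_{jk}(t))`; the receptor updates by threshold,
`x_R(t+1) = 1` iff `Ĉ > θ` at the cell's voxel.  Random networks are drawn in
the classic Kauffman NK fashion (k distinct inputs per node, truth-table
bits 1 with bias `p`); the bias solving `2kp(1−p) = 1` (for k=3,
`p = 0.2113`) places the cells at dynamical criticality.

**Field.** Secretion is basal (`η₀`) or active (`αη₀`, α=5) depending on the
signal node.  Since diffusion is fast relative to gene regulation the
concentration is the steady state of the diffusion–degradation equation —
the screened Poisson problem `(γ − DΔ)C = η/Vc` — solved exactly for the
7-point periodic discrete Laplacian by FFT.

**Dynamics.** One time step = one field solve from the signal bits, then one
synchronous Boolean update of all cells.  The system is a deterministic
finite dynamical system; a tissue sample (a tissue at one (λ, θ)) reaches
its *tissue attractor* when the global state first revisits itself, and each
cell's *cellular attractor* (CA) is the set of states it occupies over that
cycle (order ignored).

**Six signaling regions.**  Probing a 2-node cell (constant signal +
receptor) with the four extreme configurations of (own, neighbors') signal
gives four concentrations `C00 < {C01, C10} < C11` whose position relative
to θ partitions the (λ, θ) plane into three asocial regions — A1 (always
ON), A2 (self-talk), A3 (always OFF) — and three social ones — S1 (self or
neighbors), S2 (neighbor-dominant), S3 (self and neighbors).  The four
concentration curves are the region boundaries; A2 flips to S2 at the single
λ where self and total-neighbor contributions cross.

**Population metrics.**  Against the three asocial reference regimes the
package computes `b` (fraction of cells in a different CA than in the most
similar asocial reference), the minimum symmetric Kullback–Leibler
divergence between CA distributions, tissue diversity (Shannon entropy of
the CA distribution), homogeneity, and the lost/novel CA taxonomy (novel
CAs classified as *modified*, *combined* or *true novel* by state-set
overlap with asocial CAs).

## Worked example

```python
import numpy as np
from bntissue import (
    FieldParams, LatticeSpec, critical_bias, generate_rbn,
    make_tissue, run_to_attractor, unique_cellular_attractors,
    extreme_config_concentrations, crossover_lambda,
)
from bntissue.regions import classify_point

params = FieldParams()                      # D=0.0125, R=10, alpha=5, eta0=1
lattice = LatticeSpec((16, 16, 16), H=20.0) # 4096 cells

print("critical bias p(k=3) =", round(critical_bias(3), 4))
print("crossover lambda*    =", round(crossover_lambda(params, lattice), 3))
c = extreme_config_concentrations(1.5, params, lattice)
print("C00..C11 at lam=1.5  =", [round(x, 3) for x in c])
print("region of (1.5, 6.0) =", classify_point(1.5, 6.0, params, lattice))

rng = np.random.default_rng(1)
net = generate_rbn(10, 3, critical_bias(3), rng)
tissue = make_tissue(net, lattice, params, lam=1.5, theta=6.0, rng=rng)
attr = run_to_attractor(tissue, max_steps=2000)
cas, assignment = unique_cellular_attractors(attr)
print(f"transient={attr.transient} period={attr.period} unique CAs={len(cas)}")
```

prints

```
critical bias p(k=3) = 0.2113
crossover lambda*    = 0.858
C00..C11 at lam=1.5  = [2.25, 8.908, 4.592, 11.25]
region of (1.5, 6.0) = S2
transient=7 period=10 unique CAs=1
```

Read: at λ=1.5 basal secretion alone sustains a concentration of 2.25 at
every cell; a threshold of 6.0 sits between the all-neighbors curve (8.91)
and the self-only curve (4.59), so the point is neighbor-dominant (S2).
This particular critical tissue settles after a 7-step transient into a
period-10 attractor in which all 4096 cells share one cellular attractor —
a behaviorally homogeneous tissue.

The same experiments are scriptable from the shell:

```sh
bn-tissue regions --lambda-min 0.3 --lambda-max 3.0 --lambda-step 0.01 --out out/regions
bn-tissue sweep --seed 1 --n-tissues 10 --out out/sweep
bn-tissue metrics --metrics-csv out/sweep/metrics.csv --out out/profiles
```

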