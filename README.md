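# orbipool

Invariant and selective complex-cell codes over finite orthogonal groups,
learned with unsupervised (Hebbian-family) rules.

## The problem

The ventral visual stream builds object representations that ignore nuisance
transformations (position, pose, rotation) while still telling objects apart.
The classic Hubel–Wiesel motif offers an architecture for this: *simple cells*
s(x) = σ(wᵀx) detect features, and a *complex cell* c(x) = Σᵢ σ(wᵢᵀx) pools a
bank of them.  `orbipool` implements a complete, numerically assertable
account of when and why this motif yields invariance and selectivity, for
nuisance transformations forming a **finite orthogonal group** G (g⁻¹ = gᵀ):

* **Input structure.** The stimulus ensemble is a union of group orbits,
  S = {g·x_q : g ∈ G, q = 1..Q}.
* **Learning.** Any unsupervised rule descending from a loss
  L(W, S) = Σᵢⱼ f(σ(wᵢᵀxⱼ)) is *equivariant* on orbit-complete data:
  ∇L(gW, S) = g·∇L(W, S), so the solution set is a union of weight orbits.
  The simulations learn an orthonormal frame U* by maximizing
  ‖σ(UᵀS)‖²_F + λ‖σ(UᵀS_new)‖²_F subject to UᵀU = I (projected gradient
  ascent with QR retraction).
* **Wiring.** A complex cell repeatedly selects the strongest pooled
  responder to a fresh orbit set S_new from the frozen pool of learned
  weights; because the pooled response is constant along weight orbits, the
  selected weights form exactly one orbit {g·w̄}, and c is then invariant:
  c(gx) = c(x).
* **Selectivity.** With a Heaviside nonlinearity H(· − z), the family
  c_z(x) = Σᵢ H(xᵀgᵢw − z) is (up to scale and complement) the empirical CDF
  of the simple-cell drives — a *maximal invariant* of the permutation
  action: ‖c(x) − c(x′)‖ = 0 iff x ~ x′.  A finite midpoint threshold grid
  realizes this exactly; with K random thresholds the distance concentrates
  at the Hoeffding rate 2·exp(−Kε²/2p), p = (b−a)²/4.

Everything is exercised on synthetic data: unit-ball orbits of the cyclic and
dihedral permutation groups on R⁶, and rotated disk "patches" on a polar grid
(an exact-rotation stand-in for natural-image patches, with an interpolated
rotation mode that reproduces the approximate invariance of rasterized
rotations).

## Worked example

```python
import numpy as np
from orbipool import (make_cyclic_permutation_group, orbit_bank,
                      complex_response, ThresholdGrid, signature_distance)

rng = np.random.default_rng(1)
g = make_cyclic_permutation_group(6)
w = rng.standard_normal(6); w /= np.linalg.norm(w)
bank = orbit_bank(g, w)                 # 6 Heaviside cells: the orbit of w

x = rng.standard_normal(6)
print([complex_response(bank, M @ x) for M in g.elements])
# [3.0, 3.0, 3.0, 3.0, 3.0, 3.0]   <- identical on every view: invariance

grid = ThresholdGrid.uniform_random(-2, 2, K=10, rng_seed=0)
print(signature_distance(x, g.elements[3] @ x, bank, grid))   # 0.0
print(signature_distance(x, rng.standard_normal(6), bank, grid))  # 3.0
```

The same-orbit distance is exactly 0 for every group element and any shared
grid; the cross-orbit distance is positive whenever a threshold separates the
two drive multisets.  `examples/` contains five short scripts building up
from groups and orbits to the full three-experiment comparison
(`python examples/05_three_experiments.py` prints the summary table below,
computed live):

```
experiment intra max inter min overlap@10 trend rho  plateau
cyclic           0.0      66.0      0.010      0.67   0.0001
dihedral         0.0     299.0      0.006      0.98   0.0001
patch           52.0     412.0      0.069      0.98   0.0001
```

Toy-group intra-orbit distances are exactly 0 and strictly below every
inter-orbit distance; the rasterized-patch stand-in overlaps its intra and
inter distributions more than either toy group; and the cross-orbit cosine
similarity rises with the threshold count before plateauing.

## Command line

```bash
orbipool simulate --kind cyclic --seed 1 --out runs/cyc
orbipool train    --kind cyclic --seed 1 --out runs/cyc
orbipool aggregate --kind cyclic --seed 1 --out runs/cyc
orbipool evaluate --kind cyclic --seed 1 --out runs/cyc
orbipool figure1  --seed 1 --out runs/fig1      # all three presets
```

Every command is a pure function of (config, seed); matrices are tab-
separated text with JSON sidecars.

## Layout

```
src/orbipool/
  groups.py          finite orthogonal groups, orbits, axiom checks
  synthetic_data.py  unit-ball orbit datasets, synthetic patch generator
  cells.py           simple/complex responses, threshold signatures
  learning.py        loss class, gradients, training, Stiefel maximization
  aggregation.py     iterated-argmax wiring, orbit verification
  metrics.py         signature distances, overlap, similarity curves, Hoeffding
  experiments.py     the three experiment presets and the evaluation pipeline
  serialize.py       text-matrix + JSON sidecar I/O
  cli.py             thin typer CLI
docs/methods.md      model assumptions, parameter choices, limitations
examples/            one narrative script per capability
```
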