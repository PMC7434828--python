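# Methods

## Model

The package studies the simple/complex-cell motif under the idealization that
nuisance transformations form a finite orthogonal group G of d×d matrices
(g⁻¹ = gᵀ), and that the stimulus ensemble is a union of complete G-orbits of
Q base stimuli.  Under these two assumptions three facts hold and are turned
into numerically assertable checks:

1. **Equivariance of learning.**  For any loss of the form
   L(W, S) = Σᵢⱼ f(σ(wᵢᵀxⱼ)) with f nonnegative and Lipschitz on bounded
   sets, orbit-complete S implies ∇L(gW, S) = g∇L(W, S) for all g: applying
   gᵀ to the stimuli inside the sum only permutes its terms.  Consequently
   weight orbits are closed under the learning dynamics at checkpoints that
   are multiples of |G| stimulus visits.  Measured residual on permutation
   groups: ~1e-14 (float summation order), asserted ≤ 1e-8.
2. **Invariance by orbit pooling.**  If a complex cell sums simple cells
   whose weights are one orbit {g·w̄}, then c(gx) = c(x) exactly for
   permutation groups (the drive multiset is permuted, the sum unchanged) and
   to trigonometric round-off (≤ 1e-10) for rotation groups.
3. **Selectivity from thresholds.**  With σ = H(· − z), the threshold-indexed
   family c_z(x) is N·(1 − empirical CDF) of the drive multiset
   {xᵀgᵢw̄}.  The empirical CDF is a maximal invariant of the permutation
   action, so over a grid fine enough to resolve every gap between observed
   drives, ‖c(x) − c(x′)‖ = 0 iff the two drive multisets coincide, i.e. iff
   x ~ x′ for stimuli drawn from orbit-structured ensembles.

## Numerical conventions

* **Heaviside ties.** H(0) = 1 (closed at zero), so a threshold below the
  minimum drive yields the full count.  Ties are measure-zero for random
  grids.
* **Full threshold grid.** Midpoints between consecutive distinct observed
  drives plus one flanking threshold on each side.  Drives closer than 1e-9
  are merged first: dot products of permuted vectors agree only to
  accumulation round-off (~1e-16), and a midpoint inside such a float-noise
  gap would spuriously separate exactly equivalent stimuli.
* **Surrogate gradient.** The Heaviside has no usable derivative, so all
  gradients use a logistic surrogate σ(t) = expit(β(t − z)), β = 10 by
  default; evaluation (signatures, distances, selectivity) always uses the
  exact Heaviside.  Whether the original simulations smoothed the
  nonlinearity inside the learning loop is not documented; the surrogate is
  this package's choice and is recorded as such.
* **Ascent, not descent.** The printed online update carries an ambiguous
  sign while the constrained problem maximizes the same response energy; the
  package consistently performs gradient ascent (Hebbian potentiation) with
  a normalized step and backtracking halving, which guarantees monotone
  objective traces (asserted in tests).
* **Stiefel optimization.** Projected gradient ascent with a sign-fixed thin
  QR retraction; several random orthonormal restarts, best objective kept.
  Orthonormality residual at every iterate ≤ 1e-8 (typically 1e-15).
* **Initialization.** Weights default to Gaussian(0, 1e-2/√d); a `zero_init`
  flag reproduces the w₀ = 0 convention.  λ (the S_new term weight) defaults
  to 1.  The number of simple cells defaults to min(|G|, d).
* **Determinism.** All randomness flows from one root seed split per stage
  with `numpy.random.SeedSequence`; reruns are bit-identical.

### A note on learned frames and orbit structure

The solution-space theory says weight orbits are *candidate* solutions, not
that a single gradient run lands on one.  Empirically, on a single cyclic
orbit in R⁶ the orbit-structured orthonormal frames attain the highest
response energy and are fixed points of the ascent, but their basin of
attraction is negligible: random-init projected ascent converges to
non-orbit local maxima in essentially every run (measured over many restarts,
steepness values, and annealing schedules during development).  The package
therefore does not rely on the optimizer discovering orbit frames; orbit
structure enters through the wiring step, whose candidate pool is the
group-orbit closure of the learned columns — exactly what the equivariance
theorem licenses, since each learned column certifies its whole orbit as
solutions.

### Degeneracy guard in wiring

A learned template that is nearly group-invariant (e.g. aligned with the
all-ones direction for cyclic shifts) can be the strongest pooled responder,
but its orbit collapses onto near-copies of one cell: formally an orbit, in
practice a complex cell with a coarse, weakly selective code.  The pipeline
therefore selects the best-responding template whose *orbit spread*
(min over g ≠ e of ‖g·w − w‖, for unit-norm w) exceeds 0.5 — i.e. whose
nearest orbit neighbours are genuinely distinct cells (pairwise cosine
≲ 0.87).  The theory's wiring argument implicitly assumes the selected
weights are distinct elements of one orbit; the guard makes that assumption
operational.  Near-duplicates within the iterated argmax itself are skipped
at cosine > 1 − 1e-8.

## Synthetic data

* **Toy orbits.** Base points uniform in the unit ℓ₂-ball of R⁶ (Gaussian
  direction × U^(1/d) radius — exact), expanded into full orbits of the
  cyclic (order 6) or dihedral (order 12) permutation group.  Base points
  are resampled in the probability-zero event that two fall in one orbit.
* **Patches.** Natural-image patches are replaced by smoothed Gaussian
  random fields on a polar grid (10 rings × 6 sectors + centre pixel, 61
  pixels total for radius 10).  The field is generated on an angularly
  oversampled grid (64 bins ≈ the pixel resolution of the outer ring) and
  smoothed with a Gaussian of 2 px correlation length — a generic stand-in
  for the local spatial correlation of natural images; `smoothness → 0`
  recovers i.i.d. pixel noise.  Two rotation modes exist:
  * `exact` (default): the base readout is transported by the polar
    permutation group; stimuli are exact orbits and all theorems apply
    literally.
  * `interpolated` (used by the patch experiment preset): each rotated view
    resamples the rotated fine field onto the grid by circular linear
    interpolation before coarse readout — the same information loss that
    rotating a rasterized image incurs.  Stimuli then deviate from exact
    orbits by ~3e-3 (relative to unit-norm patches), so invariance is only
    approximate, which is the regime the natural-patch experiment probes.

  What passing tests on this stand-in do **not** show: anything about the
  actual pixel statistics of natural images (1/f spectra, edges,
  nonstationarity).  They do show that the model's qualitative behaviour —
  exact invariance under exact group structure, graceful degradation under
  rasterization-style violations, and reduced selectivity for spatially
  correlated stimuli — follows from the group structure alone.

## Experiment protocol (presets)

Per experiment: S = 100 training orbits, S_new = 2 wiring orbits, 100
held-out test orbits; 200 sampled intra- and 200 inter-orbit pairs, each
measured under 5 independent draws of K = 10 uniform random thresholds
(redraws reduce the variance of the rare-collision statistics that drive the
distribution overlap); similarity-vs-K curves averaged over 3 cross-orbit
pairs × 100 threshold draws for K ∈ {1, 2, 5, 10, 20, 40, 80, 160}; the
plateau statistic is the gap over the last doubling (80 → 160).  These sizes
keep the full three-experiment chain at a few seconds on one CPU while
leaving the comparison statistics stable across seeds; the original
protocol's 1000-orbit test statistics are reproduced by raising `Q_test` and
`n_pairs`.

Distance-distribution overlap is the overlap coefficient (Σ min of the two
normalized histograms, 30 shared bins) of log₁₀(distance + 1e-12); the floor
exists because intra distances are exactly 0.

## Hoeffding analysis

For z ~ Uniform(a, b), the per-threshold signature difference
Δ_z = c_z(x) − c_z(x′) lies in [−N, N] a priori (N = number of cells), so
the mean over K i.i.d. thresholds deviates from the continuous-range
expectation E_z Δ_z by more than ε with probability at most
2·exp(−Kε²/(2p)), p = (b−a)²/4 with b−a = 2N.  The range constant is not
pinned down in the source analysis; the standard Hoeffding constant is used,
which makes the bound valid but loose — at the tested (K, ε) it exceeds 1,
so the Monte-Carlo coverage check is conservative by construction.  The
exact expectation is computed in closed form (E_z H(r − z) = clipped-linear
in r), giving an independent oracle for the sampled estimator.

## Known limitations

* Only finite orthogonal groups; no Lie-group or non-group transformations.
* The Stiefel optimizer finds local maxima; no claim of global optimality.
* The patch stand-in emulates spatial correlation and rasterized rotation,
  not natural-image content.
* Selectivity guarantees are for stimuli within orbit-structured ensembles;
  two arbitrary stimuli with coincidentally equal drive multisets are not
  separated (measure zero for continuous draws).
* Moment-based poolings (mean, energy, max) are noted alternatives to the
  threshold family and are not implemented.
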