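# Methods

## Model

`conscape` treats each input conformational landscape as an empirical
point cloud `X^n` (one latent vector per particle image, all landscapes
indexed by the same ordered particle list) and learns one encoder `E_n`
and one decoder `D_n` per landscape around a shared bottleneck, the
consensus space. Encoders and decoders are plain fully connected MLPs —
`hidden_depth` ReLU layers of `hidden_width` units followed by a linear
output layer; affine layers with biases, no batch/layer normalisation, no
variational bottleneck. The consensus dimension defaults to
`min(input_dims)`: a smaller bottleneck would discard structure the
narrowest input resolves, a larger one admits unmerged directions. Inputs
are fed raw by default; latent coordinates are dimensionless and their
relative scales are themselves informative (they propagate into the error
metrics), so standardisation is an explicit opt-in.

The training objective combines four terms (sums over ordered space pairs
`(n, m)`, including the vanishing diagonal, and sum-reduction over the
batch, with a `mean` option):

* **representation**: `Σ_{n,m,i} ‖x_i^n − D_n(E_m(x_i^m))‖²`. Cross
  reconstructions (m ≠ n) force every decoder to work from every space's
  projection, which is what makes conversion between landscapes possible.
* **L1 (merging)**: `Σ_{n,m,i} ‖E_n(x_i^n) − E_m(x_i^m)‖²` pulls the
  projections of the *same particle* together. Alone it collapses
  distributions without aligning structure, hence:
* **L2 (stress)**: per space, a Sammon/Shannon-type stress
  `[Σ_{ij} (d_ij(X) − d_ij(Z))²/d_ij(X)] / Σ_{ij} d_ij(X)` between the
  input batch's self-distance matrix and its encoded batch's, preserving
  local geometry. Pairs with `d_ij(X) = 0` are excluded (the term is
  undefined there; duplicated points carry no stress). Ordered-pair
  summation is used; the ratio is unaffected by that choice.
* **L3 (spread matching)**: the order-1 Wasserstein distance between the
  encoded batches' pairwise-distance samples (all off-diagonal entries),
  summed over space pairs, aligning the distance *distributions* of the
  encoded spaces. Order 1 is used throughout (also in the consensus-set
  statistic); for equal-size samples it is the mean absolute difference of
  sorted samples, which gives a cheap exact value and subgradient.

## Training schedule

Each mini-batch draws one particle-index subset without replacement and
applies it to every landscape. The batch is forwarded sequentially through
the decoders: the step for decoder `n` minimises its reconstruction term
plus `(L1 + L2 + L3)/N`, backpropagates through decoder `n` and all
encoders, and applies one Adam update — N updates per batch. Dividing the
regularisers by N keeps their per-batch weight equal to the written
objective while retaining the per-decoder schedule; `first_step_only` is
available as an alternative placement. Optimiser defaults: Adam
(β=0.9/0.999, ε=1e-8), learning rate 1e-5, batch size 1024. Epoch count
defaults to 50 with no early stopping; the desk-scale benchmarks below use
150–200 epochs, chosen by watching the loss plateau on the affine-pair
fixture. Weight initialisation (unconstrained by the architecture
description) is seeded He-normal (fan-in scaled), giving bit-identical
builds per seed; training with a fixed seed is deterministic.

The networks, reverse-mode gradients and Adam are implemented directly on
NumPy arrays. The regulariser gradients with respect to the encoded
batches are analytic (the L3 gradient routes sign vectors through the sort
permutation of the distance samples); all are verified against central
finite differences in the test suite.

### Desk-scale configuration

The package's reference benchmarks run on 2,000-particle synthetic
landscapes with `hidden_width=64` and `batch_size=128` while keeping the
Adam/1e-5 optimiser settings. At this problem size the narrow network is
ample (the maps to learn are near-affine in 2-D), and the smaller batch
gives the low learning rate enough update steps per epoch to converge in a
few minutes on one CPU. The 1024/1024 library defaults remain appropriate
for real landscapes with 10⁵–10⁶ particles.

## Per-particle metrics

* consensus error: mean over unordered space pairs of
  `‖E_n(x_i^n) − E_m(x_i^m)‖` — zero exactly when all projections of a
  particle coincide.
* representation error: `‖x_i^n − D_n(E_m(x_i^m))‖`.

Both are reported as Euclidean norms, not squares, so they live on the
coordinate scale of the spaces and histogram comparably; squared norms
appear only inside training losses. Raw errors inherit each input space's
arbitrary scale, so a normalised variant divides by the space's
root-mean-square off-diagonal pairwise distance — a dimensionless,
scale-equivariant, data-estimable choice (`normalize_errors(c·e, c·s)` is
invariant). This normalisation is this package's own convention for
making spaces comparable, not a reproduction of any external procedure.

## Consensus set

Particles are ranked by ascending consensus error (ties broken by id for
determinism). For each K in a sweep grid (default: 20 geometric steps from
100 to the particle count) the top-K projections from the spaces are
compared by the sliced Wasserstein distance: the mean 1-D Wasserstein
distance over κ random unit projections (κ defaults to 100). Significance
comes from a label-permutation test (default 100 randomisations) that
pools the 2K points, resplits them at random, and recomputes the statistic
with the *same* projection vectors — sharing projections keeps projection
noise out of the null. The p-value is the add-one-smoothed
`(1 + #{permuted ≥ d_obs})/(1 + n_perm)`; the opposite-tail variant (the
proportion of randomised distances at or below the observed one) is
available behind `direction="le"`, but the `ge` direction is the one under
which p falls below α as the distributions separate. `K*` is the largest K
with p ≥ α (α = 0.05). With more than two spaces each pair is tested and
the minimum pair p-value is Bonferroni-corrected.

The permutation test is exact under exchangeability: under the null the
rejection rate at α = 0.05 with 100 randomisations is 5/101 ≈ 0.0495,
and the calibration benchmark (200 trials, K = 500, 3-D Gaussians)
reproduces the nominal level. One practical caveat encoded in the
acceptance script: the data draw and the test's projection/permutation
draw must use independent seeds — feeding the same generator state to
both correlates the sample with the projections and inflates rejections.

## Synthetic data

The generator emulates the input regime — several methods observing the
same per-particle states through different distortions — with known truth:

* truth states from a 3-component Gaussian mixture (discrete states plus
  within-state spread), rescaled so the RMS pairwise distance is 1; all
  sigmas/displacements are therefore fractions of the landscape scale;
* per space: an orthonormal-column affine map (or identity), an optional
  mild coordinate-wise `y + a·tanh(y)` nonlinearity (smooth, invertible
  for a < 1), and i.i.d. Gaussian noise;
* discordant particles displaced by a fixed magnitude in a random
  direction, independently per space by default. That default breaks the
  cross-space pairing while leaving every marginal distribution unchanged
  — detectable by the per-particle consensus error, *invisible in
  principle* to the marginal-distribution permutation test. The
  `discordant_spaces` option plants the displacement in a subset of spaces
  instead, which also shifts those spaces' marginals; the 30%-discordant
  sweep fixture uses it, since a distribution-level test can only ever see
  that regime;
* a method-exclusive cluster: a coherent displacement applied in one
  sighted space only, emulating states (e.g. compositional variability)
  that only some methods resolve.

What the fixtures do not emulate: estimation error correlated with
particle signal, non-smooth method failures, landscapes with grossly
different topology, or any image-level physics. Passing the benchmarks
shows the machinery is correct and calibrated on well-specified synthetic
regimes, not that any two real methods' landscapes will merge as cleanly.

## Numerical choices and limitations

* Distance terms exclude the diagonal; zero input distances are excluded
  from the stress numerator; a batch whose points all coincide raises a
  degenerate-batch error.
* A trailing mini-batch of one particle is skipped (it has no distance
  structure); `batch_size > num_particles` falls back to the full set
  with a warning.
* Non-finite losses abort training naming the offending term.
* The 1-D Wasserstein distance is computed by `scipy.stats.wasserstein_distance`;
  the test suite cross-checks it against an exact transport linear program
  on small samples.
* k-means cluster representatives use scikit-learn's `KMeans` (seeded,
  `n_init=10`).
* Checkpoints are NPZ archives containing the architecture spec and all
  weights; loading restores bit-identical behaviour.
* The sweep's `K*` rule ("largest K with p ≥ α") assumes a roughly
  monotone p-vs-K trend; highly non-monotone sweeps (tiny K grids, weak
  signals) should be inspected via the emitted sweep table rather than
  trusted blindly.
* Landscapes must cover identical particle id sets; partial overlap
  (methods that discarded different subsets) is not handled — subset the
  inputs first.
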