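# Methods

## Model

`hopland` treats a differentiating cell population as a Hopfield network
whose nodes are genes and whose edge weights store pairwise co-expression.
For genes `g_1 … g_n` measured across `m` samples, the weight matrix is

    w_ij = Pearson correlation of g_i and g_j across all m samples,
    w_ii = 0,  W = Wᵀ,  w_ij ∈ [-1, 1].

Each sample `s` is discretised to a ternary state vector
`H(s) ∈ {-1, 0, +1}^n` and assigned the network energy

    E[H] = -½ Σ_i Σ_j H_i w_ij H_j .

`E` is unitless and scales linearly with the number of concordantly active
gene pairs.  When a sample's active genes agree with the co-expression
structure stored in `W`, `E` is strongly negative (an attractor valley);
when co-variation is loose — as in cells transiting between fates — the
active states cancel against near-zero weights and `E` approaches 0 (a
hill).  The central prediction is an arc: low energies at the first and
last stages of a time course, high energies in between.

Two deliberate departures from the classical Hopfield model:

* **Correlation weights, not Hebbian learning.**  `W` stores empirical
  co-expression directly rather than a sum of outer products of chosen
  patterns.  One global `W` is computed from all samples pooled across
  stages, so every cell is placed on a single static landscape.
* **No recall iteration during profiling.**  Energies are computed for the
  observed states; running the update dynamics first would report the
  energy of an attractor the state converges to, not of the measured
  biological state.  `recall()` (asynchronous, fixed node order,
  `H_i ← sign(Σ_j w_ij H_j)` with a zero field leaving `H_i` unchanged)
  is exposed separately; its energy trajectory is provably non-increasing,
  and the sign(0)-keeps-state rule extends the descent guarantee to the
  ternary 0 state that classical ±1 theory does not cover.

## Preprocessing

* **Z-scoring** per gene (sample SD, `ddof=1`, configurable).
  Zero-variance genes are mapped to all-zero rows with a warning rather
  than an error — they are removed by feature selection anyway.
* **Feature selection** ranks genes by across-sample variance of the *raw*
  values (z-scoring would equalise them) and cuts at the elbow of the
  descending variance curve: the index maximising the drop below the
  straight chord joining the curve's endpoints.  This is deterministic and
  parameter-free; a flat curve falls back to keeping all genes with a
  warning, and `top_k` / `none` are available as alternatives.
* **Discretisation** uses a symmetric threshold on the per-gene z-score:
  `+1` above `+t`, `-1` below `-t`, else 0, with `t = 0.5` by default —
  under a standard normal all three states get substantial mass
  (≈ 31% / 38% / 31%).  The threshold is exposed everywhere it matters.

## Landscape rendering

PCA is fitted on the z-scored, feature-selected matrix with samples as
observations.  Component signs are fixed (largest-magnitude loading made
positive) so surfaces are reproducible across linear-algebra backends.  A
`grid_size × grid_size` regular grid (default 50) spans the samples'
bounding box expanded by 10% per side; each grid point is inverse-mapped
to gene space, discretised with the *same* threshold as the samples (the
energy is defined on ternary states, so grid states must be ternary to be
comparable), and scored with `E`.  Real samples carry their own energies,
computed from their actual profiles rather than their in-plane
approximations.  A degenerate (zero-extent) axis is expanded by a unit
margin with a warning.  The trajectory is the polyline through per-stage
centroids (mean PC1, PC2 and mean energy) in stage order.

## Perturbation robustness

For each fraction `f ∈ {0.05, 0.1, 0.2, 0.5, 0.9}` (configurable) and
each of `repeats` rounds (default 100): `⌈f·n⌉` genes are drawn without
replacement and *all* their values replaced by uniform draws on `[-1, 1]`
(the gene is the unit of selection; a `cellwise` variant perturbs
individual cells instead).  `W` is rebuilt from the perturbed matrix, the
perturbed data are re-discretised, and per-stage energies are compared
with a fully random matrix of the same size — implemented as the `f = 1`
limit of the same perturbation operator, redrawn each round.  Both
`mean |ΔE|` and `|mean ΔE|` are reported (either is a sensible distance
from the baseline); significance per stage is a two-sided Welch two-sample
t-test of perturbed vs random energies, reported as an exact p-value.
Per-round RNG streams derive from the master seed via
`SeedSequence(master, spawn_key=(fraction_index, repeat, role))`, making
the whole analysis bit-for-bit reproducible.  These ΔE values diagnose
whether a stage behaves as an attractor; they are not estimates of basin
depth or exit time.

## Switched genes

Replicates are aggregated to a stage consensus: the sign of the mean of
the replicate ternary states (sign(0) → 0).  Under the strict rule a gene
is switched between two stages when its consensuses are −1 and +1 (in
either order); transitions through 0 are excluded.  A lenient flag also
reports 0 ↔ ±1 changes, clearly labelled as an extension.  Note that
sign-of-mean consensus is a weak aggregator on unstructured data: with
~10 i.i.d. replicates a null gene's consensus is ±1 with probability
≈ 0.43 per stage, so strict flips between two independent null stages
occur for roughly a third of genes.  Switched-gene lists are therefore
meaningful only relative to data with real stage structure (where
non-switched genes have stable consensuses and false flips are
vanishingly rare); they are not a standalone significance test.

## Synthetic study data

`generate_arc_dataset` emulates the one statistical property the energy
measures — stage-dependent tightness of co-variation — with a latent
factor model.  Gene `g` in module `k`, sample `s` at stage `t`:

    x[g, s] = sign_k(t) · c(t) · f_k(s) + ε,
    f_k(s) ~ N(1, factor_sd²),   ε ~ N(0, noise_sd²),

where `c(t)` is `endpoint_coherence` at the first/last stage and
`transient_coherence` in between, and `sign_k(t)` flips from +1 to −1 at
the course midpoint for switched modules.  Defaults: 200 genes, 4 stages
× 10 replicates, 4 modules, coherences 0.9 / 0.2, `switch_fraction` 0.5,
`noise_sd` 0.3, `factor_sd` 0.2, seed 7.

The unit-mean factor does double duty.  Its dispersion (`factor_sd`)
creates within-module, within-stage correlation proportional to `c(t)²`,
so endpoint stages are tightly co-varying and transient stages loose, as
the model assumes.  Its unit mean gives every module a deterministic
stage-mean profile, so endpoint consensus states are essentially
noise-free and the flipped modules' genes — exactly the generator's
ground-truth switched set — are recoverable with 100% precision and
recall at low noise.  Together with the midpoint sign flip this yields
effective stage means like `(+0.9, +0.2, −0.2, −0.9)` for switched
modules: an arc through the dead zone of the discretiser, which is what
produces near-zero transient energies and the arc-shaped trajectory.

What the generator does **not** emulate: count noise or dropout
(single-cell), probe-level artefacts, unequal replicate numbers, gradual
(non-step) coherence changes, or regulatory directionality.  Passing
tests on this generator demonstrate that the method recovers the
landscape structure it is designed to detect when that structure is
present; they do not certify performance on any particular platform's
noise model.

## Numerical choices

* Correlations via `numpy.corrcoef`, symmetrised as `(W + Wᵀ)/2`, clipped
  to `[-1, 1]`, diagonal zeroed — the weight-matrix contract holds to
  machine precision.
* Variance ties in feature ranking break lexicographically by gene id, so
  selection is invariant to input row order.
* `recall` compares local fields to exactly 0; a zero field leaves the
  node unchanged.
* Stage energy defaults to the unweighted mean of replicate energies; a
  `centroid` aggregate (energy of the stage's consensus state) is
  available for comparison.
* All file outputs use full `repr` float precision; pipeline reruns with
  the same config and seed are byte-identical (the manifest, which
  records wall-clock timings, is the one exception).

## Problem sizes

The shipped tests and the acceptance script run the default design (200
genes × 40 samples) across 100 generator seeds for arc recovery and
perturbation discrimination (25 perturbation rounds per seed, 100 at the
fraction-1 limit) and 20 seeds for switch recovery — sizes chosen so the
full battery completes in well under a minute on a single CPU while
leaving Monte-Carlo margins far from the pass thresholds.

## Limitations

* Pearson correlation captures linear co-variation only; a static global
  `W` assumes the landscape itself does not rewire during the course.
* Energies are comparable within one dataset (one `W`, one gene set), not
  across datasets.
* The perturbation analysis validates the attractor/transient distinction;
  it does not quantify attractor stability.
* Switched-gene counts depend directly on the discretisation threshold
  and consensus rule; see the null-rate caveat above.
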