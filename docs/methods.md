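# Methods

This note records the model as implemented, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not demonstrate.

## Scaling

Descriptors are min–max scaled to [0, 1] per column and the target to
[`target_low`, `target_high`] = [0.1, 0.9] by default, with the ranges
fitted on the training set only.  The target headroom exists because the
Stage II output unit is a logistic sigmoid: with the training extremes at
0.1 and 0.9 the network can represent every training value without
saturating, and its predictions, mapped back, always lie inside the
training range extended by that headroom — the combined model interpolates,
it never extrapolates the property axis.  Values outside the fitted
descriptor ranges scale outside [0, 1] **without clipping**, so
extrapolation remains visible to the applicability-domain check.  Constant
descriptor columns are scaled to 0.5 and flagged with a warning instead of
being dropped: dropping would silently change the descriptor count, which
must stay equal to the Stage II input-layer size.  Missing values are
rejected at read time; imputation is out of scope.

## Stage I: counter-propagation network

Both grids (Kohonen rows × cols × n, Grossberg rows × cols) are initialised
uniformly at random in [0, 1] from the seed, independent of the data.
Training is online: each epoch presents the training compounds in a freshly
shuffled order; for each compound the winning neuron (minimal Euclidean
distance, ties to the smallest row-major index) is found, and **every**
neuron is corrected by

    Δw = η(t) · a(neuron) · (component − w)

toward the compound's descriptors (Kohonen layer) and its scaled target
(Grossberg layer) in the same pass.  The neighbourhood factor `a` is
triangular by default, `max(0, 1 − d/(radius+1))` with `d` the Chebyshev
grid distance to the winner (wrap-around on toroidal maps; a rectangular
indicator window is available).  The learning rate decays linearly from
`eta_max` = 0.5 to `eta_min` = 0.01 and the radius from
`max(rows, cols)/2` to 0 over the epochs — the classical counter-propagation
schedule.  With the final radius at 0 an update touches only the winner, so
occupied neurons converge toward the running means of their occupants'
descriptors and targets, and neighbourhood training leaves *empty* neurons
with smoothed, locally interpolated Grossberg values.  The planar topology
is the default; both topology and neighbourhood shape are configurable
because different established implementations of this model family differ
here.  After training, each training compound's distance to its winning
neuron and the per-neuron occupancy are recorded with the final weights —
these feed the applicability domain.

Prediction is a lookup: scale the query, find the winner, return its
Grossberg value in target units.  Over any probe set this emits at most
`k = rows × cols` distinct values, which is the precision limitation the
second stage removes.

## Neuron extraction

All `k` neurons are extracted as Stage II training objects by default,
empty ones included: their smoothed Grossberg values make them
representative objects in their own right, and they thicken the training
set where compounds are sparse.  An occupied-only mode exists for ablation.
Whether discarding empty neurons helps has no principled answer at this
level; both routes are exposed and the default was chosen for smoothness of
the Stage II target surface.

## Stage II: back-propagation network

One hidden layer (the published grids use 5, 10 or 12 units), logistic
sigmoid on hidden and output units, bias handled as a constant-1 input to
each layer.  Training is online back-propagation of the squared error
`E = ½(output − target)²` with momentum,

    Δw(t) = −η · ∂E/∂w + μ · Δw(t−1),

defaults η = 0.1, μ = 0.01, 1000 epochs.  Weights start uniform in
[−0.5, 0.5] from the seed.  Per-pattern (not batch) updates were chosen to
match the classical formulation of this model family; a linear-output mode
is switchable for ablation.  The innermost loop is compiled (numba); the
pure-Python single-step update is kept as the reference implementation and
the test suite verifies one-epoch equivalence of the two routes, alongside
a central-finite-difference audit of the analytic gradients.  Presentation
schedules are generated in blocks of 4000 epochs purely to bound memory;
blocking is bitwise invisible to the result.  A non-finite loss aborts with
a diagnostic (rather than silently clipping) so a mis-set learning rate
surfaces honestly.  Stage I is frozen throughout — no gradient reaches the
Kohonen weights, and Stage II never sees a compound, only neurons (enforced
by the `NeuronDataset` type).

## Model selection and evaluation

`select_model` trains Stage I once, then one Stage II network per
(hidden, epochs) grid cell on the shared neuron set, scoring each by
test-set RMSE of the combined model in target units; ties resolve to fewer
hidden neurons, then fewer epochs.  The validation set is never consulted
during selection.  Default grids are hidden {5, 10, 12} and epochs
{1000; 10,000; 100,000; 500,000}; the epoch grid end is deliberately
generous and most datasets select far below it.  `evaluate` reports, per
set, the combined-model RMSE, the Stage I lookup RMSE, and the
combined-model RMSE restricted to in-domain compounds, so runs can be laid
beside published model tables.  `crossvalidate` implements leave-k-out over
contiguous blocks of a seed-shuffled order, retraining both stages per
fold and pooling predictions.

## Applicability domain

The domain is defined on the distribution of training compounds' Euclidean
distances to their excited neurons in scaled descriptor space.  The default
threshold is the **maximum** training distance — the most permissive rule
consistent with that distribution, under which every training compound is
in domain by construction; a percentile variant (linear interpolation
between order statistics) is implemented as the documented alternative, and
the choice is stored in the model archive.  The exact functional form used
by the originating software lineage (max vs percentile vs mean + k·sd)
could not be pinned down, hence both options.  The domain is a Stage I
property only: retraining Stage II with a different hidden size cannot
change any flag.  Out-of-domain compounds are still predicted and reported,
flagged unreliable.

## SOM-based splitting

`som_split` trains an unsupervised Kohonen map (default 60 epochs) on the
scaled descriptors, groups compounds by winning neuron, and orders picks
round-robin over occupied neurons (row-major), within each neuron by
ascending distance.  Each pick is labelled with the set whose quota is
relatively least filled, ties TRAIN > TEST > VALIDATION, so every
structural neighbourhood feeds all three sets.  Quotas are
`floor(m·f_train)` for TRAIN with the remainder divided between TEST and
VALIDATION in proportion to their fractions, the larger share to TEST when
exact matching is impossible: 1674 compounds at 60/20/20 gives
1004/335/335.  The literature describes the *idea* of uniform top-map
selection but not the mechanics; the round-robin/deficit rule is this
package's deterministic realisation of it.  The map should be small enough
that several similar compounds excite each neuron; this is documented, not
enforced.

## Descriptor reduction

Three steps on scaled values: drop columns with sample variance below
0.005; for every pair with |Pearson r| > 0.95 drop the later column in file
order (the convention is arbitrary but must be fixed; file order is
reproducible); train a Kohonen map on the transposed matrix (descriptors as
objects) and keep, per occupied neuron, the descriptor nearest to and the
descriptor farthest from the neuron's weight vector.

## Synthetic data

The generator emulates curated descriptor tables: descriptors uniform on
[0, 1] (optionally clustered with ±0.15 jitter), a smooth function (linear,
quadratic, sinusoidal, or per-cluster plateau) of the first
`n_informative` columns, remaining columns pure nuisance.  Raw function
values are mapped affinely onto [−7, −2] — a 5-log-unit span typical of
curated log-property datasets — before Gaussian noise (`noise_sd`, target
units) is added, so reports read like solubility modelling.  Everything is
bit-reproducible from the seed.

`make_plateau_fixture` is the adversarial case for the lookup model: tight
clusters that each excite a single neuron, with the target globally linear
in one coordinate (slope 1 over a jitter width of 0.1 at the defaults).  A
per-neuron-constant predictor is floored at the within-cluster spread
(uniform width 0.1 → sd ≈ 0.029), while the smooth Stage II surface can
recover the underlying line; measured combined-model RMSE on held-out
probes is ≈ 0.012 against the lookup's ≈ 0.029.

What these fixtures do **not** show: real descriptor tables are
discrete-valued, heavy-tailed, collinear and non-uniformly populated, and
real property noise is not homoscedastic Gaussian.  Passing the synthetic
benchmarks demonstrates the machinery (stage coupling, scaling, domain
logic, numerical correctness) and the direction of the lookup-vs-continuous
contrast, not transferable accuracy figures for any real endpoint.

## Benchmark problem sizes

The desk-scale benchmarks in the test suite and `scripts/acceptance.py`
use m = 200 compounds with 6 descriptors (3 informative, noise sd 0.1) on a
12×12 map with Stage II grids {5, 10, 12} × {10,000; 50,000} epochs, a
Stage I schedule of 400 epochs, and 5 seeds for the stochastic claims; the
plateau fixture uses 4 clusters × 25 compounds on a 2×2 map.  These sizes
were chosen so a full multi-seed comparison trains in well under a minute
while leaving the lookup-vs-continuous gap far larger than the seed-to-seed
scatter.

## Numerical choices and degenerate inputs

Winner ties break to the smallest row-major index; this plus seeded
shuffling makes both training stages bit-deterministic given (data, config,
seed), which the suite verifies by byte-comparing serialized models.  A
constant target scales to the interval midpoint.  1×1 maps are legal (the
single neuron converges to the data mean).  Quota arithmetic carries an
epsilon guard so exact fraction products do not drift across floor/ceil
boundaries in floating point.  Models persist as a single versioned JSON
document; loading a newer major format version is an explicit error.

## Known limitations

- One property per model; multi-output Grossberg/BPE layers are non-goals.
- No descriptor computation from structures: tables of numbers in, numbers out.
- No regularisation, early stopping, or adaptive optimizers in Stage II;
  capacity control happens through the architecture/epoch grid selection.
- The Stage I training schedule (linear decays, triangular neighbourhood,
  online updates) follows the classical recipe for this model family;
  other published implementations may differ in details that their
  appendices do not fully specify, so all schedule elements are
  configurable rather than hard-coded.
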