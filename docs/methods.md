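# Methods

This note records the model, the numerical choices and the limits of what
the synthetic benchmark can demonstrate.

## Forward model and objective

Expected counts follow the affine Poisson model `ybar(x) = m * (A x + a)`.
`A` is a 2-D parallel-beam line-integral operator with exact
voxel-intersection lengths (Siddon-style ray tracing), materialised once
per geometry as a sparse matrix; the adjoint is the transpose of that same
matrix, so the pair is matched by construction and the inner-product
identity `<Ax, g> = <x, A'g>` holds to round-off.  This matters because the
sensitivity images, the EM-like preconditioner and the kappa derivation all
mix `A` and its adjoint; with an unmatched pair those quantities are
mutually inconsistent and subset solvers can stall or drift.  3-D volumes
are projected plane by plane with the same in-plane operator — adequate for
testing the dimension-agnostic mathematics, not a model of oblique 3-D
acquisition.

Virtual-crystal bins are modelled by `m_k = 0`; their likelihood terms are
defined as zero and every ratio with `ybar` excludes them before dividing.
The additive background must be strictly positive at live bins, which
guarantees `ybar > 0` wherever a count can occur.

The prior is the smoothed relative difference penalty with edge parameter
`gamma` (default 2, the field's customary value), neighbour weights equal
to the horizontal voxel pitch over the inter-voxel distance (direct
in-plane neighbours weigh 1 on an isotropic grid, in-plane diagonals
1/sqrt(2)), and a kappa image making the regularisation strength spatially
uniform.  In 2-D the 26-neighbour rule restricts to the 8 in-plane
neighbours.  The gradient is analytic; the smoothing constant
`eps > 0` makes the penalty differentiable where neighbours are equal
(the `|x_i - x_j|` kink is quadratically suppressed there).

## Derived parameters

Both `eps` and the preconditioner floor `delta` are scalar fractions of the
OSEM image maximum: `eps = 1e-4 * max(x_osem)` and
`delta = 1e-6 * max(x_osem)` by default, both configurable.  The governing
idea is that they must scale with the image's count level; the specific
fractions are this package's declared defaults.  `kappa` is
`sqrt(A' [ m^2 y / ybar^2 (A 1) ])` at the OSEM image — the square root of
minus the row-sums of the likelihood Hessian — clamped at zero against
round-off, and verified in the tests against an explicitly assembled dense
Hessian on 16-voxel instances.

## Solvers

**OSEM** uses the classic multiplicative update per angular subset with the
`0/0 := 0` convention at voxels of zero subset sensitivity.  With one
subset it is MLEM, whose likelihood-monotonicity the tests check over 200
iterations.  As a challenge entry OSEM targets the unpenalised likelihood,
so against a MAP reference it is expected to be censored — a useful
negative control for the ranking machinery.

**BSREM** performs `x <- P_C(x + alpha_k (x + delta)/S * grad_s Psi)` with
cyclic subset order, `S` the average per-subset sensitivity image (voxels
with zero sensitivity are frozen), and the relaxed schedule
`alpha_k = alpha0 / (1 + eta * epoch)`.  The update *divides* by `S`: the
preconditioner is the EM-type `(x + delta)/S` diagonal, which is what makes
the iteration an ascent in the likelihood's natural geometry.  Non-finite
iterates abort with a diagnostic rather than propagating NaNs.

**Reference reconstruction** runs BSREM in rounds.  The warm rounds restart
the relaxed schedule from the current iterate, which traverses the easy
early phase quickly.  Cyclic subset iterations, however, orbit the optimum
at a radius proportional to the step size, so after the warm phase the
remaining rounds switch to a single subset — the identical update rule,
now an exact preconditioned projected gradient ascent — with a constant
step.  A polish round is accepted only if it strictly reduces the KKT
residual (or reaches tolerance); otherwise it is discarded and the step
halved, which also handles constant-step limit cycles.  Convergence
requires the worst KKT violation (interior `|grad|`, boundary
`max(grad, 0)`), measured relative to the gradient sup-norm at the starting
image, to fall below `kkt_tol` (default 1e-6) with the objective stable
over a round.  If the budget is exhausted the image is returned flagged
non-converged.  Normalising the residual by the gradient at the solution
itself would be degenerate (the ratio tends to 1), hence the fixed
starting-image scale.

**SVRG** anchors a variance-reduced estimator
`n (grad L_s(x) - grad L_s(x~)) + grad L(x~) - beta grad R(x)` at a
snapshot `x~` refreshed every epoch, drawing subsets without replacement
from a seeded generator; with a snapshot every update the estimator
degenerates to the full gradient, a structural identity the tests exploit.
It shares the BSREM preconditioner and projection, hence the same fixed
points.

Step sizes: relaxed-subset methods need per-problem tuning.  The package
defaults (`alpha0 = 0.1`, `eta = 0.1`, 8 subsets, 500 updates for
challengers) are tuned once for the default 64x64 phantom studies, where
they are stable and reach the thresholds comfortably; `alpha0 = 1` is
stable on the small 16x16 fixtures used by the unit tests.  All tuning
knobs live in the run configuration.

## Synthetic phantoms

The generator emulates the *structure* of image-quality phantom studies,
not their anatomy: a warm elliptical body at activity 1.0 with 4–6 hot
disc/sphere inserts on a ring (image-quality style), an ellipse with
interleaved high/low bands inside a uniform rim (brain-phantom style), and
a uniform disc (sanity baseline).  Each scene carries water-equivalent
attenuation (0.0096/mm), a support mask, a whole-object VOI eroded by one
voxel (the "marginal" margin is a configurable choice), a background VOI
inside a uniform-activity region with a safety margin from inserts and the
object boundary, and one target VOI per insert or matter patch.  Insert
geometry follows fixed fractions of the grid; the seed jitters positions by
at most one voxel, so VOIs are reproducible and inserts provably disjoint.
Counts are scaled so total expected trues hit a target (default 1e6),
background is a constant strictly-positive sinogram at a fixed fraction of
trues (default 20%), and a small fraction of bins (default 1%) get `m = 0`
to exercise the virtual-crystal conventions.

What passing tests on these scenes does *not* show: robustness to scatter
model mismatch, detector blur, time-of-flight weighting, patient-scale
axial geometry, or vendor data quirks — none of which the generator
attempts to model.

## Scoring and ranking

Metrics are evaluated at every update from iterate snapshots kept in
memory.  Timestamps are taken immediately after each update and before any
metric bookkeeping, so metric cost does not pollute algorithm timing.  The
pass time is the timestamp of the *first* update of the first run of
`persistence` (default 10) consecutive passing updates whose window
completes within the time cap; traces that never achieve this are censored
at the cap.  Ranking uses per-(dataset, metric) cells: the median time over
repeated runs (censored counts as the cap), slowest rank 1, fastest rank N,
ties averaged; an algorithm's score is its mean rank.  Since uncensored
pass times are strictly below the cap by construction, censored algorithms
can never out-rank uncensored ones.

Timing is pluggable.  The default challenge clock is a deterministic cost
model — time advances by a fixed amount per view of projector work — which
makes full challenge runs bit-reproducible (traces, images, leaderboards)
and machine-independent; a wall clock is available for real benchmarking,
in which case reproducibility holds for everything except the recorded
times.

## File formats and configuration

Images and projection data are exchanged in an Interfile-lite dialect: a
plain-text `key := value` header plus a raw binary payload, with the
sinogram geometry carried in the projection header.  The recognised key set
is fixed and documented in the module; unknown keys are ignored with a
logged warning.  Run configuration is a flat INI file with sections; every
command writes its fully resolved configuration next to its outputs, so a
dataset directory is always sufficient to re-run scoring and ranking.

## Problem sizes

The test suite runs 16x16–64x64 scenes with 8–64 views; the acceptance
script's end-to-end challenge uses a 64x64 image-quality-like scene with 64
views, 8 subsets, 1e6 trues, three runs per algorithm, run twice for the
determinism check.  These sizes keep every check in seconds while leaving
all code paths identical to larger studies.

## Known limitations

- The projector is parallel-beam 2-D (stacked for 3-D); no scanner-specific
  geometry, arc correction, or resolution modelling.
- `a` is simulated, never estimated; scatter/randoms physics is out of
  scope.
- The challenge's wall-clock protocol is represented by a configurable
  time cap and the cost-model clock; absolute times are not comparable to
  any real scanner platform.
- Voxels clipped to zero by the BSREM projection recover only at a rate
  proportional to `delta`; nearly-unregularised problems may need a smaller
  step (see the solver notes above) to avoid transient clipping.
- At strong regularisation the prior couples the object rim to the zero
  exterior, so MAP solutions shrink at the boundary; this is a property of
  the model, not a solver artefact.
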