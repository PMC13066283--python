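"""Reconstruction algorithms: OSEM initialiser, BSREM reference, SVRG.

BSREM is the convergent reference solver: a relaxed, preconditioned subset
gradient ascent on the MAP objective,

    x_new = P_C( x + alpha_k * (x + delta) / S * grad_s Psi(x; y) ),

with P_C the projection onto the constraint set (clip negatives inside the
support mask, zero outside), S the average of the per-subset sensitivity
images A_s^T m_s, delta a small positive constant derived from the OSEM
image, and a step size alpha_k that decays with epoch.  The (x+delta)/S
factor is the EM-like diagonal preconditioner; voxels with zero sensitivity
are frozen at zero.

The SVRG challenger uses the same preconditioner and constraint projection
but replaces the plain subset gradient with a variance-reduced estimator
anchored at a full-gradient snapshot refreshed every epoch.

Timing is pluggable: a wall clock for real benchmarking, or a deterministic
cost-model clock (time proportional to projector work) for bit-reproducible
challenge runs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .acquisition import (
    AcquisitionFactors,
    ProjectionData,
    ProjectorGeometry,
    SubsetScheme,
    sensitivity_images,
    subset_back,
    subset_forward,
)
from .grids import ImageVolume
from .objective import (
    ObjectiveValue,
    PriorParams,
    full_grad,
    objective,
    subset_grad,
)

__all__ = [
    "StepSchedule",
    "BsremConfig",
    "SolverTrace",
    "WallClock",
    "VirtualClock",
    "project_C",
    "osem",
    "osem_solver",
    "bsrem",
    "svrg_solver",
    "reconstruct_reference",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite (step schedule too aggressive)."""


class WallClock:
    """Real elapsed seconds since construction; `tick` cost is ignored."""

    def __init__(self) -> None:
        self._t0 = time.perf_counter()

    def tick(self, cost_units: float) -> None:  # noqa: ARG002 - wall time ignores cost
        pass

    def now(self) -> float:
        return time.perf_counter() - self._t0


class VirtualClock:
    """Deterministic clock advancing by a fixed time per unit of projector work.

    One cost unit is one view's worth of forward or back projection; the
    conversion factor is arbitrary but fixed, so rankings and traces are
    bit-reproducible across runs and machines.
    """

    def __init__(self, seconds_per_unit: float = 1e-3) -> None:
        self.seconds_per_unit = float(seconds_per_unit)
        self._t = 0.0

    def tick(self, cost_units: float) -> None:
        self._t += cost_units * self.seconds_per_unit

    def now(self) -> float:
        return self._t


@dataclass(frozen=True)
class StepSchedule:
    """Relaxed step size alpha_k = alpha0 / (1 + eta * epoch(k)).

    ``k`` counts updates; the epoch is ``k // n_subsets``.  ``eta = 0``
    gives a constant step; ``eta > 0`` gives the decaying schedule required
    for convergence of the subset iteration.
    """

    alpha0: float = 1.0
    eta: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")

    def alpha(self, k: int, n_subsets: int) -> float:
        return self.alpha0 / (1.0 + self.eta * (k // n_subsets))


@dataclass(frozen=True)
class BsremConfig:
    """Configuration shared by the subset solvers."""

    schedule: StepSchedule = field(default_factory=StepSchedule)
    delta: float = 1e-6
    n_subsets: int = 8
    max_updates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.max_updates < 1:
            raise ValueError("max_updates must be >= 1")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


@dataclass
class SolverTrace:
    """Per-update history of one solver run.

    Timestamps are taken immediately after each update and before any
    objective/metric bookkeeping, so diagnostics do not pollute the timing.
    """

    updates: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    logliks: list[float] = field(default_factory=list)
    priors: list[float] = field(default_factory=list)
    totals: list[float] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)
    final: ImageVolume | None = None
    converged: bool = False

    def record(
        self, k: int, t: float, obj: ObjectiveValue, image: np.ndarray | None
    ) -> None:
        if self.updates and (k != self.updates[-1] + 1 or t < self.times[-1]):
            raise ValueError("updates must be consecutive with non-decreasing times")
        self.updates.append(k)
        self.times.append(t)
        self.logliks.append(obj.loglik)
        self.priors.append(obj.prior)
        self.totals.append(obj.total)
        if image is not None:
            self.snapshots.append(image.copy())

    def to_rows(self) -> list[dict]:
        return [
            {
                "update": u,
                "time_s": t,
                "loglik": l,
                "prior": p,
                "total": v,
            }
            for u, t, l, p, v in zip(
                self.updates, self.times, self.logliks, self.priors, self.totals
            )
        ]


def project_C(x: ImageVolume, object_mask: np.ndarray) -> ImageVolume:
    """Projection onto the constraint set: clip inside the mask, zero outside."""
    out = np.where(object_mask, np.maximum(x.values, 0.0), 0.0)
    return x.with_values(out)


def _subset_factors(factors: AcquisitionFactors, views: tuple[int, ...]):
    v = list(views)
    return factors.m.values[..., v, :], factors.a.values[..., v, :]


def osem(
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    scheme: SubsetScheme,
    n_epochs: int,
    x0: ImageVolume | None = None,
    object_mask: np.ndarray | None = None,
) -> ImageVolume:
    """Ordered-subsets EM: x <- x / (A_s^T m_s) * A_s^T [ m_s y_s / ybar_s ].

    One subset reduces to MLEM, which never decreases the log-likelihood.
    Voxels with zero subset sensitivity are left untouched (0/0 := 0); the
    iterate stays non-negative and supported on the mask.
    """
    per_subset, _ = sensitivity_images(geom, factors, scheme)
    if object_mask is None:
        object_mask = np.ones(
            per_subset[0].shape if x0 is None else x0.shape, dtype=bool
        )
    if x0 is None:
        x0 = per_subset[0].with_values(np.where(object_mask, 1.0, 0.0))
    if np.any(x0.values < 0):
        raise ValueError("OSEM initial image must be non-negative")
    if not any(s.values.max() > 0 for s in per_subset):
        raise ValueError("zero sensitivity everywhere; no data reaches the image")
    x = np.where(object_mask, x0.values, 0.0)
    for _ in range(n_epochs):
        for views, sens in zip(scheme.subsets, per_subset):
            m_s, a_s = _subset_factors(factors, views)
            ax = subset_forward(x0.with_values(x), geom, views)
            ybar = m_s * (ax + a_s)
            ratio = np.zeros_like(ybar)
            live = m_s > 0
            yb = ybar[live]
            y_s = y.values[..., list(views), :][live]
            if np.any((yb <= 0) & (y_s > 0)):
                raise ValueError("zero expectation at a live bin with counts")
            ok = yb > 0
            r = np.zeros_like(yb)
            r[ok] = m_s[live][ok] * y_s[ok] / yb[ok]
            ratio[live] = r
            bp = subset_back(ratio, geom, views).values
            s = sens.values
            upd = np.ones_like(x)
            pos = s > 0
            upd[pos] = bp[pos] / s[pos]
            x = np.where(object_mask, x * upd, 0.0)
    return x0.with_values(x)


def osem_solver(
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
    cfg: BsremConfig,
    x0: ImageVolume,
    object_mask: np.ndarray,
    scheme: SubsetScheme | None = None,
    clock=None,
    record_images: bool = True,
) -> SolverTrace:
    """OSEM run as a challenge entry: one subset update per trace record.

    OSEM ignores the prior, so against a MAP reference it converges to a
    different limit; ``p`` is used only to log objective components.
    """
    if scheme is None:
        from .acquisition import make_subsets

        scheme = make_subsets(geom.n_views, cfg.n_subsets)
    if clock is None:
        clock = WallClock()
    trace = SolverTrace()
    per_subset, _ = sensitivity_images(geom, factors, scheme)
    x = project_C(x0, object_mask).values
    if x.max() <= 0:
        x = np.where(object_mask, 1.0, 0.0)
    for k in range(cfg.max_updates):
        s = k % scheme.n_subsets
        views = scheme.subsets[s]
        m_s, a_s = _subset_factors(factors, views)
        ax = subset_forward(x0.with_values(x), geom, views)
        ybar = m_s * (ax + a_s)
        ratio = np.zeros_like(ybar)
        live = m_s > 0
        yb = ybar[live]
        y_s = y.values[..., list(views), :][live]
        ok = yb > 0
        r = np.zeros_like(yb)
        r[ok] = m_s[live][ok] * y_s[ok] / yb[ok]
        ratio[live] = r
        bp = subset_back(ratio, geom, views).values
        sens = per_subset[s].values
        upd = np.ones_like(x)
        pos = sens > 0
        upd[pos] = bp[pos] / sens[pos]
        x = np.where(object_mask, x * upd, 0.0)
        clock.tick(_update_cost(len(views)))
        t = clock.now()
        obj = objective(x0.with_values(x), y, geom, factors, p)
        trace.record(k + 1, t, obj, x if record_images else None)
    trace.final = x0.with_values(x)
    return trace


def _preconditioner(
    x: np.ndarray, delta: float, S: np.ndarray, object_mask: np.ndarray
) -> np.ndarray:
    """EM-like diagonal preconditioner (x+delta)/S; zero-sensitivity voxels frozen."""
    pre = np.zeros_like(x)
    ok = (S > 0) & object_mask
    pre[ok] = (x[ok] + delta) / S[ok]
    return pre


def _update_cost(n_subset_views: int) -> float:
    # one subset forward + one subset back projection, in view units
    return 2.0 * n_subset_views


def bsrem(
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
    cfg: BsremConfig,
    x0: ImageVolume,
    object_mask: np.ndarray,
    scheme: SubsetScheme | None = None,
    clock=None,
    k_offset: int = 0,
    record_images: bool = True,
    trace: SolverTrace | None = None,
) -> SolverTrace:
    """Relaxed preconditioned BSREM ascent on the MAP objective.

    Subsets are visited cyclically in order (deterministic reference
    behaviour).  ``k_offset`` shifts the step-size schedule, so a restart
    is a fresh call with ``k_offset=0`` starting from the current iterate.
    """
    if scheme is None:
        from .acquisition import make_subsets

        scheme = make_subsets(geom.n_views, cfg.n_subsets)
    if clock is None:
        clock = WallClock()
    if trace is None:
        trace = SolverTrace()
    _, S_img = sensitivity_images(geom, factors, scheme)
    S = S_img.values
    x = project_C(x0, object_mask).values
    start = len(trace.updates)
    for k in range(cfg.max_updates):
        s = k % scheme.n_subsets
        g = subset_grad(
            x0.with_values(x), s, scheme, y, geom, factors, p
        ).values
        pre = _preconditioner(x, cfg.delta, S, object_mask)
        alpha = cfg.schedule.alpha(k + k_offset, scheme.n_subsets)
        x = np.where(object_mask, np.maximum(x + alpha * pre * g, 0.0), 0.0)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(
                f"non-finite iterate at update {k + 1}; reduce alpha0 or "
                "increase the relaxation rate eta"
            )
        clock.tick(_update_cost(len(scheme.subsets[s])))
        t = clock.now()
        obj = objective(x0.with_values(x), y, geom, factors, p)
        trace.record(
            start + k + 1, t, obj, x if record_images else None
        )
    trace.final = x0.with_values(x)
    return trace


def svrg_solver(
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
    cfg: BsremConfig,
    x0: ImageVolume,
    object_mask: np.ndarray,
    scheme: SubsetScheme | None = None,
    clock=None,
    snapshot_period: int | None = None,
    record_images: bool = True,
) -> SolverTrace:
    """Preconditioned SVRG ascent with an epoch-refreshed gradient snapshot.

    The stochastic estimator at update k with subset s is

        G = n (grad L_s(x) - grad L_s(x~)) + grad L(x~) - beta grad R(x),

    with x~ the snapshot image.  Subsets are drawn without replacement per
    epoch from a seeded generator, so runs are deterministic given the
    config seed.  ``snapshot_period=1`` refreshes the snapshot every update
    and the estimator degenerates to the full gradient (preconditioned
    projected gradient ascent).
    """
    from .objective import _subset_loglik_grad  # shared ratio/adjoint kernel

    if scheme is None:
        from .acquisition import make_subsets

        scheme = make_subsets(geom.n_views, cfg.n_subsets)
    if clock is None:
        clock = WallClock()
    if snapshot_period is None:
        snapshot_period = scheme.n_subsets
    rng = np.random.default_rng(cfg.seed)
    trace = SolverTrace()
    _, S_img = sensitivity_images(geom, factors, scheme)
    S = S_img.values
    x = project_C(x0, object_mask).values
    n = scheme.n_subsets
    snap_x: np.ndarray | None = None
    snap_full: np.ndarray | None = None
    order: list[int] = []
    for k in range(cfg.max_updates):
        if k % snapshot_period == 0 or snap_x is None:
            snap_x = x.copy()
            gl = sum(
                _subset_loglik_grad(
                    x0.with_values(snap_x), views, y, geom, factors
                ).values
                for views in scheme.subsets
            )
            snap_full = gl
            clock.tick(2.0 * geom.n_views)
        if not order:
            order = list(rng.permutation(n))
        s = int(order.pop())
        views = scheme.subsets[s]
        gs_x = _subset_loglik_grad(x0.with_values(x), views, y, geom, factors).values
        gs_snap = _subset_loglik_grad(
            x0.with_values(snap_x), views, y, geom, factors
        ).values
        from .objective import rdp_grad

        g = n * (gs_x - gs_snap) + snap_full - p.beta * rdp_grad(
            x0.with_values(x), p
        ).values
        pre = _preconditioner(x, cfg.delta, S, object_mask)
        alpha = cfg.schedule.alpha(k, n)
        x = np.where(object_mask, np.maximum(x + alpha * pre * g, 0.0), 0.0)
        if not np.all(np.isfinite(x)):
            raise DivergenceError(f"non-finite iterate at update {k + 1}")
        clock.tick(2.0 * _update_cost(len(views)))
        t = clock.now()
        obj = objective(x0.with_values(x), y, geom, factors, p)
        trace.record(k + 1, t, obj, x if record_images else None)
    trace.final = x0.with_values(x)
    return trace


def kkt_residual(
    x: ImageVolume,
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
    object_mask: np.ndarray,
) -> float:
    """First-order optimality residual of the constrained maximisation.

    At a solution, voxels with x > 0 have zero gradient and voxels at the
    bound x = 0 (inside the mask) have non-positive gradient.  Returns the
    worst absolute violation (gradient units); callers normalise by a
    problem scale such as the gradient sup-norm at the starting image.
    """
    g = full_grad(x, y, geom, factors, p).values
    interior = object_mask & (x.values > 0)
    boundary = object_mask & (x.values == 0)
    res = 0.0
    if interior.any():
        res = max(res, float(np.abs(g[interior]).max()))
    if boundary.any():
        res = max(res, float(np.clip(g[boundary], 0.0, None).max()))
    return res


def reconstruct_reference(
    y: ProjectionData,
    geom: ProjectorGeometry,
    factors: AcquisitionFactors,
    p: PriorParams,
    cfg: BsremConfig,
    x0: ImageVolume,
    object_mask: np.ndarray,
    scheme: SubsetScheme | None = None,
    clock=None,
    kkt_tol: float = 1e-6,
    obj_tol: float = 1e-12,
    max_restarts: int = 10,
    warm_rounds: int = 2,
    record_images: bool = False,
) -> tuple[ImageVolume, SolverTrace]:
    """BSREM reference run: restarted subset rounds, then a full-gradient polish.

    The warm phase runs ``warm_rounds`` rounds of ``cfg.max_updates`` subset
    updates, resetting (restarting) the relaxed step schedule each round to
    traverse the easy early phase quickly.  Cyclic subset updates orbit the
    optimum at a radius proportional to the step size, so the remaining
    rounds switch to a single subset (the same update rule, now an exact
    preconditioned projected gradient ascent) with a constant step, which
    converges to the constrained optimum to machine precision.  If a polish
    round ever decreases the objective, its step is halved and the round is
    repeated.

    Convergence requires the KKT residual (relative to the gradient
    sup-norm at the starting image) below ``kkt_tol`` and the relative
    objective change over the last round below ``obj_tol``; otherwise the
    final iterate is returned flagged ``trace.converged = False``.
    """
    if scheme is None:
        from .acquisition import make_subsets

        scheme = make_subsets(geom.n_views, cfg.n_subsets)
    if clock is None:
        clock = WallClock()
    g0 = full_grad(project_C(x0, object_mask), y, geom, factors, p).values
    g_scale = max(float(np.abs(g0[object_mask]).max()), 1e-30)
    trace = SolverTrace()
    x = x0
    for _ in range(max(warm_rounds, 0)):
        trace = bsrem(
            y, geom, factors, p, cfg, x, object_mask, scheme=scheme,
            clock=clock, k_offset=0, record_images=record_images, trace=trace,
        )
        x = trace.final
    from .acquisition import make_subsets as _mk

    one = _mk(geom.n_views, 1)
    alpha = cfg.schedule.alpha0
    prev_total = trace.totals[-1] if trace.totals else None
    prev_res = kkt_residual(x, y, geom, factors, p, object_mask) / g_scale
    for _ in range(max_restarts):
        polish_cfg = BsremConfig(
            schedule=StepSchedule(alpha0=alpha, eta=0.0),
            delta=cfg.delta,
            n_subsets=1,
            max_updates=cfg.max_updates,
            seed=cfg.seed,
        )
        candidate = SolverTrace()
        try:
            candidate = bsrem(
                y, geom, factors, p, polish_cfg, x, object_mask, scheme=one,
                clock=clock, record_images=record_images, trace=candidate,
            )
        except DivergenceError:
            alpha *= 0.5
            continue
        total = candidate.totals[-1]
        res = kkt_residual(
            candidate.final, y, geom, factors, p, object_mask
        ) / g_scale
        worse_obj = (
            prev_total is not None
            and total < prev_total - 1e-9 * abs(prev_total)
        )
        if (res >= prev_res or worse_obj) and res >= kkt_tol:
            # oscillating or stalled: discard the round, halve the step
            alpha *= 0.5
            continue
        # merge the accepted round into the public trace
        for i in range(len(candidate.updates)):
            trace.record(
                len(trace.updates) + 1,
                candidate.times[i],
                ObjectiveValue(
                    candidate.logliks[i], candidate.priors[i], p.beta
                ),
                candidate.snapshots[i] if record_images else None,
            )
        x = candidate.final
        obj_change = (
            abs(total - prev_total) / max(abs(total), 1.0)
            if prev_total is not None
            else np.inf
        )
        prev_total = total
        prev_res = res
        if res < kkt_tol and obj_change < obj_tol:
            trace.converged = True
            break
    trace.final = x
    return x, trace
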