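"""End-to-end challenge harness: simulate, reconstruct, score, rank.

This module is the library behind the command-line interface.  A dataset
directory written by :func:`build_dataset` is self-describing (resolved
config, images, sinograms, one Interfile-lite file per VOI) and sufficient
to re-run scoring and ranking without re-reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import interfile
from .acquisition import (
    AcquisitionFactors,
    ProjectionData,
    ProjectorGeometry,
    SubsetScheme,
    make_subsets,
    simulate_acquisition,
)
from .config import RunConfig
from .grids import ImageVolume
from .objective import PriorParams, epsilon_from_osem, kappa_from_osem
from .phantoms import PhantomScene, VoiSet, generate_phantom
from .scoring import (
    MetricTrace,
    Thresholds,
    compute_metric_trace,
    per_metric_pass_times,
    rank_algorithms,
)
from .solvers import (
    BsremConfig,
    SolverTrace,
    StepSchedule,
    VirtualClock,
    WallClock,
    bsrem,
    osem,
    osem_solver,
    reconstruct_reference,
    svrg_solver,
)

__all__ = [
    "Dataset",
    "Problem",
    "build_dataset",
    "load_dataset",
    "prepare_problem",
    "run_algorithm",
    "score_trace",
    "run_challenge",
]

log = logging.getLogger("petbench.pipeline")


@dataclass
class Dataset:
    """Everything the solvers need, as loaded from or written to disk."""

    cfg: RunConfig
    vois: VoiSet
    geom: ProjectorGeometry
    factors: AcquisitionFactors
    counts: ProjectionData
    activity: ImageVolume | None = None
    mu: ImageVolume | None = None
    reference: ImageVolume | None = None


@dataclass
class Problem:
    """Dataset plus derived reconstruction inputs (OSEM start, prior, scheme)."""

    dataset: Dataset
    scheme: SubsetScheme
    x_osem: ImageVolume
    prior: PriorParams
    delta: float
    thresholds: Thresholds


def _mask_to_image(mask: np.ndarray, voxel_size: tuple[float, ...]) -> ImageVolume:
    return ImageVolume(mask.astype(np.float64), voxel_size)


def _derived_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def build_dataset(cfg: RunConfig, out_dir: str | Path) -> Dataset:
    """Generate a phantom scene, simulate one acquisition, write it out."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dims = (cfg.size, cfg.size)
    scene = generate_phantom(
        cfg.phantom_kind,
        dims=dims,
        voxel_size=(cfg.voxel_size_mm,) * 2,
        contrast=cfg.contrast,
        seed=cfg.seed,
        erosion_iterations=cfg.erosion_iterations,
    )
    sim_seed, = _derived_seeds(cfg.seed + 1, 1)
    from .acquisition import default_geometry

    geom = default_geometry(
        scene, n_views=cfg.n_views if cfg.n_views > 0 else None
    )
    sim = simulate_acquisition(
        scene,
        geom=geom,
        counts_target=cfg.counts_target,
        background_fraction=cfg.background_fraction,
        efficiency=cfg.efficiency,
        dead_fraction=cfg.dead_fraction,
        seed=sim_seed,
    )
    interfile.write_image(sim.x_true, out / "activity")
    interfile.write_image(scene.mu, out / "mu")
    interfile.write_projdata(sim.counts, out / "counts")
    interfile.write_projdata(sim.factors.m, out / "mult_factors")
    interfile.write_projdata(sim.factors.a, out / "additive")
    vs = scene.activity.voxel_size
    for name, mask in scene.vois.items():
        interfile.write_image(_mask_to_image(mask, vs), out / f"VOI_{name}")
    cfg.to_ini(out / "config.ini")
    log.info("dataset written to %s (seed=%d)", out, cfg.seed)
    return Dataset(
        cfg=cfg,
        vois=scene.vois,
        geom=sim.geom,
        factors=sim.factors,
        counts=sim.counts,
        activity=sim.x_true,
        mu=scene.mu,
    )


def load_dataset(path: str | Path) -> Dataset:
    """Re-load a dataset directory written by :func:`build_dataset`."""
    path = Path(path)
    cfg = RunConfig.from_ini(path / "config.ini")
    counts = interfile.read_projdata(path / "counts", expect_counts=True)
    m = interfile.read_projdata(path / "mult_factors")
    a = interfile.read_projdata(path / "additive")
    factors = AcquisitionFactors(m=m, a=a)

    def _mask(name: str) -> np.ndarray:
        return interfile.read_image(path / f"VOI_{name}").values > 0.5

    targets = {}
    for f in sorted(path.glob("VOI_*.hv")):
        name = f.stem[len("VOI_") :]
        if name not in ("object", "whole_eroded", "background"):
            targets[name] = _mask(name)
    vois = VoiSet(
        object_mask=_mask("object"),
        whole_eroded=_mask("whole_eroded"),
        background=_mask("background"),
        targets=targets,
    )
    ds = Dataset(
        cfg=cfg,
        vois=vois,
        geom=counts.geom,
        factors=factors,
        counts=counts,
    )
    if (path / "activity.hv").exists():
        ds.activity = interfile.read_image(path / "activity")
    if (path / "mu.hv").exists():
        ds.mu = interfile.read_image(path / "mu")
    if (path / "reference.hv").exists():
        ds.reference = interfile.read_image(path / "reference")
    return ds


def prepare_problem(ds: Dataset) -> Problem:
    """Run the OSEM initialiser and derive kappa, epsilon and delta."""
    cfg = ds.cfg
    scheme = make_subsets(ds.geom.n_views, cfg.n_subsets)
    mask = ds.vois.object_mask
    x_osem = osem(
        ds.counts, ds.geom, ds.factors, scheme, cfg.osem_epochs, object_mask=mask
    )
    kappa = kappa_from_osem(x_osem, ds.counts, ds.geom, ds.factors)
    eps = epsilon_from_osem(x_osem, cfg.epsilon_rel)
    delta = cfg.delta_rel * float(x_osem.values.max())
    prior = PriorParams(beta=cfg.beta, kappa=kappa, gamma=cfg.gamma, epsilon=eps)
    th = Thresholds(
        whole_rmse=cfg.whole_rmse,
        background_rmse=cfg.background_rmse,
        voi_aem=cfg.voi_aem,
        persistence=cfg.persistence,
        time_cap=cfg.time_cap_s,
    )
    return Problem(
        dataset=ds,
        scheme=scheme,
        x_osem=x_osem,
        prior=prior,
        delta=delta,
        thresholds=th,
    )


def _make_clock(kind: str):
    return VirtualClock() if kind == "virtual" else WallClock()


def _solver_config(prob: Problem, seed: int, max_updates: int | None = None) -> BsremConfig:
    cfg = prob.dataset.cfg
    return BsremConfig(
        schedule=StepSchedule(alpha0=cfg.alpha0, eta=cfg.eta),
        delta=prob.delta,
        n_subsets=cfg.n_subsets,
        max_updates=max_updates or cfg.max_updates,
        seed=seed,
    )


def compute_reference(prob: Problem, clock=None) -> tuple[ImageVolume, SolverTrace]:
    """Converged BSREM reference image (restarted until KKT criteria hold)."""
    cfg = prob.dataset.cfg
    ds = prob.dataset
    scfg = _solver_config(prob, cfg.seed, max_updates=cfg.reference_max_updates)
    if clock is None:
        clock = _make_clock(cfg.clock)
    r, trace = reconstruct_reference(
        ds.counts,
        ds.geom,
        ds.factors,
        prob.prior,
        scfg,
        prob.x_osem,
        ds.vois.object_mask,
        scheme=prob.scheme,
        clock=clock,
        kkt_tol=cfg.kkt_tol,
        max_restarts=cfg.reference_max_restarts,
        record_images=False,
    )
    if not trace.converged:
        log.warning(
            "reference run exhausted its restart budget; image flagged non-reference"
        )
    return r, trace


def run_algorithm(
    name: str, prob: Problem, seed: int, clock=None, record_images: bool = True
) -> SolverTrace:
    """Run one challenger (``osem``, ``bsrem`` or ``svrg``) from the OSEM start."""
    ds = prob.dataset
    scfg = _solver_config(prob, seed)
    if clock is None:
        clock = _make_clock(ds.cfg.clock)
    common = dict(
        scheme=prob.scheme, clock=clock, record_images=record_images
    )
    if name == "osem":
        return osem_solver(
            ds.counts, ds.geom, ds.factors, prob.prior, scfg, prob.x_osem,
            ds.vois.object_mask, **common,
        )
    if name == "bsrem":
        return bsrem(
            ds.counts, ds.geom, ds.factors, prob.prior, scfg, prob.x_osem,
            ds.vois.object_mask, **common,
        )
    if name == "svrg":
        return svrg_solver(
            ds.counts, ds.geom, ds.factors, prob.prior, scfg, prob.x_osem,
            ds.vois.object_mask, **common,
        )
    raise ValueError(f"unknown algorithm {name!r} (expected osem, bsrem or svrg)")


def score_trace(
    trace: SolverTrace, reference: ImageVolume, vois: VoiSet, th: Thresholds
) -> MetricTrace:
    """Metric trace of a solver run against the reference image."""
    if not trace.snapshots:
        raise ValueError("trace holds no iterate snapshots to score")
    return compute_metric_trace(trace.snapshots, trace.times, reference, vois, th)


def _trace_csv(trace: SolverTrace, path: Path) -> None:
    pd.DataFrame(trace.to_rows()).to_csv(path, index=False, float_format="%.17g")


def run_challenge(cfg: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Full protocol: simulate, reference, all algorithms x n_runs, rank.

    Writes the dataset, the reference image, per-run solver and metric
    traces, the pass-time table, per-cell ranks and the leaderboard; the
    leaderboard DataFrame is returned.  With the default deterministic
    cost-model clock the whole output tree is bit-reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "petbench.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("petbench")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        ds = build_dataset(cfg, out)
        prob = prepare_problem(ds)
        interfile.write_image(prob.x_osem, out / "osem")
        interfile.write_image(prob.prior.kappa, out / "kappa")
        r, ref_trace = compute_reference(prob)
        interfile.write_image(r, out / "reference")
        _trace_csv(ref_trace, out / "reference_trace.csv")
        recon_dir = out / "recons"
        recon_dir.mkdir(exist_ok=True)
        run_seeds = _derived_seeds(cfg.seed + 2, cfg.n_runs * len(cfg.algorithm_list))
        rows = []
        i = 0
        for algo in cfg.algorithm_list:
            for run in range(cfg.n_runs):
                seed = run_seeds[i]
                i += 1
                log.info("running %s run %d (seed=%d)", algo, run, seed)
                trace = run_algorithm(algo, prob, seed)
                _trace_csv(trace, recon_dir / f"{algo}_run{run}_trace.csv")
                mt = score_trace(trace, r, ds.vois, prob.thresholds)
                mt.to_frame().to_csv(
                    recon_dir / f"{algo}_run{run}_metrics.csv",
                    index=False,
                    float_format="%.17g",
                )
                for metric, pt in per_metric_pass_times(mt, prob.thresholds).items():
                    rows.append(
                        {
                            "dataset": f"{cfg.phantom_kind}_{cfg.size}",
                            "metric": metric,
                            "algorithm": algo,
                            "run": run,
                            "time_s": pt.time_s,
                            "censored": pt.censored,
                        }
                    )
        times = pd.DataFrame(rows)
        times.to_csv(out / "pass_times.csv", index=False, float_format="%.17g")
        table = rank_algorithms(times, time_cap=prob.thresholds.time_cap)
        table.ranks.to_csv(out / "ranks.csv", float_format="%.17g")
        board = table.leaderboard()
        board.to_csv(out / "leaderboard.csv", float_format="%.17g")
        lines = ["rank  algorithm    mean_rank  sem"]
        for pos, (algo, row) in enumerate(board.iterrows(), start=1):
            lines.append(
                f"{pos:<5d} {algo:<12s} {row['mean_rank']:.4f}     {row['sem']:.4f}"
            )
        (out / "leaderboard.txt").write_text("\n".join(lines) + "\n")
        log.info("challenge complete; winner: %s", board.index[0])
        return board
    finally:
        root.removeHandler(handler)
        handler.close()
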