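"""Convergence metrics and ranking protocol.

An iterate theta is scored against the converged reference image r with
three normalised criteria, all divided by the reference background mean
MEAN(r; B):

* whole-object   RMSE(theta; r; W) / MEAN(r; B) < 0.01
* background     RMSE(theta; r; B) / MEAN(r; B) < 0.01
* per target VOI |MEAN(theta; R_i) - MEAN(r; R_i)| / MEAN(r; B) < 0.005

W is the marginally eroded whole-object VOI, B the background VOI.  An
algorithm "passes" at the timestamp of the first update that begins a run
of 10 consecutive passing updates; runs that never achieve this within the
time cap are censored at the cap.  For ranking, each (dataset, metric)
cell takes the median pass time over repeated runs, ranks the slowest
algorithm 1 and the fastest N (ties averaged), and an algorithm's overall
score is its mean rank across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import ImageVolume
from .phantoms import VoiSet

__all__ = [
    "Thresholds",
    "CriteriaResult",
    "MetricTrace",
    "PassTime",
    "RankTable",
    "rmse",
    "mean_in",
    "evaluate_criteria",
    "compute_metric_trace",
    "pass_time",
    "per_metric_pass_times",
    "rank_algorithms",
]


@dataclass(frozen=True)
class Thresholds:
    """Convergence thresholds, persistence rule and run-time cap."""

    whole_rmse: float = 0.01
    background_rmse: float = 0.01
    voi_aem: float = 0.005
    persistence: int = 10
    time_cap: float = 3600.0

    def __post_init__(self) -> None:
        if min(self.whole_rmse, self.background_rmse, self.voi_aem) <= 0:
            raise ValueError("thresholds must be > 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")
        if self.time_cap <= 0:
            raise ValueError("time_cap must be > 0")


def rmse(x: ImageVolume, r: ImageVolume, region: np.ndarray) -> float:
    """Voxel-wise root-mean-squared error of x against r over a region."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    if x.shape != r.shape or region.shape != x.shape:
        raise ValueError("image/region shapes do not match")
    d = x.values[region] - r.values[region]
    return float(np.sqrt(np.mean(d * d)))


def mean_in(x: ImageVolume, region: np.ndarray) -> float:
    """Arithmetic mean of x over the region's voxels."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    if region.shape != x.shape:
        raise ValueError("image/region shapes do not match")
    return float(np.mean(x.values[region]))


@dataclass(frozen=True)
class CriteriaResult:
    """Normalised metric values and the combined pass flag for one image."""

    whole: float
    background: float
    aem: dict[str, float]
    passed: bool
    normaliser: float


def evaluate_criteria(
    x: ImageVolume, r: ImageVolume, vois: VoiSet, th: Thresholds
) -> CriteriaResult:
    """Normalised whole/background RMSE and per-VOI AEM, with pass flag.

    All three are normalised by MEAN(r; B), which must be positive.  The
    image passes iff every criterion is strictly below its threshold.
    """
    norm = mean_in(r, vois.background)
    if norm <= 0:
        raise ValueError("reference background mean must be > 0")
    whole = rmse(x, r, vois.whole_eroded) / norm
    background = rmse(x, r, vois.background) / norm
    aem = {
        name: abs(mean_in(x, t) - mean_in(r, t)) / norm
        for name, t in vois.targets.items()
    }
    passed = (
        whole < th.whole_rmse
        and background < th.background_rmse
        and all(v < th.voi_aem for v in aem.values())
    )
    return CriteriaResult(
        whole=whole, background=background, aem=aem, passed=passed, normaliser=norm
    )


@dataclass
class MetricTrace:
    """Per-update criterion values for one solver run."""

    updates: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    whole: list[float] = field(default_factory=list)
    background: list[float] = field(default_factory=list)
    aem: list[dict[str, float]] = field(default_factory=list)
    passes: list[bool] = field(default_factory=list)
    normaliser: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.updates):
            row = {
                "update": u,
                "time_s": self.times[i],
                "whole": self.whole[i],
                "background": self.background[i],
                "passed": self.passes[i],
            }
            for name, v in self.aem[i].items():
                row[f"aem_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def compute_metric_trace(
    snapshots: list[np.ndarray],
    times: list[float],
    r: ImageVolume,
    vois: VoiSet,
    th: Thresholds,
    stride: int = 1,
) -> MetricTrace:
    """Score a sequence of iterate snapshots against the reference image."""
    if len(snapshots) != len(times):
        raise ValueError("snapshots and times must align")
    mt = MetricTrace()
    for i in range(0, len(snapshots), stride):
        img = r.with_values(snapshots[i])
        res = evaluate_criteria(img, r, vois, th)
        mt.updates.append(i + 1)
        mt.times.append(times[i])
        mt.whole.append(res.whole)
        mt.background.append(res.background)
        mt.aem.append(res.aem)
        mt.passes.append(res.passed)
        mt.normaliser = res.normaliser
    return mt


@dataclass(frozen=True)
class PassTime:
    """Time to convergence; censored runs carry the cap as their time."""

    time_s: float
    censored: bool
    update: int | None = None


def _first_sustained(
    updates: list[int],
    times: list[float],
    flags: list[bool],
    persistence: int,
    time_cap: float,
) -> PassTime:
    n = len(updates)
    for i in range(0, n - persistence + 1):
        if times[i + persistence - 1] > time_cap:
            break
        if all(flags[i : i + persistence]):
            return PassTime(time_s=times[i], censored=False, update=updates[i])
    return PassTime(time_s=time_cap, censored=True, update=None)


def pass_time(mt: MetricTrace, th: Thresholds) -> PassTime:
    """First timestamp from which `persistence` consecutive updates pass
    all three criteria jointly.

    Only updates whose timestamp is within the cap count.  The reported
    time is the timestamp of the FIRST update of the qualifying run.  If
    no qualifying run exists, the result is censored at the cap.
    """
    if not mt.updates:
        raise ValueError("metric trace is empty")
    return _first_sustained(mt.updates, mt.times, mt.passes, th.persistence, th.time_cap)


def per_metric_pass_times(mt: MetricTrace, th: Thresholds) -> dict[str, PassTime]:
    """Pass time of each individual criterion, for per-metric ranking cells.

    Keys are ``whole``, ``background`` and ``aem_<voi>``; each uses its own
    threshold with the same persistence rule and cap.
    """
    if not mt.updates:
        raise ValueError("metric trace is empty")
    out: dict[str, PassTime] = {}
    flags = [v < th.whole_rmse for v in mt.whole]
    out["whole"] = _first_sustained(mt.updates, mt.times, flags, th.persistence, th.time_cap)
    flags = [v < th.background_rmse for v in mt.background]
    out["background"] = _first_sustained(
        mt.updates, mt.times, flags, th.persistence, th.time_cap
    )
    for name in mt.aem[0]:
        flags = [d[name] < th.voi_aem for d in mt.aem]
        out[f"aem_{name}"] = _first_sustained(
            mt.updates, mt.times, flags, th.persistence, th.time_cap
        )
    return out


@dataclass(frozen=True)
class RankTable:
    """Per-cell ranks and mean rank per algorithm.

    ``ranks`` has one row per (dataset, metric) cell and one column per
    algorithm; ``mean_rank`` and ``sem`` summarise each algorithm across
    cells.  Rank N is best (fastest), rank 1 worst.
    """

    medians: pd.DataFrame
    ranks: pd.DataFrame
    mean_rank: pd.Series
    sem: pd.Series

    def leaderboard(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"mean_rank": self.mean_rank, "sem": self.sem}
        ).sort_values("mean_rank", ascending=False)
        out.index.name = "algorithm"
        return out


def rank_algorithms(times: pd.DataFrame, time_cap: float) -> RankTable:
    """Aggregate pass times into challenge ranks.

    ``times`` needs columns ``dataset, metric, algorithm, run, time_s,
    censored``.  Censored observations enter the median as the cap; any
    cell median at or above the cap is treated as censored and ties with
    other censored algorithms (averaged ranks), so censored algorithms
    never out-rank an uncensored one.
    """
    required = {"dataset", "metric", "algorithm", "run", "time_s", "censored"}
    missing = required - set(times.columns)
    if missing:
        raise ValueError(f"times table missing columns: {sorted(missing)}")
    df = times.copy()
    df["eff_time"] = np.where(
        df["censored"].astype(bool), time_cap, df["time_s"]
    ).clip(max=time_cap)
    algos = sorted(df["algorithm"].unique())
    per_cell = (
        df.groupby(["dataset", "metric", "algorithm"])["eff_time"]
        .median()
        .unstack("algorithm")
    )
    if per_cell.isna().any().any():
        raise ValueError("every algorithm must appear in every (dataset, metric) cell")
    per_cell = per_cell[algos]
    n = len(algos)
    rank_rows = []
    for _, row in per_cell.iterrows():
        vals = row.to_numpy(dtype=float)
        # ascending rankdata: smallest time -> 1; challenge wants fastest -> N
        rank_rows.append(n + 1 - rankdata(vals, method="average"))
    ranks = pd.DataFrame(rank_rows, index=per_cell.index, columns=algos)
    mean_rank = ranks.mean(axis=0)
    nc = len(ranks)
    sem = ranks.std(axis=0, ddof=1) / np.sqrt(nc) if nc > 1 else ranks.std(axis=0) * 0.0
    return RankTable(medians=per_cell, ranks=ranks, mean_rank=mean_rank, sem=sem)
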