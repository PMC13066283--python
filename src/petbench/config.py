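"""Run configuration: one flat key/value file with sections (INI).

Every command resolves its settings into a :class:`RunConfig`, writes the
fully resolved file next to its outputs for provenance, and can re-load it
bit-identically.  All defaults live here.
"""

from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # [phantom]
    phantom_kind: str = "nema_like"
    size: int = 64
    voxel_size_mm: float = 2.0
    contrast: float = 4.0
    erosion_iterations: int = 1
    # [acquisition]
    n_views: int = 0  # 0 -> derived from the grid (one view per row)
    counts_target: float = 1e6
    background_fraction: float = 0.2
    efficiency: float = 1.0
    dead_fraction: float = 0.01
    # [prior]
    beta: float = 1.0
    gamma: float = 2.0
    epsilon_rel: float = 1e-4
    # [solver]
    n_subsets: int = 8
    osem_epochs: int = 2
    alpha0: float = 0.1
    eta: float = 0.1
    delta_rel: float = 1e-6
    max_updates: int = 500
    reference_max_updates: int = 800
    reference_max_restarts: int = 10
    kkt_tol: float = 1e-5
    # [thresholds]
    whole_rmse: float = 0.01
    background_rmse: float = 0.01
    voi_aem: float = 0.005
    persistence: int = 10
    time_cap_s: float = 3600.0
    # [run]
    seed: int = 1
    n_runs: int = 3
    algorithms: str = "osem,bsrem,svrg"
    clock: str = "virtual"  # or "wall"

    _SECTIONS = {
        "phantom": (
            "phantom_kind",
            "size",
            "voxel_size_mm",
            "contrast",
            "erosion_iterations",
        ),
        "acquisition": (
            "n_views",
            "counts_target",
            "background_fraction",
            "efficiency",
            "dead_fraction",
        ),
        "prior": ("beta", "gamma", "epsilon_rel"),
        "solver": (
            "n_subsets",
            "osem_epochs",
            "alpha0",
            "eta",
            "delta_rel",
            "max_updates",
            "reference_max_updates",
            "reference_max_restarts",
            "kkt_tol",
        ),
        "thresholds": (
            "whole_rmse",
            "background_rmse",
            "voi_aem",
            "persistence",
            "time_cap_s",
        ),
        "run": ("seed", "n_runs", "algorithms", "clock"),
    }

    def validate(self) -> "RunConfig":
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if self.contrast <= 0 or self.beta <= 0:
            raise ValueError("contrast and beta must be > 0")
        if self.clock not in ("virtual", "wall"):
            raise ValueError("clock must be 'virtual' or 'wall'")
        if self.n_runs < 1 or self.persistence < 1:
            raise ValueError("n_runs and persistence must be >= 1")
        return self

    @property
    def algorithm_list(self) -> list[str]:
        return [a.strip() for a in self.algorithms.split(",") if a.strip()]

    def to_ini(self, path: str | Path) -> Path:
        cp = configparser.ConfigParser()
        values = asdict(self)
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: repr(values[k]) if isinstance(values[k], float) else str(values[k]) for k in keys}
        path = Path(path)
        with open(path, "w") as fh:
            cp.write(fh)
        return path

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(Path(path)):
            raise FileNotFoundError(path)
        kwargs: dict = {}
        defaults = cls()
        for section, keys in cls._SECTIONS.items():
            for k in keys:
                if section in cp and k in cp[section]:
                    raw = cp[section][k]
                    default = getattr(defaults, k)
                    if isinstance(default, bool):
                        kwargs[k] = raw.lower() in ("1", "true", "yes")
                    elif isinstance(default, int):
                        kwargs[k] = int(raw)
                    elif isinstance(default, float):
                        kwargs[k] = float(raw)
                    else:
                        kwargs[k] = raw
        return cls(**kwargs).validate()
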