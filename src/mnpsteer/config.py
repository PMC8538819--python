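"""Run configuration, initial-condition generation, sweeps and manifests.

One YAML config drives every workflow; it is schema-validated (unknown keys
rejected) before any computation.  ``generate_initial_conditions`` places
non-overlapping beads uniformly in the box (the in vitro droplet), and
``run_sweep`` executes the parameter grids of the aggregation study
(diameter / exposure time / coil current / suspension density).

The suspension density is specified in uL as in the experiments; the
particle count follows the documented linear convention
``count = round(PARTICLES_PER_UL * uL)``.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .actuation import ActuationScheme, CoilPair
from .aggregates import AggregateStats, aggregate_stats
from .dynamics import (
    DEFAULT_MSAT,
    IntegratorConfig,
    SimulationState,
    Trajectory,
    run,
)
from .forces import FluidMedium, Particle

__all__ = [
    "RunConfig",
    "InitialPlacement",
    "generate_initial_conditions",
    "run_simulation",
    "run_sweep",
    "sweep_grid_from_fixture",
    "density_to_count",
    "manifest",
    "PARTICLES_PER_UL",
]

#: Linear uL -> particle-count convention for scaled-down simulations.
PARTICLES_PER_UL = 4.0


def density_to_count(volume_uL: float, per_uL: float = PARTICLES_PER_UL) -> int:
    """Map a suspension volume (uL) to a simulated particle count."""
    return max(1, int(round(per_uL * volume_uL)))


class ParticleSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 60
    radius_m: float = 0.5e-6
    density_kg_m3: float = 2500.0
    msat_A_m: float = DEFAULT_MSAT


class MediumSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    viscosity_Pa_s: float = 1.0e-3
    density_kg_m3: float = 1000.0


class SchemeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scheme: str = "static"
    H_A: float = 3.0
    h_A: float = 1.0
    frequency_Hz: float = 1.0
    t_dis_s: float = 0.0


class IntegratorSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "overdamped"
    dt_s: float = 2.0e-4
    duration_s: float = 1.0
    output_stride: int = 250
    neighbor_cutoff_m: float = 12.0e-6
    remanence: float = 0.0


class AnalysisSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tolerance: float = 1.05


class RunConfig(BaseModel):
    """Schema-validated scenario configuration (YAML-serializable)."""

    model_config = ConfigDict(extra="forbid")
    scenario: str = "default"
    particles: ParticleSpec = Field(default_factory=ParticleSpec)
    medium: MediumSpec = Field(default_factory=MediumSpec)
    scheme: SchemeSpec = Field(default_factory=SchemeSpec)
    integrator: IntegratorSpec = Field(default_factory=IntegratorSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)
    box_um: float = 40.0
    min_separation_diameters: float = 1.5
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


@dataclass
class InitialPlacement:
    """Uniform random non-overlapping placement request."""

    n: int
    box: np.ndarray  # (2, 3) m
    min_separation: float = 1.5  # multiples of the particle diameter
    seed: int = 0


class PackingError(RuntimeError):
    """Requested placement is infeasible at the requested separation."""


def generate_initial_conditions(
    placement: InitialPlacement,
    radius: float = 0.5e-6,
    density: float = 2500.0,
) -> SimulationState:
    """Seeded uniform placement with all pairwise center distances at least
    ``min_separation`` diameters; fails loudly if the packing is infeasible
    (volume-fraction precheck plus bounded rejection sampling)."""
    box = np.asarray(placement.box, dtype=float)
    d = 2.0 * radius
    sep = placement.min_separation * d
    vol = float(np.prod(box[1] - box[0]))
    if placement.n * sep**3 >= 0.3 * vol:
        raise PackingError(
            f"{placement.n} particles at min separation {sep:g} m do not fit "
            f"in the box at a safe packing fraction"
        )
    rng = np.random.default_rng(placement.seed)
    lo = box[0] + radius
    hi = box[1] - radius
    placed: List[np.ndarray] = []
    attempts = 0
    max_attempts = 5000 * placement.n
    while len(placed) < placement.n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"rejection sampling failed after {max_attempts} attempts; "
                "reduce n or min_separation"
            )
        cand = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(cand - q) >= sep for q in placed):
            placed.append(cand)
    particles = [
        Particle(id=k, position=placed[k], radius=radius, density=density)
        for k in range(placement.n)
    ]
    return SimulationState(time=0.0, particles=particles, box=box)


def _build(config: RunConfig, seed: Optional[int] = None):
    seed = config.seed if seed is None else seed
    half = config.box_um * 1e-6 / 2.0
    box = np.array([[-half, -half, -half], [half, half, half]])
    state = generate_initial_conditions(
        InitialPlacement(
            n=config.particles.n,
            box=box,
            min_separation=config.min_separation_diameters,
            seed=seed,
        ),
        radius=config.particles.radius_m,
        density=config.particles.density_kg_m3,
    )
    medium = FluidMedium(
        viscosity=config.medium.viscosity_Pa_s, density=config.medium.density_kg_m3
    )
    scheme = ActuationScheme(
        scheme=config.scheme.scheme,
        H=config.scheme.H_A,
        h=config.scheme.h_A,
        frequency=config.scheme.frequency_Hz,
        t_dis=config.scheme.t_dis_s,
    )
    cutoff = max(
        config.integrator.neighbor_cutoff_m, 2.0 * config.particles.radius_m
    )
    cfg = IntegratorConfig(
        mode=config.integrator.mode,
        dt=config.integrator.dt_s,
        duration=config.integrator.duration_s,
        output_stride=config.integrator.output_stride,
        neighbor_cutoff=cutoff,
        seed=seed,
        remanence=config.integrator.remanence,
    )
    coils = CoilPair()
    return state, cfg, coils, scheme, medium


def run_simulation(config: RunConfig, seed: Optional[int] = None) -> Trajectory:
    """One full simulation from a validated config; deterministic per seed."""
    state, cfg, coils, scheme, medium = _build(config, seed)
    return run(state, cfg, coils, scheme, medium, msat=config.particles.msat_A_m)


def manifest(config: RunConfig, seed: int) -> Dict:
    """Reproducibility record: config hash, seed, library versions."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "mnpsteer": __version__,
            "numpy": np.__version__,
            "python": sys.version.split()[0],
        },
    }


def sweep_grid_from_fixture() -> pd.DataFrame:
    """Nominal values and ranges of the four aggregation parameters, loaded
    from the packaged fixture (diameter, time, current, density)."""
    path = resources.files("mnpsteer.data").joinpath("aggregation_parameters.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def run_sweep(
    config: RunConfig,
    sweep: Dict[str, Sequence[float]],
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Run one simulation per grid point per seed and report the final mean
    chain length.

    ``sweep`` maps parameter names (``diameter_um``, ``time_s``,
    ``current_A``, ``density_uL``) to value lists; per-point failures are
    recorded in the report and the sweep continues.
    """
    known = {"diameter_um", "time_s", "current_A", "density_uL"}
    unknown = set(sweep) - known
    if unknown:
        raise ValueError(f"unknown sweep parameters: {sorted(unknown)}")
    names = sorted(sweep)
    grids = [sweep[n] for n in names]
    rows = []
    for values in _product(grids):
        point = dict(zip(names, values))
        for seed in seeds:
            cfg = config.model_copy(deep=True)
            if "diameter_um" in point:
                cfg.particles.radius_m = point["diameter_um"] * 1e-6 / 2.0
            if "time_s" in point:
                cfg.integrator.duration_s = point["time_s"]
            if "current_A" in point:
                cfg.scheme.H_A = point["current_A"]
                if cfg.scheme.scheme == "dma":
                    cfg.scheme.h_A = point["current_A"]
                else:
                    cfg.scheme.h_A = min(cfg.scheme.h_A, point["current_A"])
            if "density_uL" in point:
                cfg.particles.n = density_to_count(point["density_uL"])
            row = dict(point, seed=seed)
            try:
                traj = run_simulation(cfg, seed=seed)
                stats = aggregate_stats(traj, tolerance=cfg.analysis.tolerance)
                row["final_mean_length_um"] = stats.mean_length[-1]
                row["final_n_clusters"] = stats.count[-1]
                row["error"] = ""
            except Exception as err:  # noqa: BLE001 - sweep must continue
                row["final_mean_length_um"] = np.nan
                row["final_n_clusters"] = -1
                row["error"] = f"{type(err).__name__}: {err}"
            rows.append(row)
    return pd.DataFrame(rows)


def _product(grids: List[Sequence[float]]):
    if not grids:
        yield ()
        return
    for head in grids[0]:
        for rest in _product(grids[1:]):
            yield (head, *rest)
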