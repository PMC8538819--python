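"""Scaled-down study protocols: aggregation trend sweeps and SMD orderings.

These functions reproduce, at desk scale, the qualitative parameter studies
of the aggregation experiments (exposure time, coil current, particle
diameter, continuous vs discontinuous actuation) and the coarse-grained
membrane-crossing comparisons (aggregate vs single particle, pull velocity,
particle size).  The mesoscale runs use 100 beads in a 28.5 um box — large
enough for stable chain statistics, small enough to run in minutes — and
chain lengths are time-averaged over short windows rather than read from a
single frame, which suppresses the frame-to-frame fluctuation of the mean
when marginal contacts open and close.

Absolute micrometre values are not comparable to the laboratory
measurements (material constants of the beads are not published); only the
orderings and ratios are meaningful, and those are what these protocols
report.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .aggregates import aggregate_stats
from .config import RunConfig, run_simulation
from . import membrane as mb

__all__ = [
    "trend_config",
    "window_mean_length",
    "time_trend",
    "current_trend",
    "diameter_trend",
    "disaggregation_comparison",
    "smd_ordering",
    "chain_pair_gap",
]

#: Study-condition defaults for the scaled-down aggregation sweeps.
N_PARTICLES = 100
BOX_UM = 28.5
FRAME_S = 0.02

TREND_CURRENTS_A = (0.5, 1.0, 2.0, 3.0)
TREND_DIAMETERS_UM = (0.5, 0.75, 1.0)
#: Exposure-time checkpoints (windows in s) inside the growth phase.
TIME_WINDOWS = ((0.06, 0.14), (0.30, 0.44), (0.95, 1.20))


def trend_config() -> RunConfig:
    cfg = RunConfig()
    cfg.particles.n = N_PARTICLES
    cfg.box_um = BOX_UM
    cfg.integrator.output_stride = int(round(FRAME_S / cfg.integrator.dt_s))
    return cfg


def window_mean_length(stats, t_lo: float, t_hi: float) -> float:
    """Mean chain length averaged over saved frames inside [t_lo, t_hi]."""
    t = np.asarray(stats.times)
    ml = np.asarray(stats.mean_length)
    sel = (t >= t_lo) & (t <= t_hi)
    if not np.any(sel):
        raise ValueError("no saved frames inside the requested window")
    return float(ml[sel].mean())


def _run_stats(cfg: RunConfig, seed: int):
    return aggregate_stats(run_simulation(cfg, seed=seed), tolerance=cfg.analysis.tolerance)


def time_trend(seeds: Sequence[int]) -> List[float]:
    """Seed-averaged mean chain length at three exposure-time checkpoints
    under static 3 A actuation; expected non-decreasing."""
    cfg = trend_config()
    cfg.integrator.duration_s = TIME_WINDOWS[-1][1]
    per_seed = []
    for s in seeds:
        st = _run_stats(cfg, s)
        per_seed.append([window_mean_length(st, lo, hi) for lo, hi in TIME_WINDOWS])
    return list(np.mean(per_seed, axis=0))


def current_trend(seeds: Sequence[int]) -> Tuple[List[float], float]:
    """Seed-averaged final chain length versus coil current, plus the
    Spearman rank correlation with current (expected 1)."""
    means = []
    for current in TREND_CURRENTS_A:
        cfg = trend_config()
        cfg.integrator.duration_s = 0.6
        cfg.scheme.H_A = current
        cfg.scheme.h_A = min(1.0, current)
        vals = [window_mean_length(_run_stats(cfg, s), 0.5, 0.6) for s in seeds]
        means.append(float(np.mean(vals)))
    rho = float(spearmanr(TREND_CURRENTS_A, means).statistic)
    return means, rho


def diameter_trend(seeds: Sequence[int]) -> Tuple[List[float], float]:
    """Seed-averaged final chain length versus bead diameter at 3 A, plus
    the Spearman rank correlation with diameter (expected 1)."""
    means = []
    for diameter in TREND_DIAMETERS_UM:
        cfg = trend_config()
        cfg.integrator.duration_s = 0.6
        cfg.particles.radius_m = diameter * 1e-6 / 2.0
        vals = [window_mean_length(_run_stats(cfg, s), 0.5, 0.6) for s in seeds]
        means.append(float(np.mean(vals)))
    rho = float(spearmanr(TREND_DIAMETERS_UM, means).statistic)
    return means, rho


def disaggregation_comparison(seeds: Sequence[int]) -> Tuple[float, float]:
    """(static, da-dma) seed-averaged final chain length at equal total
    time; discontinuous actuation is expected to yield shorter chains."""
    out = []
    for scheme in ("static", "da-dma"):
        cfg = trend_config()
        cfg.integrator.duration_s = 1.0
        cfg.scheme.scheme = scheme
        if scheme == "da-dma":
            cfg.scheme.frequency_Hz = 2.0
            cfg.scheme.t_dis_s = 0.5
        vals = [window_mean_length(_run_stats(cfg, s), 0.9, 1.0) for s in seeds]
        out.append(float(np.mean(vals)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Membrane-crossing comparisons

SMD_MEMBRANE_NX = 6
SMD_RADIUS_A = 5.0
SMD_SLOW = 0.03
SMD_FAST = 0.05


def _pull_work(part, velocity: float, seed: int) -> Tuple[float, float]:
    mem = mb.build_membrane(SMD_MEMBRANE_NX, SMD_MEMBRANE_NX, seed=seed)
    cfg = mb.SMDConfig(velocity=velocity, dt=2.0, gamma=0.05, equil_steps=250)
    res = mb.smd_pull(mem, part, cfg, seed=seed)
    return (
        mb.aufdc(res.curve),
        mb.lost_atom_fraction(res.membrane_before, res.membrane_after),
    )


def smd_ordering(seeds: Sequence[int]) -> Dict[str, float]:
    """Seed-averaged crossing work for the protocol comparisons:

    single particle at slow/fast pull velocity, a radius-doubled particle,
    and an orthogonal two-particle aggregate; also the worst lost-bead
    fraction across all runs.
    """
    acc: Dict[str, List[float]] = {k: [] for k in ("slow", "fast", "big", "aggregate")}
    lost_max = 0.0
    for seed in seeds:
        w, l1 = _pull_work(mb.build_particle(SMD_RADIUS_A), SMD_SLOW, seed)
        acc["slow"].append(w)
        w, l2 = _pull_work(mb.build_particle(SMD_RADIUS_A), SMD_FAST, seed)
        acc["fast"].append(w)
        w, l3 = _pull_work(mb.build_particle(2.0 * SMD_RADIUS_A), SMD_SLOW, seed)
        acc["big"].append(w)
        w, l4 = _pull_work(mb.build_aggregate(SMD_RADIUS_A, "orthogonal"), SMD_SLOW, seed)
        acc["aggregate"].append(w)
        lost_max = max(lost_max, l1, l2, l3, l4)
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["lost_fraction_max"] = lost_max
    return out


def chain_pair_gap(separation_m: float = 4.0e-6, duration_s: float = 0.2) -> Dict[str, float]:
    """Two beads released on the coil axis under a static field: they should
    close into a touching chain aligned with the field.

    Returns the final center gap relative to contact (expected 1) and the
    cosine of the chain axis with the coil axis (expected 1).
    """
    from .actuation import ActuationScheme, CoilPair
    from .dynamics import IntegratorConfig, SimulationState, run
    from .forces import FluidMedium, Particle

    radius = 0.5e-6
    box = np.array([[-2e-5] * 3, [2e-5] * 3])
    state = SimulationState(
        0.0,
        [
            Particle(0, [-separation_m / 2.0, 0.0, 0.0], radius=radius),
            Particle(1, [separation_m / 2.0, 0.0, 0.0], radius=radius),
        ],
        box,
    )
    cfg = IntegratorConfig(dt=2e-4, duration=duration_s, output_stride=100,
                           neighbor_cutoff=1.2e-5)
    traj = run(state, cfg, CoilPair(), ActuationScheme(scheme="static", H=3.0),
               FluidMedium())
    final = traj.frames[-1]
    r = final.particles[0].position - final.particles[1].position
    gap = float(np.linalg.norm(r))
    return {
        "separation_over_contact": gap / (2.0 * radius),
        "axis_alignment": float(abs(r[0]) / np.linalg.norm(r)),
    }
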