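"""Time integration of the mesoscale particle model.

Integrates the Newtonian force balance for N magnetic beads under the
two-coil actuation field.  Two modes:

``overdamped`` (default)
    Inertia dropped: the velocity is the mobility times the sum of the
    non-drag forces, v = vf + F / (6 pi eta R).  For micron beads in water
    the velocity relaxation time m/(6 pi eta R) is ~1e-7 s, far below any
    useful time step, so this limit is both faithful and cheap.

``inertial``
    Semi-implicit Euler with the Stokes drag treated implicitly in the
    velocity update (explicit drag is unstable once dt exceeds the
    relaxation time); recovers the overdamped limit exactly as
    dt >> m/(6 pi eta R).

Numerical guards: a per-step displacement cap (fraction of the particle's
own radius) and an optional pairwise overlap projection after each move —
the Hertzian contact equilibrium relaxes on ~ns scales that no mesoscale dt
resolves, so penetrations are removed geometrically instead of by stiff
springs.  Forces are accumulated in ascending particle-id order and all
updates are pure float64 array operations, so trajectories are reproducible
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .actuation import ActuationScheme, CoilPair, field_batch
from .forces import MU0, ContactParams, FluidMedium, Particle

__all__ = [
    "SimulationState",
    "IntegratorConfig",
    "Trajectory",
    "StabilityError",
    "neighbor_pairs",
    "step",
    "run",
    "DEFAULT_MSAT",
]

#: Default saturation magnetization (A/m) for silica-coated magnetite
#: composite beads; a config entry, not a measured value.
DEFAULT_MSAT = 5.0e4


class StabilityError(RuntimeError):
    """Raised when a step violates the overlap blow-up guard."""


@dataclass
class SimulationState:
    """Instantaneous system state: time, particles, axis-aligned box (m).

    ``box`` is a (2, 3) array of lower and upper corner.
    """

    time: float
    particles: List[Particle]
    box: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (2, 3):
            raise ValueError("box must be a (2, 3) array of lo/hi corners")
        if np.any(self.box[1] <= self.box[0]):
            raise ValueError("box upper corner must exceed lower corner")

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.particles])

    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.particles])

    def validate(self, overlap_guard: float = 0.5) -> None:
        """Check containment and the overlap blow-up guard."""
        pos = self.positions()
        if len(self.particles) == 0:
            return
        if np.any(pos < self.box[0] - 1e-12) or np.any(pos > self.box[1] + 1e-12):
            raise StabilityError("particle outside simulation box")
        rad = self.radii()
        pairs = _grid_pairs(pos, float(2.0 * rad.max()))
        for i, j in pairs:
            d = float(np.linalg.norm(pos[i] - pos[j]))
            overlap = rad[i] + rad[j] - d
            if overlap > overlap_guard * min(rad[i], rad[j]):
                raise StabilityError(
                    f"overlap {overlap:.3g} m between particles "
                    f"{self.particles[i].id} and {self.particles[j].id} exceeds "
                    f"the blow-up guard; reduce dt"
                )


@dataclass
class IntegratorConfig:
    """Integration parameters.

    ``max_move_fraction`` caps the per-step displacement at that fraction of
    each particle's own radius (None disables); ``remanence`` is the moment
    fraction retained during field-off intervals; ``project_overlaps``
    enables the geometric contact projection.
    """

    mode: str = "overdamped"
    dt: float = 2.0e-4
    neighbor_cutoff: float = 10.0e-6
    seed: int = 0
    duration: float = 1.0
    output_stride: int = 100
    max_move_fraction: Optional[float] = 0.25
    remanence: float = 0.0
    project_overlaps: bool = True
    chi: float = 3.0
    projection_sweeps: int = 6
    overlap_guard: float = 0.5
    extrapolate_field: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("overdamped", "inertial"):
            raise ValueError("mode must be 'overdamped' or 'inertial'")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")
        if not self.neighbor_cutoff > 0:
            raise ValueError("neighbor_cutoff must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")


# ---------------------------------------------------------------------------
# Neighbor search: uniform cell grid with cell edge = cutoff.


def _dense_pairs(pos: np.ndarray, cutoff: float) -> List[Tuple[int, int]]:
    """Vectorized all-pairs scan; identical output to the cell grid, faster
    for moderate N."""
    n = pos.shape[0]
    if n < 2:
        return []
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu, ju = np.triu_indices(n, k=1)
    keep = d2[iu, ju] <= cutoff * cutoff
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def _grid_pairs(pos: np.ndarray, cutoff: float) -> List[Tuple[int, int]]:
    n = pos.shape[0]
    if n < 2:
        return []
    if n <= 512:
        return _dense_pairs(pos, cutoff)
    cells = np.floor(pos / cutoff).astype(np.int64)
    buckets: dict = {}
    for idx in range(n):
        buckets.setdefault(tuple(cells[idx]), []).append(idx)
    pairs: List[Tuple[int, int]] = []
    offsets = [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ]
    cut2 = cutoff * cutoff
    for key, members in buckets.items():
        for off in offsets:
            other = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            if other not in buckets:
                continue
            if other < key:
                continue
            cand = buckets[other]
            if other == key:
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        i, j = members[a], members[b]
                        d2 = float(np.dot(pos[i] - pos[j], pos[i] - pos[j]))
                        if d2 <= cut2:
                            pairs.append((min(i, j), max(i, j)))
            else:
                for i in members:
                    for j in cand:
                        d2 = float(np.dot(pos[i] - pos[j], pos[i] - pos[j]))
                        if d2 <= cut2:
                            pairs.append((min(i, j), max(i, j)))
    pairs = sorted(set(pairs))
    return pairs


def neighbor_pairs(state: SimulationState, cutoff: float) -> List[Tuple[int, int]]:
    """Index pairs with inter-center distance <= cutoff (closed boundary),
    found with a uniform cell grid; set semantics, sorted ascending."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    return _grid_pairs(state.positions(), float(cutoff))


# ---------------------------------------------------------------------------
# Vectorized force evaluation on struct-of-arrays state.


class _Arrays:
    """Internal struct-of-arrays mirror of SimulationState."""

    def __init__(self, state: SimulationState):
        self.ids = np.array([p.id for p in state.particles], dtype=int)
        order = np.argsort(self.ids, kind="stable")
        ps = [state.particles[k] for k in order]
        self.ids = self.ids[order]
        self.pos = np.array([p.position for p in ps], dtype=float)
        self.vel = np.array([p.velocity for p in ps], dtype=float)
        self.rad = np.array([p.radius for p in ps], dtype=float)
        self.rho = np.array([p.density for p in ps], dtype=float)
        self.mom = np.array([p.moment for p in ps], dtype=float)
        self.allow_small = any(p.allow_brownian_scale for p in ps)
        self.box = state.box.copy()
        self.time = state.time

    @property
    def n(self) -> int:
        return self.ids.size

    def volume(self) -> np.ndarray:
        return (4.0 / 3.0) * np.pi * self.rad**3

    def to_state(self) -> SimulationState:
        particles = [
            Particle(
                id=int(self.ids[k]),
                position=self.pos[k].copy(),
                velocity=self.vel[k].copy(),
                radius=float(self.rad[k]),
                density=float(self.rho[k]),
                moment=self.mom[k].copy(),
                allow_brownian_scale=self.allow_small,
            )
            for k in range(self.n)
        ]
        return SimulationState(time=self.time, particles=particles, box=self.box.copy())


def _pair_terms(arr: _Arrays, ii: np.ndarray, jj: np.ndarray, mu1: float, k_contact: float):
    """Dipole + Hertz contact force on the first index of each pair
    (vectorized); also returns overlaps for the guard/projection."""
    if ii.size == 0:
        return None
    rij = arr.pos[ii] - arr.pos[jj]
    rn = np.linalg.norm(rij, axis=1)
    if np.any(rn == 0.0):
        raise StabilityError("coincident particle centers")
    rhat = rij / rn[:, None]
    mi = arr.mom[ii]
    mj = arr.mom[jj]
    mi_n = np.linalg.norm(mi, axis=1)
    mj_n = np.linalg.norm(mj, axis=1)
    f = np.zeros_like(rij)
    act = (mi_n > 0) & (mj_n > 0)
    if np.any(act):
        mih = mi[act] / mi_n[act, None]
        mjh = mj[act] / mj_n[act, None]
        rh = rhat[act]
        ci = np.einsum("ij,ij->i", rh, mih)
        cj = np.einsum("ij,ij->i", rh, mjh)
        cij = np.einsum("ij,ij->i", mih, mjh)
        pref = 3.0 * mu1 * mi_n[act] * mj_n[act] / (4.0 * np.pi * rn[act] ** 4)
        f[act] = pref[:, None] * (
            cij[:, None] * rh
            + cj[:, None] * mih
            + ci[:, None] * mjh
            - 5.0 * (ci * cj)[:, None] * rh
        )
    overlap = np.maximum(0.0, arr.rad[ii] + arr.rad[jj] - rn)
    has = overlap > 0
    if np.any(has):
        f[has] += (k_contact * overlap[has] ** 1.5)[:, None] * rhat[has]
    return ii, jj, f, overlap, rhat


def _wall_force(arr: _Arrays, k_contact: float) -> np.ndarray:
    """Hertzian contact against the box walls (same power law vs a plane)."""
    f = np.zeros_like(arr.pos)
    for ax in range(3):
        lo = arr.pos[:, ax] - arr.box[0, ax]
        hi = arr.box[1, ax] - arr.pos[:, ax]
        d_lo = np.maximum(0.0, arr.rad - lo)
        d_hi = np.maximum(0.0, arr.rad - hi)
        f[:, ax] += k_contact * d_lo**1.5
        f[:, ax] -= k_contact * d_hi**1.5
    return f


def _nondrag_forces(
    arr: _Arrays,
    ii: np.ndarray,
    jj: np.ndarray,
    cfg: IntegratorConfig,
    coils: CoilPair,
    scheme: ActuationScheme,
    medium: FluidMedium,
    contact: ContactParams,
    msat: float,
) -> np.ndarray:
    vol = arr.volume()
    H, J = field_batch(
        arr.pos, arr.time, coils, scheme, msat, extrapolate=cfg.extrapolate_field
    )
    hn = np.linalg.norm(H, axis=1)
    on = hn > 0
    # instantaneous induced moments, M = min(chi |H|, Msat) along the field
    # (remanent fraction of the saturated value when the field is off)
    new_mom = np.zeros_like(arr.mom)
    if np.any(on):
        mag = vol[on] * np.minimum(cfg.chi * hn[on], msat)
        new_mom[on] = (mag / hn[on])[:, None] * H[on]
    if cfg.remanence > 0 and np.any(~on):
        old_n = np.linalg.norm(arr.mom[~on], axis=1)
        keep = old_n > 0
        sub = np.zeros_like(arr.mom[~on])
        sub[keep] = (cfg.remanence * vol[~on][keep] * msat / old_n[keep])[:, None] * arr.mom[
            ~on
        ][keep]
        new_mom[~on] = sub
    arr.mom = new_mom

    f = np.zeros_like(arr.pos)
    if np.any(on):
        hhat = H[on] / hn[on][:, None]
        grad_term = np.einsum("nab,nb->na", J[on], hhat)
        f[on] += (medium.permeability * vol[on] * msat)[:, None] * grad_term
    f += (vol * (arr.rho - medium.density))[:, None] * medium.gravity[None, :]
    f += _wall_force(arr, contact.stiffness)
    terms = _pair_terms(arr, ii, jj, medium.permeability, contact.stiffness)
    if terms is not None:
        fp = terms[2]
        np.add.at(f, ii, fp)
        np.add.at(f, jj, -fp)
    return f


def _fluid_velocities(arr: _Arrays, medium: FluidMedium) -> np.ndarray:
    if medium.velocity_field is None:
        return np.zeros_like(arr.pos)
    return np.array([medium.velocity_field(x) for x in arr.pos], dtype=float)


def _project_overlaps(arr: _Arrays, ii: np.ndarray, jj: np.ndarray, sweeps: int) -> None:
    """Damped Jacobi projection pushing overlapping pairs back to contact."""
    if ii.size == 0:
        return
    target = arr.rad[ii] + arr.rad[jj]
    for _ in range(sweeps):
        rij = arr.pos[ii] - arr.pos[jj]
        rn = np.linalg.norm(rij, axis=1)
        overlap = target - rn
        active = overlap > 0
        if not np.any(active):
            break
        shift = np.zeros_like(rij)
        shift[active] = (0.5 * 0.8 * overlap[active] / rn[active])[:, None] * rij[active]
        np.add.at(arr.pos, ii, shift)
        np.add.at(arr.pos, jj, -shift)


def _advance(
    arr: _Arrays,
    cfg: IntegratorConfig,
    coils: CoilPair,
    scheme: ActuationScheme,
    medium: FluidMedium,
    contact: ContactParams,
    msat: float,
) -> None:
    pairs = _grid_pairs(arr.pos, cfg.neighbor_cutoff)
    if pairs:
        ii = np.array([p[0] for p in pairs], dtype=int)
        jj = np.array([p[1] for p in pairs], dtype=int)
    else:
        ii = jj = np.zeros(0, dtype=int)
    f = _nondrag_forces(arr, ii, jj, cfg, coils, scheme, medium, contact, msat)
    vf = _fluid_velocities(arr, medium)
    gamma = 6.0 * np.pi * medium.viscosity * arr.rad  # drag coefficient
    if cfg.mode == "overdamped":
        v = vf + f / gamma[:, None]
    else:
        mass = arr.rho * arr.volume()
        r = cfg.dt * gamma / mass  # dt / relaxation time
        v = (arr.vel + cfg.dt * f / mass[:, None] + r[:, None] * vf) / (1.0 + r)[:, None]
    disp = v * cfg.dt
    if cfg.max_move_fraction is not None:
        dn = np.linalg.norm(disp, axis=1)
        cap = cfg.max_move_fraction * arr.rad
        scale = np.where(dn > cap, np.where(dn > 0, cap / np.maximum(dn, 1e-300), 1.0), 1.0)
        disp = disp * scale[:, None]
        v = disp / cfg.dt
    arr.pos = arr.pos + disp
    arr.vel = v
    if cfg.project_overlaps:
        _project_overlaps(arr, ii, jj, cfg.projection_sweeps)
    # keep spheres inside the box
    arr.pos = np.clip(arr.pos, arr.box[0] + arr.rad[:, None], arr.box[1] - arr.rad[:, None])
    arr.time = arr.time + cfg.dt
    # blow-up guard (the step displacement cap guarantees any new overlap
    # involves a pair already inside the neighbor cutoff)
    if ii.size:
        d = np.linalg.norm(arr.pos[ii] - arr.pos[jj], axis=1)
        overlap = arr.rad[ii] + arr.rad[jj] - d
        guard = cfg.overlap_guard * np.minimum(arr.rad[ii], arr.rad[jj])
        bad = overlap > guard
        if np.any(bad):
            k = int(np.argmax(overlap - guard))
            raise StabilityError(
                f"overlap {overlap[k]:.3g} m between particles {arr.ids[ii[k]]} "
                f"and {arr.ids[jj[k]]} at t={arr.time:.6g} s exceeds the "
                "blow-up guard; reduce dt"
            )


def step(
    state: SimulationState,
    cfg: IntegratorConfig,
    coils: CoilPair,
    scheme: ActuationScheme,
    medium: FluidMedium,
    contact: Optional[ContactParams] = None,
    msat: float = DEFAULT_MSAT,
) -> SimulationState:
    """Advance the state by one time step; deterministic given its inputs."""
    if contact is None:
        contact = default_contact(state)
    arr = _Arrays(state)
    _advance(arr, cfg, coils, scheme, medium, contact, msat)
    return arr.to_state()


def default_contact(state: SimulationState) -> ContactParams:
    """Hertz stiffness from the default effective modulus (1e7 Pa) and the
    mean particle radius."""
    rad = state.radii()
    reff = float(rad.mean()) / 2.0 if rad.size else 0.25e-6
    return ContactParams.from_modulus(1.0e7, reff)


@dataclass
class Trajectory:
    """Saved frames of a run, with CSV/XYZ export and lossless round-trip."""

    frames: List[SimulationState]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            for p in f.particles:
                rows.append(
                    dict(
                        time=f.time,
                        id=p.id,
                        x=p.position[0],
                        y=p.position[1],
                        z=p.position[2],
                        vx=p.velocity[0],
                        vy=p.velocity[1],
                        vz=p.velocity[2],
                        radius=p.radius,
                        density=p.density,
                    )
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        box = self.frames[0].box
        with open(path, "w") as fh:
            fh.write(
                "# box "
                + " ".join(repr(float(v)) for v in box.ravel())
                + "\n"
            )
            df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            header = fh.readline()
            box = np.array([float(v) for v in header.split()[2:]]).reshape(2, 3)
            df = pd.read_csv(fh, float_precision="round_trip")
        frames = []
        for t, grp in df.groupby("time", sort=True):
            particles = [
                Particle(
                    id=int(r.id),
                    position=np.array([r.x, r.y, r.z]),
                    velocity=np.array([r.vx, r.vy, r.vz]),
                    radius=float(r.radius),
                    density=float(r.density),
                )
                for r in grp.itertuples()
            ]
            frames.append(SimulationState(time=float(t), particles=particles, box=box))
        return cls(frames=frames)

    def to_xyz(self, path, scale: float = 1e6) -> None:
        """XYZ export (positions scaled to micrometres by default)."""
        with open(path, "w") as fh:
            for f in self.frames:
                fh.write(f"{len(f.particles)}\n")
                fh.write(f"t={f.time:.9g}\n")
                for p in f.particles:
                    x, y, z = p.position * scale
                    fh.write(f"P{p.id} {x:.9g} {y:.9g} {z:.9g}\n")


def run(
    initial: SimulationState,
    cfg: IntegratorConfig,
    coils: CoilPair,
    scheme: ActuationScheme,
    medium: FluidMedium,
    contact: Optional[ContactParams] = None,
    msat: float = DEFAULT_MSAT,
) -> Trajectory:
    """Integrate from ``initial`` for ``cfg.duration``, saving every
    ``cfg.output_stride`` steps (plus the initial and final states)."""
    if contact is None:
        contact = default_contact(initial)
    if initial.particles:
        max_rad = max(p.radius for p in initial.particles)
        if cfg.neighbor_cutoff < 2.0 * max_rad:
            raise ValueError("neighbor_cutoff must be at least twice the max radius")
    arr = _Arrays(initial)
    n_steps = int(round(cfg.duration / cfg.dt))
    frames = [arr.to_state()]
    for k in range(1, n_steps + 1):
        try:
            _advance(arr, cfg, coils, scheme, medium, contact, msat)
        except StabilityError as err:
            raise StabilityError(f"{err} (failing step at t={arr.time:.6g} s)") from err
        if k % cfg.output_stride == 0 or k == n_steps:
            frames.append(arr.to_state())
    return Trajectory(frames=frames)
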