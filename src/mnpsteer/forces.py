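"""Mesoscale force model for micron-scale magnetic particles in a viscous fluid.

Newtonian dynamics of magnetic nanoparticle (MNP) beads large enough
(diameter > 500 nm) that Brownian motion is negligible.  The net force on a
particle is the sum of five terms:

* **magnetic (actuation) force** — a magnetized sphere in a field gradient,
  F = (4/3) pi mu1 R^3 Msat (grad H acting along the field direction);
* **dipole–dipole force** — the point-dipole interaction that drives
  chain-shaped aggregation, decaying as r^-4;
* **Stokes drag** — F = -6 pi eta R (vp - vf);
* **gravity/buoyancy** — F = (4/3) pi R^3 (rho_p - rho_b) G;
* **Hertzian contact** — normal repulsion k * delta^(3/2) on overlap.

All quantities are SI.  These are pure functions; the integrator in
:mod:`mnpsteer.dynamics` composes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "MU0",
    "DEFAULT_CHI",
    "Particle",
    "FluidMedium",
    "MagneticSample",
    "ContactParams",
    "sphere_volume",
    "induced_moment",
    "saturated_moment",
    "magnetic_force",
    "dipole_force",
    "drag_force",
    "gravity_buoyancy_force",
    "contact_force",
    "net_force",
]

#: Vacuum permeability, H/m.  Water is effectively non-magnetic, so the fluid
#: permeability defaults to this value.
MU0 = 4.0e-7 * np.pi

#: Minimum radius (m) below which Brownian forces, which this model excludes,
#: would matter (diameter 500 nm threshold).
BROWNIAN_RADIUS = 250e-9

_ZERO3 = np.zeros(3)


def _vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {v}")
    return v


def sphere_volume(radius: float) -> float:
    """Volume of a sphere of the given radius."""
    return (4.0 / 3.0) * np.pi * radius**3


@dataclass
class Particle:
    """One mesoscale magnetic bead.

    Parameters
    ----------
    id : int
        Stable identifier; pair forces are accumulated in ascending id order.
    position, velocity : (3,) array, m and m/s
    radius : float, m
        Must exceed the Brownian exclusion threshold (250 nm) unless
        ``allow_brownian_scale`` is set.
    density : float, kg/m^3
    moment : (3,) array, A m^2
        Magnetic moment; usually set each step from the local field via
        :func:`saturated_moment`.
    """

    id: int
    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.5e-6
    density: float = 2500.0
    moment: np.ndarray = field(default_factory=lambda: np.zeros(3))
    allow_brownian_scale: bool = False

    def __post_init__(self) -> None:
        self.position = _vec3(self.position, "position")
        self.velocity = _vec3(self.velocity, "velocity")
        self.moment = _vec3(self.moment, "moment")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not self.density > 0:
            raise ValueError("density must be positive")
        if self.radius < BROWNIAN_RADIUS and not self.allow_brownian_scale:
            raise ValueError(
                f"radius {self.radius:g} m is below the 250 nm Brownian "
                "exclusion threshold; pass allow_brownian_scale=True to "
                "override"
            )

    @property
    def volume(self) -> float:
        return sphere_volume(self.radius)

    @property
    def mass(self) -> float:
        return self.density * self.volume


@dataclass
class FluidMedium:
    """Carrier fluid: viscosity eta, density rho_b, permeability mu1,
    a prescribed velocity field vf(x) (default: quiescent) and gravity G."""

    viscosity: float = 1.0e-3
    density: float = 1000.0
    permeability: float = MU0
    velocity_field: Optional[Callable[[np.ndarray], np.ndarray]] = None
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -9.81]))

    def __post_init__(self) -> None:
        self.gravity = _vec3(self.gravity, "gravity")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")
        if not self.permeability > 0:
            raise ValueError("permeability must be positive")

    def fluid_velocity(self, position: np.ndarray) -> np.ndarray:
        if self.velocity_field is None:
            return _ZERO3
        return np.asarray(self.velocity_field(position), dtype=float)


@dataclass
class MagneticSample:
    """Local field sample: intensity H (A/m), its spatial Jacobian
    grad H (A/m^2, ``gradient[a, b] = dH_a/dx_b``) and the particle-material
    saturation magnetization Msat (A/m)."""

    intensity: np.ndarray
    gradient: np.ndarray
    saturation: float

    def __post_init__(self) -> None:
        self.intensity = _vec3(self.intensity, "intensity")
        g = np.asarray(self.gradient, dtype=float)
        if g.shape != (3, 3):
            raise ValueError("gradient must be a 3x3 tensor")
        if not np.all(np.isfinite(g)):
            raise ValueError("gradient must be finite")
        self.gradient = g


@dataclass
class ContactParams:
    """Hertzian normal-contact stiffness k (N/m^1.5).

    ``from_modulus`` derives k = (4/3) E* sqrt(R_eff) from an effective
    Young's modulus, the package's documented default route.
    """

    stiffness: float

    def __post_init__(self) -> None:
        if not self.stiffness > 0:
            raise ValueError("stiffness must be positive")

    @classmethod
    def from_modulus(cls, effective_modulus: float, effective_radius: float) -> "ContactParams":
        return cls(stiffness=(4.0 / 3.0) * effective_modulus * np.sqrt(effective_radius))


#: Effective susceptibility of a high-permeability sphere (demagnetization
#: limit); magnetization is M = min(chi |H|, Msat).
DEFAULT_CHI = 3.0


def induced_moment(
    p: Particle,
    sample: MagneticSample,
    remanence: float = 0.0,
    chi: float = DEFAULT_CHI,
) -> np.ndarray:
    """Field-induced moment of a magnetizable bead.

    Magnitude V * min(chi |H|, Msat) aligned with the local field: linear
    response with the sphere-limit susceptibility at the mT-scale fields of
    the coil rig, saturating at Msat in strong fields.  With the field off
    the moment drops to ``remanence`` times the saturated value along the
    previous moment direction (default 0 — full demagnetization during the
    off intervals of discontinuous actuation).
    """
    msat = sample.saturation
    h = sample.intensity
    hn = float(np.linalg.norm(h))
    if hn > 0.0:
        mag = p.volume * min(chi * hn, msat)
        return mag * h / hn
    mn = float(np.linalg.norm(p.moment))
    if remanence > 0.0 and mn > 0.0:
        return remanence * p.volume * msat * p.moment / mn
    return np.zeros(3)


def saturated_moment(
    p: Particle, sample: MagneticSample, remanence: float = 0.0
) -> np.ndarray:
    """Fully saturated moment (magnitude V * Msat along the field); the
    strong-field limit of :func:`induced_moment`."""
    return induced_moment(p, sample, remanence=remanence, chi=np.inf)


def magnetic_force(p: Particle, sample: MagneticSample, medium: FluidMedium) -> np.ndarray:
    """Actuation force on a magnetized sphere in a field gradient.

    F = (4/3) pi mu1 R^3 Msat (h_hat . grad) H, i.e. the field-gradient
    tensor contracted along the unit field direction.  Zero in a uniform
    field and zero when the field itself vanishes (no moment to act on).
    """
    g = sample.gradient
    h = sample.intensity
    hn = float(np.linalg.norm(h))
    if hn == 0.0 or not np.any(g):
        return np.zeros(3)
    hhat = h / hn
    return medium.permeability * sphere_volume(p.radius) * sample.saturation * (g @ hhat)


def dipole_force(pi: Particle, pj: Particle, medium: FluidMedium) -> np.ndarray:
    """Point-dipole interaction force on ``pi`` due to ``pj``.

    F_i = (3 mu1 |mi||mj| / 4 pi r^4) [ (mi_hat.mj_hat) r_hat
          + (r_hat.mj_hat) mi_hat + (r_hat.mi_hat) mj_hat
          - 5 r_hat (r_hat.mi_hat)(r_hat.mj_hat) ],   r_hat from j to i.

    Exactly the negative gradient of
    U = (mu1 / 4 pi r^3)[mi.mj - 3 (mi.r_hat)(mj.r_hat)]; head-to-tail
    co-aligned moments attract, which is what chains rely on.
    """
    r = pi.position - pj.position
    rn = float(np.linalg.norm(r))
    if rn == 0.0:
        raise ValueError("coincident particle centers: dipole force singular")
    mi_n = float(np.linalg.norm(pi.moment))
    mj_n = float(np.linalg.norm(pj.moment))
    if mi_n == 0.0 or mj_n == 0.0:
        return np.zeros(3)
    rhat = r / rn
    mi_hat = pi.moment / mi_n
    mj_hat = pj.moment / mj_n
    ci = float(rhat @ mi_hat)
    cj = float(rhat @ mj_hat)
    cij = float(mi_hat @ mj_hat)
    pref = 3.0 * medium.permeability * mi_n * mj_n / (4.0 * np.pi * rn**4)
    return pref * (cij * rhat + cj * mi_hat + ci * mj_hat - 5.0 * ci * cj * rhat)


def drag_force(p: Particle, medium: FluidMedium) -> np.ndarray:
    """Stokes drag, F = -6 pi eta R (vp - vf(x))."""
    vf = medium.fluid_velocity(p.position)
    return -6.0 * np.pi * medium.viscosity * p.radius * (p.velocity - vf)


def gravity_buoyancy_force(p: Particle, medium: FluidMedium) -> np.ndarray:
    """Net gravitational force with buoyancy, F = (4/3) pi R^3 (rho_p - rho_b) G."""
    return sphere_volume(p.radius) * (p.density - medium.density) * medium.gravity


def contact_force(pi: Particle, pj: Particle, params: ContactParams) -> np.ndarray:
    """Hertzian normal contact on ``pi``: k delta^(3/2) along the center line
    from ``pj`` to ``pi``; zero without overlap (d >= Ri + Rj)."""
    r = pi.position - pj.position
    d = float(np.linalg.norm(r))
    if d == 0.0:
        raise ValueError("coincident particle centers: contact force undefined")
    delta = pi.radius + pj.radius - d
    if delta <= 0.0:
        return np.zeros(3)
    return params.stiffness * delta**1.5 * (r / d)


def net_force(
    p: Particle,
    others: Sequence[Particle],
    sample: MagneticSample,
    medium: FluidMedium,
    params: ContactParams,
) -> np.ndarray:
    """Sum of all five force terms on ``p`` given its interaction partners."""
    f = (
        magnetic_force(p, sample, medium)
        + drag_force(p, medium)
        + gravity_buoyancy_force(p, medium)
    )
    for q in others:
        if q is p or q.id == p.id:
            raise ValueError("net_force: particle must not appear in `others`")
        f = f + dipole_force(p, q, medium) + contact_force(p, q, params)
    return f
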