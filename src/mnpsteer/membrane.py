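"""Coarse-grained steered membrane-crossing engine.

A bead-spring surrogate of a POPC lipid bilayer is pulled through by a
rigid magnetite particle (or a two-particle aggregate) attached to a
harmonic guide moving at constant velocity — the steered-molecular-dynamics
(SMD) protocol.  The recorded membrane-on-particle force versus guide
displacement gives the force-displacement curve, whose area (AUFDC) is the
crossing-work criterion used to compare particle sizes, velocities and
aggregate orientations.

Interaction forms (all forces are exact negative gradients of their
potentials):

* bonds       V = kb (b - b0)^2
* angles      V = ktheta (theta - theta0)^2
* dihedrals   V = kphi (1 + cos(n phi - delta))
* impropers   V = komega (omega - omega0)^2
* Van der Waals   V = 4 eps [(sigma/r)^12 - (sigma/r)^6], CHARMM switching
  between 10 and 12 A for membrane-membrane pairs
* electrostatic   V = q1 q2 / (4 pi eps0 r), truncated with the
  particle-membrane cutoff (16.7 A)

Unit system of this module: angstrom, femtosecond, kcal/mol, g/mol,
elementary charge, kelvin.  The mesoscale modules use SI; conversion
helpers are exported here.

The nanoparticle is rigid (its internal forces are never computed): surface
interaction sites carry the Fe3O4 partial charges (+1.68 tetrahedral Fe,
+1.60 octahedral Fe, -1.22 O) in a 1:2:4 cycle so every 7-site block is
neutral.  Thermostatting is Langevin (BAOAB) on the membrane beads at
310 K; the lateral box is fixed and edge lipids are tethered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "KB_KCAL",
    "COULOMB_K",
    "ACC",
    "kcal_per_mol_per_A_to_N",
    "kcal_per_mol_to_J",
    "ForceFieldParams",
    "MembraneModel",
    "RigidParticleModel",
    "SMDConfig",
    "ForceDisplacementCurve",
    "SMDResult",
    "SMDInstabilityError",
    "build_membrane",
    "relax",
    "bonded_forces",
    "nonbonded_forces",
    "build_particle",
    "build_aggregate",
    "smd_pull",
    "aufdc",
    "lost_atom_fraction",
]

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.001987204259
#: 1/(4 pi eps0) in kcal mol^-1 A e^-2.
COULOMB_K = 332.0637
#: Acceleration conversion: a [A/fs^2] = ACC * F [kcal/mol/A] / m [g/mol].
ACC = 4.184e-4

FE3O4_CHARGE_CYCLE = (1.68, 1.60, 1.60, -1.22, -1.22, -1.22, -1.22)


def kcal_per_mol_per_A_to_N(f: float) -> float:
    """Force conversion to newtons (per molecule)."""
    return f * 4184.0 / 6.02214076e23 / 1e-10


def kcal_per_mol_to_J(e: float) -> float:
    """Energy conversion to joules (per molecule)."""
    return e * 4184.0 / 6.02214076e23


class SMDInstabilityError(RuntimeError):
    """Energy/velocity blow-up during pulling; reduce dt."""


# ---------------------------------------------------------------------------
# Force-field parameters and models


@dataclass
class ForceFieldParams:
    """Coarse-grained force-field constants (kcal/mol, A, rad).

    Bead types: ``H`` head (charged -q), ``M`` mid/glycerol (+q), ``T``
    tail.  ``theta0`` below pi gives each lipid a planar zigzag whose
    dihedral is well-defined (a perfectly straight chain would make the
    torsion degenerate).
    """

    kb: float = 5.0
    b0: float = 5.0
    ktheta: float = 5.0
    theta0: float = float(np.deg2rad(165.0))
    kphi: float = 1.0
    nphi: int = 1
    delta: float = 0.0
    komega: float = 2.0
    omega0: float = float(np.pi)
    bead_eps: dict = field(
        default_factory=lambda: {"H": 0.30, "M": 0.30, "T": 0.35}
    )
    bead_sigma: dict = field(
        default_factory=lambda: {"H": 5.0, "M": 4.6, "T": 4.6}
    )
    bead_charge: dict = field(
        default_factory=lambda: {"H": -0.20, "M": 0.20, "T": 0.0}
    )
    bead_mass: dict = field(
        default_factory=lambda: {"H": 100.0, "M": 90.0, "T": 80.0}
    )

    def validate(self) -> None:
        if min(self.kb, self.ktheta, self.komega) < 0 or self.kphi < 0:
            raise ValueError("force constants must be non-negative")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.nphi < 1:
            raise ValueError("dihedral periodicity must be >= 1")
        if any(s <= 0 for s in self.bead_sigma.values()):
            raise ValueError("sigma must be positive")
        if not 0 < self.theta0 < np.pi:
            raise ValueError("theta0 must lie in (0, pi)")


@dataclass
class MembraneModel:
    """Bead-spring bilayer patch.

    ``positions`` (N, 3) in A; per-bead ``types``/``masses``/``charges``/
    ``eps``/``sigma``; bonded topology index arrays; edge-lipid anchor
    tethers (harmonic, ``anchor_k |x - ref|^2``).
    """

    positions: np.ndarray
    types: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray
    impropers: np.ndarray
    params: ForceFieldParams
    lateral_size: Tuple[float, float]
    masses: np.ndarray
    charges: np.ndarray
    eps: np.ndarray
    sigma: np.ndarray
    anchor_idx: np.ndarray
    anchor_ref: np.ndarray
    anchor_k: float = 2.0

    def __post_init__(self):
        n = self.positions.shape[0]
        for name in ("bonds", "angles", "dihedrals", "impropers"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} reference beads outside the model")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "MembraneModel":
        return replace(
            self,
            positions=self.positions.copy(),
            anchor_ref=self.anchor_ref.copy(),
        )

    def z_range(self) -> Tuple[float, float]:
        return float(self.positions[:, 2].min()), float(self.positions[:, 2].max())

    def exclusion_pairs(self) -> set:
        if not hasattr(self, "_excl"):
            self._excl = {(int(i), int(j)) for i, j in self.bonds} | {
                (int(j), int(i)) for i, j in self.bonds
            }
        return self._excl

    def to_xyz(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_beads}\n")
            fh.write("coarse-grained bilayer\n")
            for t, (x, y, z) in zip(self.types, self.positions):
                fh.write(f"{t} {x:.6f} {y:.6f} {z:.6f}\n")


BEADS_PER_LIPID = 4
_LIPID_TYPES = ("H", "M", "T", "T")


def build_membrane(
    nx: int,
    ny: int,
    params: Optional[ForceFieldParams] = None,
    seed: int = 0,
    spacing: float = 7.8,
    jitter: float = 0.3,
    anchor_k: float = 2.0,
) -> MembraneModel:
    """Build an nx x ny x 2 coarse-lipid bilayer patch, centered laterally
    on the origin with its mid-plane at z = 0.

    Each lipid is a 4-bead planar zigzag (head + three tail beads) built at
    its bonded equilibrium geometry; leaflets are mirror images with heads
    facing outward.  ``jitter`` applies a small seeded rigid lateral shift
    per lipid.  Edge-column lipids are tethered to their build positions.
    Deterministic for a given seed.
    """
    if nx < 2 or ny < 2:
        raise ValueError("need nx, ny >= 2")
    p = params or ForceFieldParams()
    p.validate()
    rng = np.random.default_rng(seed)
    alpha = 0.5 * (np.pi - p.theta0)
    dz = p.b0 * np.cos(alpha)
    s = p.b0 * np.sin(alpha)
    # leaflet tail tips must sit near the tail-bead LJ contact distance
    gap = p.bead_sigma["T"] + 0.2
    z_head = 3.0 * dz + 0.5 * gap

    positions, types, bonds, angles, dihedrals, impropers = [], [], [], [], [], []
    anchor_lipids = []
    lipid = 0
    for leaflet in (+1, -1):
        for i in range(nx):
            for j in range(ny):
                x0 = (i - 0.5 * (nx - 1)) * spacing
                y0 = (j - 0.5 * (ny - 1)) * spacing
                shift = rng.normal(0.0, jitter, size=2) if jitter > 0 else np.zeros(2)
                base = len(positions)
                zsgn = leaflet
                beads = [
                    (x0 + shift[0], y0 + shift[1], zsgn * z_head),
                    (x0 + shift[0] + s, y0 + shift[1], zsgn * (z_head - dz)),
                    (x0 + shift[0], y0 + shift[1], zsgn * (z_head - 2 * dz)),
                    (x0 + shift[0] + s, y0 + shift[1], zsgn * (z_head - 3 * dz)),
                ]
                positions.extend(beads)
                types.extend(_LIPID_TYPES)
                bonds += [(base, base + 1), (base + 1, base + 2), (base + 2, base + 3)]
                angles += [
                    (base, base + 1, base + 2),
                    (base + 1, base + 2, base + 3),
                ]
                dihedrals.append((base, base + 1, base + 2, base + 3))
                impropers.append((base, base + 1, base + 2, base + 3))
                if i in (0, nx - 1) or j in (0, ny - 1):
                    anchor_lipids.extend(range(base, base + BEADS_PER_LIPID))
                lipid += 1

    pos = np.asarray(positions, dtype=float)
    types_arr = np.asarray(types)
    model = MembraneModel(
        positions=pos,
        types=types_arr,
        bonds=np.asarray(bonds, dtype=int),
        angles=np.asarray(angles, dtype=int),
        dihedrals=np.asarray(dihedrals, dtype=int),
        impropers=np.asarray(impropers, dtype=int),
        params=p,
        lateral_size=(nx * spacing, ny * spacing),
        masses=np.array([p.bead_mass[t] for t in types]),
        charges=np.array([p.bead_charge[t] for t in types]),
        eps=np.array([p.bead_eps[t] for t in types]),
        sigma=np.array([p.bead_sigma[t] for t in types]),
        anchor_idx=np.asarray(anchor_lipids, dtype=int),
        anchor_ref=pos[np.asarray(anchor_lipids, dtype=int)].copy(),
        anchor_k=anchor_k,
    )
    return model


# ---------------------------------------------------------------------------
# Bonded terms (forces are analytic negative gradients, checked against
# finite differences in the test suite)


def _bond_terms(pos, bonds, kb, b0):
    ri = pos[bonds[:, 0]]
    rj = pos[bonds[:, 1]]
    d = ri - rj
    b = np.linalg.norm(d, axis=1)
    if np.any(b < 1e-8):
        raise ValueError("zero-length bond")
    e = float(np.sum(kb * (b - b0) ** 2))
    # dV/db = 2 kb (b - b0); force on i = -dV/db * d_hat
    fmag = -2.0 * kb * (b - b0)
    f = np.zeros_like(pos)
    fi = (fmag / b)[:, None] * d
    np.add.at(f, bonds[:, 0], fi)
    np.add.at(f, bonds[:, 1], -fi)
    return f, e


def _angle_terms(pos, angles, kt, t0):
    ri = pos[angles[:, 0]]
    rj = pos[angles[:, 1]]
    rk = pos[angles[:, 2]]
    u = ri - rj
    v = rk - rj
    un = np.linalg.norm(u, axis=1)
    vn = np.linalg.norm(v, axis=1)
    uh = u / un[:, None]
    vh = v / vn[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(1.0 - c * c)
    if np.any(s < 1e-8):
        raise ValueError("collinear angle triple: angle force undefined")
    theta = np.arccos(c)
    e = float(np.sum(kt * (theta - t0) ** 2))
    dv = 2.0 * kt * (theta - t0)
    dthet_di = (c[:, None] * uh - vh) / (un * s)[:, None]
    dthet_dk = (c[:, None] * vh - uh) / (vn * s)[:, None]
    f = np.zeros_like(pos)
    fi = -dv[:, None] * dthet_di
    fk = -dv[:, None] * dthet_dk
    np.add.at(f, angles[:, 0], fi)
    np.add.at(f, angles[:, 2], fk)
    np.add.at(f, angles[:, 1], -(fi + fk))
    return f, e


def _torsion_geometry(pos, quads):
    r1 = pos[quads[:, 0]]
    r2 = pos[quads[:, 1]]
    r3 = pos[quads[:, 2]]
    r4 = pos[quads[:, 3]]
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=1)
    n2n = np.linalg.norm(n2, axis=1)
    if np.any(n1n < 1e-8) or np.any(n2n < 1e-8):
        raise ValueError("degenerate (collinear) torsion quadruple")
    b2n = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(
        np.einsum("ij,ij->i", np.cross(n1, n2), b2 / b2n[:, None]),
        np.einsum("ij,ij->i", n1, n2),
    )
    # angle gradients (standard torsion derivatives)
    dphi_d1 = -(b2n / n1n**2)[:, None] * n1
    dphi_d4 = (b2n / n2n**2)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / b2n**2
    c32 = np.einsum("ij,ij->i", b3, b2) / b2n**2
    dphi_d2 = -(1.0 + c12)[:, None] * dphi_d1 + c32[:, None] * dphi_d4
    dphi_d3 = c12[:, None] * dphi_d1 - (1.0 + c32)[:, None] * dphi_d4
    return phi, (dphi_d1, dphi_d2, dphi_d3, dphi_d4)


def _dihedral_terms(pos, quads, kphi, n, delta):
    phi, grads = _torsion_geometry(pos, quads)
    e = float(np.sum(kphi * (1.0 + np.cos(n * phi - delta))))
    dv = -kphi * n * np.sin(n * phi - delta)
    f = np.zeros_like(pos)
    for col, g in enumerate(grads):
        np.add.at(f, quads[:, col], -dv[:, None] * g)
    return f, e


def _improper_terms(pos, quads, kw, w0):
    w, grads = _torsion_geometry(pos, quads)
    dw = np.mod(w - w0 + np.pi, 2.0 * np.pi) - np.pi  # wrap into (-pi, pi]
    e = float(np.sum(kw * dw**2))
    dv = 2.0 * kw * dw
    f = np.zeros_like(pos)
    for col, g in enumerate(grads):
        np.add.at(f, quads[:, col], -dv[:, None] * g)
    return f, e


def bonded_forces(m: MembraneModel) -> Tuple[np.ndarray, float]:
    """Per-bead bonded forces and the total bonded potential energy
    (bonds + angles + dihedrals + impropers)."""
    p = m.params
    total_f = np.zeros_like(m.positions)
    total_e = 0.0
    if m.bonds.size:
        f, e = _bond_terms(m.positions, m.bonds, p.kb, p.b0)
        total_f += f
        total_e += e
    if m.angles.size:
        f, e = _angle_terms(m.positions, m.angles, p.ktheta, p.theta0)
        total_f += f
        total_e += e
    if m.dihedrals.size:
        f, e = _dihedral_terms(m.positions, m.dihedrals, p.kphi, p.nphi, p.delta)
        total_f += f
        total_e += e
    if m.impropers.size:
        f, e = _improper_terms(m.positions, m.impropers, p.komega, p.omega0)
        total_f += f
        total_e += e
    return total_f, total_e


def _anchor_forces(m: MembraneModel) -> Tuple[np.ndarray, float]:
    f = np.zeros_like(m.positions)
    if m.anchor_idx.size == 0:
        return f, 0.0
    d = m.positions[m.anchor_idx] - m.anchor_ref
    f[m.anchor_idx] = -2.0 * m.anchor_k * d
    return f, float(m.anchor_k * np.sum(d * d))


# ---------------------------------------------------------------------------
# Non-bonded terms


def _switching(r, ron, roff):
    """CHARMM switching function and its radial derivative."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > ron) & (r < roff)
    denom = (roff**2 - ron**2) ** 3
    rm = r[mid]
    a = roff**2 - rm**2
    s[mid] = a**2 * (roff**2 + 2.0 * rm**2 - 3.0 * ron**2) / denom
    ds[mid] = 12.0 * rm * a * (ron**2 - rm**2) / denom
    s[r >= roff] = 0.0
    return s, ds


def _lj(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    v = 4.0 * eps * (sr6 * sr6 - sr6)
    dv = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return v, dv


def membrane_nonbonded(
    m: MembraneModel, ron: float = 10.0, roff: float = 12.0
) -> Tuple[np.ndarray, float]:
    """Membrane-membrane Lennard-Jones with switching between ``ron`` and
    ``roff``; directly bonded pairs are excluded."""
    pos = m.positions
    n = m.n_beads
    if n < 2:
        return np.zeros_like(pos), 0.0
    d = cdist(pos, pos)
    iu, ju = np.triu_indices(n, k=1)
    r = d[iu, ju]
    within = r < roff
    iu, ju, r = iu[within], ju[within], r[within]
    if np.any(r < 1e-6):
        raise ValueError("overlapping beads (r -> 0) in non-bonded evaluation")
    excl = m.exclusion_pairs()
    keep = np.fromiter(
        ((int(a), int(b)) not in excl for a, b in zip(iu, ju)),
        dtype=bool,
        count=iu.size,
    )
    iu, ju, r = iu[keep], ju[keep], r[keep]
    eps = np.sqrt(m.eps[iu] * m.eps[ju])
    sig = 0.5 * (m.sigma[iu] + m.sigma[ju])
    v, dv = _lj(r, eps, sig)
    s, ds = _switching(r, ron, roff)
    e = float(np.sum(v * s))
    dtot = dv * s + v * ds  # d(V S)/dr
    rij = pos[iu] - pos[ju]
    f = np.zeros_like(pos)
    fi = (-dtot / r)[:, None] * rij
    np.add.at(f, iu, fi)
    np.add.at(f, ju, -fi)
    return f, e


# ---------------------------------------------------------------------------
# Rigid particle


@dataclass
class RigidParticleModel:
    """Rigid magnetite particle: charged LJ sites on the sphere surface
    (body frame), a pose, and lumped mass/inertia.  Internal forces are
    never computed (rigidity assumption)."""

    body_sites: np.ndarray
    site_charges: np.ndarray
    site_eps: np.ndarray
    site_sigma: np.ndarray
    radius: float
    sphere_centers: np.ndarray
    mass: float
    inertia: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def n_sites(self) -> int:
        return self.body_sites.shape[0]

    def world_sites(self) -> np.ndarray:
        return self.position[None, :] + self.body_sites @ self.rotation.T

    def axial_extent(self, axis=(0.0, 0.0, 1.0)) -> float:
        """Extent of the rigid body's spheres along ``axis``."""
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        proj = (self.sphere_centers @ self.rotation.T) @ a
        return float(proj.max() - proj.min() + 2.0 * self.radius)

    def copy(self) -> "RigidParticleModel":
        return replace(
            self, position=self.position.copy(), rotation=self.rotation.copy()
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


FE3O4_DENSITY_G_CM3 = 5.2


def _sphere_sites(radius: float, area_per_block: float = 60.0):
    n_blocks = max(1, int(round(4.0 * np.pi * radius**2 / area_per_block)))
    n_sites = 7 * n_blocks
    sites = radius * _fibonacci_sphere(n_sites)
    charges = np.array(
        [FE3O4_CHARGE_CYCLE[k % 7] for k in range(n_sites)], dtype=float
    )
    return sites, charges


def _particle_from_centers(
    centers: np.ndarray, radius: float, site_eps: float = 0.15, site_sigma: float = 3.5
) -> RigidParticleModel:
    all_sites, all_q = [], []
    for c in centers:
        s, q = _sphere_sites(radius)
        all_sites.append(s + c)
        all_q.append(q)
    sites = np.concatenate(all_sites)
    q = np.concatenate(all_q)
    vol = len(centers) * (4.0 / 3.0) * np.pi * radius**3  # A^3
    mass = FE3O4_DENSITY_G_CM3 * 0.6022 * vol  # g/mol (0.6022 = NA * 1e-24)
    per_sphere = mass / len(centers)
    inertia = sum(
        0.4 * per_sphere * radius**2 + per_sphere * float(np.dot(c, c)) for c in centers
    )
    return RigidParticleModel(
        body_sites=sites,
        site_charges=q,
        site_eps=np.full(sites.shape[0], site_eps),
        site_sigma=np.full(sites.shape[0], site_sigma),
        radius=radius,
        sphere_centers=np.asarray(centers, dtype=float),
        mass=mass,
        inertia=inertia,
    )


def build_particle(radius: float) -> RigidParticleModel:
    """Single rigid sphere with charged surface sites (1:2:4 Fe_tet:Fe_oct:O
    charge cycle, exactly neutral)."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    return _particle_from_centers(np.zeros((1, 3)), radius)


def build_aggregate(radius: float, orientation: str = "orthogonal") -> RigidParticleModel:
    """Two tangent rigid spheres; center line along the membrane normal
    (``orthogonal``) or in the membrane plane (``parallel``)."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    if orientation == "orthogonal":
        axis = np.array([0.0, 0.0, 1.0])
    elif orientation == "parallel":
        axis = np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError("orientation must be 'orthogonal' or 'parallel'")
    centers = np.array([-radius * axis, radius * axis])
    return _particle_from_centers(centers, radius)


# ---------------------------------------------------------------------------
# Particle-membrane interaction


def particle_membrane_forces(
    m: MembraneModel, p: RigidParticleModel, cutoff: float = 16.7
) -> Tuple[np.ndarray, np.ndarray, float]:
    """LJ (Lorentz-Berthelot mixing) + Coulomb between particle sites and
    membrane beads, truncated at ``cutoff``.

    Returns (site forces, bead forces, energy).
    """
    sites = p.world_sites()
    f_sites = np.zeros_like(sites)
    f_beads = np.zeros_like(m.positions)
    if m.n_beads == 0:
        return f_sites, f_beads, 0.0
    d = cdist(sites, m.positions)
    si, bi = np.nonzero(d < cutoff)
    if si.size == 0:
        return f_sites, f_beads, 0.0
    r = d[si, bi]
    if np.any(r < 1e-6):
        raise ValueError("overlapping particle site and membrane bead")
    eps = np.sqrt(p.site_eps[si] * m.eps[bi])
    sig = 0.5 * (p.site_sigma[si] + m.sigma[bi])
    v, dv = _lj(r, eps, sig)
    qq = COULOMB_K * p.site_charges[si] * m.charges[bi]
    v_c = qq / r
    dv_c = -qq / r**2
    e = float(np.sum(v + v_c))
    dtot = dv + dv_c
    rij = sites[si] - m.positions[bi]
    fi = (-dtot / r)[:, None] * rij
    np.add.at(f_sites, si, fi)
    np.add.at(f_beads, bi, -fi)
    return f_sites, f_beads, e


def nonbonded_forces(
    m: MembraneModel,
    p: Optional[RigidParticleModel] = None,
    cfg: Optional["SMDConfig"] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """All non-bonded forces: membrane-membrane LJ with switching, plus
    particle-membrane LJ + Coulomb if a particle is given.

    Returns (bead forces, site forces, total energy).
    """
    c = cfg or SMDConfig()
    f_beads, e = membrane_nonbonded(m, ron=c.switch_on, roff=c.pair_cutoff)
    f_sites = np.zeros((0, 3))
    if p is not None:
        fs, fb, ep = particle_membrane_forces(m, p, cutoff=c.particle_cutoff)
        f_beads = f_beads + fb
        f_sites = fs
        e += ep
    return f_beads, f_sites, e


# ---------------------------------------------------------------------------
# Relaxation (energy minimization)


def total_membrane_energy_grad(m: MembraneModel, flat_pos: np.ndarray):
    pos0 = m.positions
    m.positions = flat_pos.reshape(-1, 3)
    try:
        fb, eb = bonded_forces(m)
        fn, en = membrane_nonbonded(m)
        fa, ea = _anchor_forces(m)
    finally:
        m.positions = pos0
    f = fb + fn + fa
    return eb + en + ea, -f.ravel()


def relax(m: MembraneModel, maxiter: int = 300) -> MembraneModel:
    """Energy-minimized copy of the membrane (L-BFGS with analytic
    gradients over bonded + non-bonded + anchor terms)."""
    out = m.copy()
    res = minimize(
        lambda x: total_membrane_energy_grad(out, x),
        out.positions.ravel(),
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=maxiter),
    )
    out.positions = res.x.reshape(-1, 3)
    return out


# ---------------------------------------------------------------------------
# SMD pulling


@dataclass
class SMDConfig:
    """Constant-velocity pulling protocol.

    ``velocity`` in A/fs (protocol values 0.03-0.05), ``spring_k`` in
    kcal/mol/A^2 (default 15), pull ``direction`` the membrane normal,
    Langevin thermostat at ``temperature`` K with friction ``gamma`` 1/fs.
    """

    velocity: float = 0.04
    spring_k: float = 15.0
    direction: Tuple[float, float, float] = (0.0, 0.0, -1.0)
    temperature: float = 310.0
    dt: float = 5.0
    gamma: float = 0.02
    pair_cutoff: float = 12.0
    switch_on: float = 10.0
    particle_cutoff: float = 16.7
    rotate: bool = True
    particle_damping: float = 0.01
    clearance: float = 4.0
    standoff: float = 3.0
    equil_steps: int = 200
    record_stride: int = 5
    max_steps: int = 200_000

    def __post_init__(self):
        if not self.velocity > 0:
            raise ValueError("pull velocity must be positive")
        if not self.spring_k > 0:
            raise ValueError("spring constant must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class ForceDisplacementCurve:
    """Guide displacement (A) versus membrane-on-particle axial resistance
    force (kcal/mol/A)."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.size != self.force.size:
            raise ValueError("displacement and force must have equal length")
        if self.displacement.size >= 2 and np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            dict(displacement_A=self.displacement, force_kcal_mol_A=self.force)
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForceDisplacementCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            displacement=df["displacement_A"].to_numpy(),
            force=df["force_kcal_mol_A"].to_numpy(),
        )


@dataclass
class SMDResult:
    """Outcome of a pulling run: the force-displacement curve plus the
    membrane state before/after crossing (for integrity checks)."""

    curve: ForceDisplacementCurve
    membrane_before: Optional[MembraneModel]
    membrane_after: Optional[MembraneModel]
    particle: RigidParticleModel


def _rodrigues(axis_angle: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(axis_angle))
    if angle < 1e-12:
        return np.eye(3)
    k = axis_angle / angle
    kx = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]], dtype=float
    )
    return np.eye(3) + np.sin(angle) * kx + (1.0 - np.cos(angle)) * (kx @ kx)


def _check_finite(v: np.ndarray, label: str) -> None:
    if not np.all(np.isfinite(v)) or np.any(np.abs(v) > 1.0):
        raise SMDInstabilityError(
            f"{label} blew up during SMD pulling; reduce dt or the pull velocity"
        )


def smd_pull(
    m: Optional[MembraneModel],
    p: RigidParticleModel,
    cfg: Optional[SMDConfig] = None,
    seed: int = 0,
) -> SMDResult:
    """Pull a rigid particle through the membrane at constant guide velocity.

    A one-dimensional harmonic guide of stiffness ``spring_k``, attached to
    the particle's reference point along the pull axis, moves at
    ``velocity``; membrane beads evolve under Langevin (BAOAB) dynamics at
    ``temperature`` while the rigid particle translates (and optionally
    rotates) under the membrane and spring forces.  The membrane-on-particle
    axial force is recorded against guide displacement until the particle
    clears the far leaflet.  Deterministic for a given seed.

    ``m=None`` runs the free-pulling control (no membrane force at all).
    """
    cfg = cfg or SMDConfig()
    rng = np.random.default_rng(seed)
    d_hat = np.asarray(cfg.direction, dtype=float)
    d_hat = d_hat / np.linalg.norm(d_hat)

    part = p.copy()
    if m is not None:
        mem = m.copy()
        zmin, zmax = mem.z_range()
        entry_z = zmax if d_hat[2] <= 0 else zmin
        # place the particle just outside the membrane on the approach side
        start = np.array([0.0, 0.0, entry_z]) - d_hat * (
            0.5 * part.axial_extent(d_hat) + cfg.standoff
        )
        part.position = start
        vel = np.zeros_like(mem.positions)
        inv_m = 1.0 / mem.masses[:, None]
        c1 = np.exp(-cfg.gamma * cfg.dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        v_th = np.sqrt(ACC * KB_KCAL * cfg.temperature / mem.masses)[:, None]

        def bead_forces(with_particle: bool):
            fb, eb = bonded_forces(mem)
            fn, en = membrane_nonbonded(mem, cfg.switch_on, cfg.pair_cutoff)
            fa, ea = _anchor_forces(mem)
            f = fb + fn + fa
            fs = np.zeros((part.n_sites, 3))
            if with_particle:
                fsp, fbp, _ = particle_membrane_forces(mem, part, cfg.particle_cutoff)
                f = f + fbp
                fs = fsp
            return f, fs

        # short Langevin equilibration of the membrane alone
        f, _ = bead_forces(False)
        for _ in range(cfg.equil_steps):
            vel += 0.5 * cfg.dt * ACC * f * inv_m
            mem.positions += 0.5 * cfg.dt * vel
            vel = c1 * vel + c2 * v_th * rng.standard_normal(vel.shape)
            mem.positions += 0.5 * cfg.dt * vel
            f, _ = bead_forces(False)
            _check_finite(vel, "membrane velocity")
        membrane_before = mem.copy()
        travel_target = (
            cfg.standoff
            + (zmax - zmin)
            + part.axial_extent(d_hat)
            + cfg.clearance
        )
    else:
        mem = None
        membrane_before = None
        part.position = np.zeros(3)
        travel_target = 30.0

    a0 = float(part.position @ d_hat)
    v_part = np.zeros(3)
    omega = np.zeros(3)
    disp_rec: List[float] = []
    force_rec: List[float] = []
    acc_force = 0.0
    acc_n = 0
    t = 0.0
    damp = np.exp(-cfg.particle_damping * cfg.dt)

    if mem is not None:
        f_beads, f_sites = bead_forces(True)
    else:
        f_beads = None
        f_sites = np.zeros((part.n_sites, 3))
    for step_i in range(cfg.max_steps):
        f_mem_on_part = f_sites.sum(axis=0)
        guide_a = a0 + cfg.velocity * t
        spring = cfg.spring_k * (guide_a - float(part.position @ d_hat)) * d_hat
        f_part = f_mem_on_part + spring

        # record axial resistance (positive opposes the pull direction)
        acc_force += float(-f_mem_on_part @ d_hat)
        acc_n += 1
        if (step_i + 1) % cfg.record_stride == 0:
            disp_rec.append(cfg.velocity * (t + cfg.dt))
            force_rec.append(acc_force / acc_n)
            acc_force = 0.0
            acc_n = 0

        # rigid particle: damped velocity Verlet (translation + rotation)
        v_part = damp * (v_part + cfg.dt * ACC * f_part / part.mass)
        part.position = part.position + cfg.dt * v_part
        if cfg.rotate and part.n_sites > 1:
            torque = np.cross(part.world_sites() - part.position, f_sites).sum(axis=0)
            omega = damp * (omega + cfg.dt * ACC * torque / part.inertia)
            part.rotation = _rodrigues(omega * cfg.dt) @ part.rotation

        # membrane beads: BAOAB Langevin step (one force eval per step)
        if mem is not None:
            vel += 0.5 * cfg.dt * ACC * f_beads * inv_m
            mem.positions += 0.5 * cfg.dt * vel
            vel = c1 * vel + c2 * v_th * rng.standard_normal(vel.shape)
            mem.positions += 0.5 * cfg.dt * vel
            f_beads, f_sites = bead_forces(True)
            vel += 0.5 * cfg.dt * ACC * f_beads * inv_m
            _check_finite(vel, "membrane velocity")
        _check_finite(v_part, "particle velocity")

        t += cfg.dt
        if float(part.position @ d_hat) - a0 >= travel_target:
            break
    else:
        raise SMDInstabilityError(
            "pulling did not complete within max_steps; check the configuration"
        )

    curve = ForceDisplacementCurve(
        displacement=np.asarray(disp_rec), force=np.asarray(force_rec)
    )
    return SMDResult(
        curve=curve,
        membrane_before=membrane_before,
        membrane_after=mem.copy() if mem is not None else None,
        particle=part,
    )


def aufdc(curve: ForceDisplacementCurve) -> float:
    """Area under the force-displacement curve (trapezoidal), kcal/mol —
    the crossing-work criterion."""
    if curve.displacement.size < 2:
        raise ValueError("need at least two points to integrate")
    return float(np.trapezoid(curve.force, curve.displacement))


def lost_atom_fraction(
    before: MembraneModel, after: MembraneModel, detachment_radius: float = 15.0
) -> float:
    """Fraction of membrane beads displaced beyond ``detachment_radius``
    outside the original bilayer slab — the membrane-integrity metric
    (< 1% counts as non-invasive crossing)."""
    if before.n_beads != after.n_beads or not np.array_equal(before.bonds, after.bonds):
        raise ValueError("membrane topologies do not match")
    zmin, zmax = before.z_range()
    z = after.positions[:, 2]
    lost = (z > zmax + detachment_radius) | (z < zmin - detachment_radius)
    return float(np.count_nonzero(lost)) / before.n_beads
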