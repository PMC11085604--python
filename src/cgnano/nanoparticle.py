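"""The two C60 fullerene models.

Explicit model: 20 alanine-like interaction centers at the vertices of a
regular dodecahedron (circumradius default 3.55 Å, so the center-to-center
diameter matches the 0.71 nm C60 diameter), each with an inward-facing
Calpha anchor; all 190 anchor pairs carry harmonic restraints
(k = 10 kcal/mol/Å^2 by default) keeping the particle sphere-like while
leaving it free to translate and rotate.

Implicit model: an immobile sphere of hard-core radius R0 (default 3.5 Å)
interacting with every protein interaction site through the Kihara
potential U(r) = 4 eps [ (sigma/(r-R0))^12 - (sigma/(r-R0))^6 ].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .params import KiharaParams

# Explicit-particle unit masses: 36 amu per vertex unit (24 amu on the
# interaction center + 12 amu on its anchor) so the whole particle totals
# C60's 720 amu while both site classes stay dynamic.
CENTER_MASS = 24.0
ANCHOR_MASS = 12.0


@dataclass
class ExplicitNanoparticle:
    """Mobile 20-center dodecahedral C60 model."""

    sc_xyz: np.ndarray                 # (20, 3) interaction centers
    ca_xyz: np.ndarray                 # (20, 3) inward anchors
    restraints: list                   # (i, j, d0, k) over all anchor pairs
    center_type: str = "A"
    bond_d0: float = 1.53              # anchor-center virtual bond length
    bond_k: float = 100.0

    def __post_init__(self):
        self.sc_xyz = np.asarray(self.sc_xyz, float).reshape(-1, 3)
        self.ca_xyz = np.asarray(self.ca_xyz, float).reshape(-1, 3)
        if self.sc_xyz.shape[0] != 20 or self.ca_xyz.shape[0] != 20:
            raise ValueError("explicit nanoparticle requires exactly 20 "
                             "interaction centers and 20 anchors")
        if len(self.restraints) != 190:
            raise ValueError(
                f"expected C(20,2)=190 restraint pairs, got {len(self.restraints)}")

    def copy(self):
        return ExplicitNanoparticle(self.sc_xyz.copy(), self.ca_xyz.copy(),
                                    list(self.restraints), self.center_type,
                                    self.bond_d0, self.bond_k)


@dataclass
class ImplicitSphere:
    """Immobile Kihara sphere; at most one per system."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    R0: float = 3.5
    kihara: KiharaParams = field(default_factory=KiharaParams)

    def __post_init__(self):
        self.center = np.asarray(self.center, float).reshape(3)
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


def dodecahedron_vertices(circumradius: float) -> np.ndarray:
    """Vertices of a regular dodecahedron at the given circumradius."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [np.array(s, float) for s in itertools.product((1, -1), repeat=3)]
    for a, b in itertools.product((1, -1), repeat=2):
        verts.append(np.array([0.0, a / phi, b * phi]))
        verts.append(np.array([a / phi, b * phi, 0.0]))
        verts.append(np.array([a * phi, 0.0, b / phi]))
    V = np.array(verts)
    V *= circumradius / np.linalg.norm(V, axis=1)[:, None]
    return V


def build_explicit_c60(circumradius: float = 3.55, restraint_k: float = 10.0,
                       center_type: str = "A", bond_d0: float = 1.53,
                       bond_k: float = 100.0) -> ExplicitNanoparticle:
    """Construct the restrained dodecahedral C60 particle.

    Interaction centers sit at the dodecahedron vertices; anchors sit on
    the segment from each vertex toward the centroid, one anchor-center
    bond length inside.  All 190 anchor-pair restraints are set with
    d0 equal to the built distance, so the restraint energy of a freshly
    built particle is exactly zero.
    """
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    if restraint_k <= 0:
        raise ValueError("restraint force constant must be positive")
    centers = dodecahedron_vertices(circumradius)
    anchors = centers * (1.0 - bond_d0 / circumradius)
    restraints = []
    for i in range(20):
        for j in range(i + 1, 20):
            d0 = float(np.linalg.norm(anchors[i] - anchors[j]))
            restraints.append((i, j, d0, restraint_k))
    return ExplicitNanoparticle(centers, anchors, restraints, center_type,
                                bond_d0, bond_k)


def alignment_energy(nano: ExplicitNanoparticle, anchors, centers,
                     with_forces: bool = False):
    """Anchor-center coupling: U = sum 1/2 k |c_i - t_i|^2.

    The target point t_i sits one bond length radially outward from
    anchor i (along the line from the anchor centroid through the
    anchor), so the term restrains both the anchor-center distance and
    the center's outward orientation.  It stands in for the orientational
    side-chain attachment of the parent force field, which the particle
    needs to keep its interacting surface sphere-like.
    """
    anchors = np.asarray(anchors, float).reshape(20, 3)
    centers = np.asarray(centers, float).reshape(20, 3)
    k = nano.bond_k
    d0 = nano.bond_d0
    G = anchors.mean(axis=0)
    r = anchors - G
    rn = np.linalg.norm(r, axis=1)
    u = r / rn[:, None]
    t = anchors + d0 * u
    e = centers - t
    energy = float(0.5 * k * np.sum(e * e))
    if not with_forces:
        return energy
    f_c = -k * e
    # dt_i/da_j = delta_ij (I + d0 J_i) - (d0/20) J_i, J_i = (I - u u^T)/|r_i|
    J_e = np.zeros_like(e)
    for i in range(20):
        J = (np.eye(3) - np.outer(u[i], u[i])) / rn[i]
        J_e[i] = J @ e[i]
    f_a = k * (e + d0 * J_e - (d0 / 20.0) * J_e.sum(axis=0))
    return energy, f_a, f_c


def restraint_energy(nano: ExplicitNanoparticle, xyz=None,
                     with_forces: bool = False):
    """Harmonic restraint energy sum(1/2 k (d - d0)^2) over anchor pairs."""
    xyz = nano.ca_xyz if xyz is None else np.asarray(xyz, float)
    if xyz.shape != (20, 3):
        raise ValueError(f"expected (20, 3) anchor coordinates, got {xyz.shape}")
    idx = np.array([(i, j) for i, j, _, _ in nano.restraints])
    d0 = np.array([r[2] for r in nano.restraints])
    k = np.array([r[3] for r in nano.restraints])
    dvec = xyz[idx[:, 0]] - xyz[idx[:, 1]]
    d = np.linalg.norm(dvec, axis=1)
    energy = float(np.sum(0.5 * k * (d - d0) ** 2))
    if not with_forces:
        return energy
    forces = np.zeros_like(xyz)
    dUdd = k * (d - d0)
    fpair = -(dUdd / d)[:, None] * dvec
    np.add.at(forces, idx[:, 0], fpair)
    np.add.at(forces, idx[:, 1], -fpair)
    return energy, forces


def kihara_energy(r, params: KiharaParams, R0: float):
    """Kihara potential: 4 eps [ (sigma/(r-R0))^12 - (sigma/(r-R0))^6 ].

    Zero at r = R0 + sigma, minimum -eps at r = R0 + 2^(1/6) sigma.
    Raises for any r on or inside the hard core r <= R0.
    """
    r = np.asarray(r, float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite distance passed to kihara_energy")
    if np.any(r <= R0):
        raise ValueError(f"distance inside the hard core (r <= R0 = {R0})")
    x = params.sigma / (r - R0)
    return 4.0 * params.epsilon * (x ** 12 - x ** 6)


def kihara_force_mag(r, params: KiharaParams, R0: float):
    """-dU/dr of the Kihara potential (positive = repulsive)."""
    r = np.asarray(r, float)
    if np.any(r <= R0):
        raise ValueError(f"distance inside the hard core (r <= R0 = {R0})")
    s = params.sigma
    x = s / (r - R0)
    return 4.0 * params.epsilon * (12.0 * x ** 12 - 6.0 * x ** 6) / (r - R0)


def implicit_interaction_energy(sites, sphere: ImplicitSphere,
                                with_forces: bool = False):
    """Sum of Kihara terms between interaction sites and the sphere.

    Strictly additive over sites; returns (total, per_site) or, with
    forces, (total, per_site, forces).  Raises identifying the first site
    on or inside the hard core.
    """
    sites = np.asarray(sites, float).reshape(-1, 3)
    dvec = sites - sphere.center
    r = np.linalg.norm(dvec, axis=1)
    inside = np.nonzero(r <= sphere.R0)[0]
    if inside.size:
        raise ValueError(
            f"site {inside[0]} is inside the nanoparticle hard core "
            f"(r = {r[inside[0]]:.3f} Å <= R0 = {sphere.R0} Å)")
    per_site = kihara_energy(r, sphere.kihara, sphere.R0)
    total = float(per_site.sum())
    if not with_forces:
        return total, per_site
    fmag = kihara_force_mag(r, sphere.kihara, sphere.R0)
    forces = (fmag / r)[:, None] * dvec
    return total, per_site, forces
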