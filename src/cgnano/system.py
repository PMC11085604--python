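"""Simulation system: protein + nanoparticles + parameter set.

The dynamic degrees of freedom are the protein Calpha and side-chain
sites plus, for each explicit nanoparticle, its 20 anchors and 20
interaction centers.  Peptide-group sites are derived (Calpha midpoints)
and are not independent degrees of freedom: forces acting on them are
redistributed half-and-half onto the flanking Calpha sites.  An implicit
sphere, if present, exerts forces but carries no degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nanoparticle import (ANCHOR_MASS, CENTER_MASS, ExplicitNanoparticle,
                           ImplicitSphere)
from .params import EnergyWeights, ForceFieldParams
from .topology import CGProtein


@dataclass
class System:
    protein: CGProtein = None
    particles: list = field(default_factory=list)
    sphere: ImplicitSphere = None
    params: ForceFieldParams = field(default_factory=ForceFieldParams)
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    # intra-particle center-center nonbonded (restraints dominate; off by default)
    particle_intra_nonbonded: bool = False
    # pluggable mean-field electrostatic and multibody terms:
    # callables (system, coords_dict) -> energy or (energy, forces_dict)
    pp_el_term: object = None
    corr3_term: object = None
    turn3_term: object = None

    def __post_init__(self):
        if self.sphere is not None and not isinstance(self.sphere, ImplicitSphere):
            raise TypeError("sphere must be an ImplicitSphere")
        if self.protein is None and not self.particles:
            raise ValueError("system needs a protein and/or explicit particles")

    # ---- coordinate layout -------------------------------------------------
    @property
    def n_res(self):
        return self.protein.n_residues if self.protein is not None else 0

    @property
    def n_sites(self):
        return 2 * self.n_res + 40 * len(self.particles)

    def ca_slice(self):
        return slice(0, self.n_res)

    def sc_slice(self):
        return slice(self.n_res, 2 * self.n_res)

    def anchor_slice(self, k):
        base = 2 * self.n_res + 40 * k
        return slice(base, base + 20)

    def center_slice(self, k):
        base = 2 * self.n_res + 40 * k + 20
        return slice(base, base + 20)

    def coords(self) -> np.ndarray:
        """Current dynamic coordinates, shape (n_sites, 3)."""
        parts = []
        if self.protein is not None:
            parts += [self.protein.ca_xyz, self.protein.sc_xyz]
        for p in self.particles:
            parts += [p.ca_xyz, p.sc_xyz]
        return np.concatenate(parts) if parts else np.empty((0, 3))

    def set_coords(self, x: np.ndarray):
        x = np.asarray(x, float).reshape(self.n_sites, 3)
        if self.protein is not None:
            self.protein.ca_xyz = x[self.ca_slice()].copy()
            self.protein.sc_xyz = x[self.sc_slice()].copy()
        for k, p in enumerate(self.particles):
            p.ca_xyz = x[self.anchor_slice(k)].copy()
            p.sc_xyz = x[self.center_slice(k)].copy()

    def masses(self) -> np.ndarray:
        parts = []
        if self.protein is not None:
            parts += [self.protein.ca_masses, self.protein.sc_masses]
        for _ in self.particles:
            parts += [np.full(20, ANCHOR_MASS), np.full(20, CENTER_MASS)]
        return np.concatenate(parts) if parts else np.empty(0)

    # ---- subsystems for binding-energy decomposition -----------------------
    def protein_only(self) -> "System":
        if self.protein is None:
            raise ValueError("system has no protein component")
        return System(protein=self.protein, particles=[], sphere=None,
                      params=self.params, weights=self.weights,
                      pp_el_term=self.pp_el_term, corr3_term=self.corr3_term,
                      turn3_term=self.turn3_term)

    def particles_only(self) -> "System":
        if not self.particles:
            raise ValueError("system has no explicit nanoparticle")
        return System(protein=None, particles=self.particles, sphere=None,
                      params=self.params, weights=self.weights,
                      particle_intra_nonbonded=self.particle_intra_nonbonded)

    def copy(self) -> "System":
        return System(
            protein=self.protein.copy() if self.protein is not None else None,
            particles=[p.copy() for p in self.particles],
            sphere=self.sphere, params=self.params, weights=self.weights,
            particle_intra_nonbonded=self.particle_intra_nonbonded,
            pp_el_term=self.pp_el_term, corr3_term=self.corr3_term,
            turn3_term=self.turn3_term)
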