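"""Reduced protein representation and its internal coordinates.

A protein is reduced to one Calpha site and one united side-chain (SC)
site per residue, plus united peptide-group (p) sites placed halfway
between consecutive Calpha atoms of the same chain.  The Calpha trace
defines the backbone geometry through virtual bond angles theta and
virtual dihedrals gamma; side-chain centers are located by the polar
angles (alpha, beta) relative to the local backbone frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import internal
from .constants import (CA_CA_BOND, CA_SITE_MASS, BACKBONE_ATOMS, SC_MASS,
                        THREE_TO_ONE)


@dataclass
class CGProtein:
    """Coarse-grained protein: sequence plus site coordinates.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid codes, one per residue.
    chain_ids : list[str]
        Per-residue chain label; residues of a chain are contiguous.
    ca_xyz, sc_xyz : (n, 3) float arrays, Å
        Calpha and side-chain-center coordinates.  Glycine SC sites
        coincide with the Calpha.
    disulfide_pairs : list[tuple[int, int]]
        0-based residue index pairs of bonded/bondable cysteines, i < j.
    residue_numbers : (n,) int array
        1-based residue numbering mirroring PDB.
    """

    sequence: str
    ca_xyz: np.ndarray
    sc_xyz: np.ndarray
    chain_ids: list = None
    disulfide_pairs: list = field(default_factory=list)
    residue_numbers: np.ndarray = None

    def __post_init__(self):
        self.ca_xyz = np.asarray(self.ca_xyz, float).reshape(-1, 3)
        self.sc_xyz = np.asarray(self.sc_xyz, float).reshape(-1, 3)
        n = len(self.sequence)
        if self.ca_xyz.shape[0] != n or self.sc_xyz.shape[0] != n:
            raise ValueError(
                f"site count mismatch: {n} residues, {self.ca_xyz.shape[0]} "
                f"Ca sites, {self.sc_xyz.shape[0]} SC sites")
        if self.chain_ids is None:
            self.chain_ids = ["A"] * n
        if len(self.chain_ids) != n:
            raise ValueError("chain_ids length mismatch")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, n + 1)
        self.residue_numbers = np.asarray(self.residue_numbers, int)
        bad = [s for s in self.sequence if s not in SC_MASS]
        if bad:
            raise ValueError(f"unknown residue code(s): {sorted(set(bad))}")
        for i, j in self.disulfide_pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid disulfide pair ({i}, {j})")
            if self.sequence[i] != "C" or self.sequence[j] != "C":
                raise ValueError(
                    f"disulfide pair ({i}, {j}) references non-cysteine "
                    f"residues {self.sequence[i]}/{self.sequence[j]}")
        if len(set(map(tuple, self.disulfide_pairs))) != len(self.disulfide_pairs):
            raise ValueError("duplicate disulfide pairs")
        for start, stop in self.chain_slices():
            if stop - start < 2:
                raise ValueError(
                    f"single-residue chain {self.chain_ids[start]!r}: "
                    "no virtual bond can be defined")

    @property
    def n_residues(self):
        return len(self.sequence)

    def chain_slices(self):
        """(start, stop) residue index ranges, one per chain."""
        out = []
        start = 0
        for i in range(1, len(self.chain_ids) + 1):
            if i == len(self.chain_ids) or self.chain_ids[i] != self.chain_ids[start]:
                out.append((start, i))
                start = i
        return out

    @property
    def pg_xyz(self):
        """Peptide-group sites: midpoints of consecutive Ca pairs per chain."""
        blocks = [0.5 * (self.ca_xyz[a:b - 1] + self.ca_xyz[a + 1:b])
                  for a, b in self.chain_slices()]
        return np.concatenate(blocks) if blocks else np.empty((0, 3))

    def pg_flanks(self):
        """(n_pg, 2) residue indices flanking each peptide group."""
        rows = []
        for a, b in self.chain_slices():
            for i in range(a, b - 1):
                rows.append((i, i + 1))
        return np.array(rows, int).reshape(-1, 2)

    @property
    def sc_masses(self):
        return np.array([SC_MASS[s] for s in self.sequence])

    @property
    def ca_masses(self):
        return np.full(self.n_residues, CA_SITE_MASS)

    def copy(self):
        return CGProtein(self.sequence, self.ca_xyz.copy(), self.sc_xyz.copy(),
                         list(self.chain_ids), list(self.disulfide_pairs),
                         self.residue_numbers.copy())


@dataclass
class CGGeometry:
    """Internal coordinates of a CG chain (angles in degrees, lengths Å).

    theta has n-2 entries per chain, gamma n-3; alpha/beta/d_sc one per
    residue (NaN at chain termini and for zero-length SC bonds where the
    placement angles are undefined); d_bb one per backbone virtual bond.
    """

    theta: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    d_bb: np.ndarray
    d_sc: np.ndarray
    chain_lengths: list = None

    def __post_init__(self):
        for name in ("theta", "gamma", "alpha", "beta", "d_bb", "d_sc"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.chain_lengths is None:
            self.chain_lengths = [len(self.d_sc)]
        ok = np.isfinite(self.theta)
        if np.any((self.theta[ok] <= 0) | (self.theta[ok] > 180)):
            raise ValueError("theta values must lie in (0, 180]")
        if np.any(self.d_bb <= 0):
            raise ValueError("backbone virtual bond lengths must be positive")


def coarse_grain_structure(atoms) -> CGProtein:
    """Reduce an all-atom structure (biotite AtomArray) to CG sites.

    One Calpha site per residue (copied), one SC site per residue (the
    unweighted centroid of side-chain heavy atoms; glycine and residues
    with no side-chain heavy atoms fall back to the Calpha), and derived
    peptide groups at Calpha midpoints.  Cysteine pairs whose SG atoms lie
    within 2.5 Å are recorded as disulfide pairs.
    """
    import biotite.structure as struc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid residues in structure")
    sequence = []
    chain_ids = []
    res_numbers = []
    ca, sc = [], []
    sg_pos = {}
    for res in struc.residue_iter(atoms):
        name3 = res.res_name[0]
        if name3 not in THREE_TO_ONE:
            raise ValueError(f"unknown residue code {name3!r}")
        code = THREE_TO_ONE[name3]
        ca_mask = res.atom_name == "CA"
        if not ca_mask.any():
            raise ValueError(
                f"residue {name3} {res.res_id[0]} (chain {res.chain_id[0]}) "
                "has no Calpha atom")
        ca_pos = res.coord[ca_mask][0]
        heavy = res[(~np.isin(res.atom_name, list(BACKBONE_ATOMS)))
                    & (res.element != "H")]
        if heavy.array_length() > 0:
            sc_pos = heavy.coord.mean(axis=0)
        else:
            sc_pos = ca_pos.copy()
            if code != "G":
                warnings.warn(
                    f"residue {name3} {res.res_id[0]} has no side-chain "
                    "heavy atoms; SC site placed on the Calpha")
        if code == "C":
            sg = res.coord[res.atom_name == "SG"]
            if len(sg):
                sg_pos[len(sequence)] = sg[0]
        sequence.append(code)
        chain_ids.append(str(res.chain_id[0]))
        res_numbers.append(int(res.res_id[0]))
        ca.append(ca_pos)
        sc.append(sc_pos)

    ss_pairs = []
    keys = sorted(sg_pos)
    for a_i in range(len(keys)):
        for b_i in range(a_i + 1, len(keys)):
            i, j = keys[a_i], keys[b_i]
            if np.linalg.norm(sg_pos[i] - sg_pos[j]) < 2.5:
                ss_pairs.append((i, j))

    return CGProtein("".join(sequence), np.array(ca), np.array(sc),
                     chain_ids, ss_pairs, np.array(res_numbers))


def compute_internal_coordinates(protein: CGProtein) -> CGGeometry:
    """Measure (theta, gamma, alpha, beta, d) from Cartesian CG sites.

    Collinear backbone quadruplets yield NaN dihedrals (undefined, not
    zero); side-chain angles are NaN at chain termini and for SC sites
    coinciding with their Calpha (glycine convention).
    """
    n = protein.n_residues
    theta, gamma, d_bb = [], [], []
    alpha = np.full(n, np.nan)
    beta = np.full(n, np.nan)
    d_sc = np.zeros(n)
    ca = protein.ca_xyz
    for a, b in protein.chain_slices():
        if b - a < 3:
            raise ValueError("need at least 3 residues per chain for theta")
        for i in range(a, b - 1):
            d_bb.append(np.linalg.norm(ca[i + 1] - ca[i]))
        for i in range(a + 1, b - 1):
            theta.append(internal.bond_angle(ca[i - 1], ca[i], ca[i + 1]))
        for i in range(a + 1, b - 2):
            gamma.append(internal.dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2]))
        for i in range(a, b):
            w = protein.sc_xyz[i] - ca[i]
            d_sc[i] = np.linalg.norm(w)
            if a < i < b - 1 and d_sc[i] > 1e-9:
                try:
                    alpha[i], beta[i], _ = internal.measure_sc(
                        ca[i - 1], ca[i], ca[i + 1], protein.sc_xyz[i])
                except ValueError:
                    pass  # collinear frame: angles stay NaN
    chain_lengths = [b - a for a, b in protein.chain_slices()]
    return CGGeometry(np.array(theta), np.array(gamma), alpha, beta,
                      np.array(d_bb), d_sc, chain_lengths)


def rebuild_cartesian(geometry: CGGeometry, seed_frame=None,
                      sequence=None) -> CGProtein:
    """Rebuild Cartesian CG coordinates from internal coordinates.

    Natural-extension reference frame construction for a single chain:
    the first three Calpha positions reproduce ``seed_frame`` (default: a
    canonical frame in the xy-plane built from d_bb[0], d_bb[1] and
    theta[0]); every later Calpha is placed from (d, theta, gamma).
    Side-chain sites are placed from (d_sc, alpha, beta); termini and
    zero-length side chains sit on their Calpha.
    """
    if len(geometry.chain_lengths) != 1:
        raise ValueError("rebuild_cartesian supports single-chain geometries")
    n = geometry.chain_lengths[0]
    theta, gamma = geometry.theta, geometry.gamma
    if len(theta) != n - 2 or len(gamma) != n - 3:
        raise ValueError("theta/gamma counts inconsistent with chain length")
    ok = np.isfinite(theta)
    if np.any((theta[ok] <= 0) | (theta[ok] > 180)):
        raise ValueError("theta values must lie in (0, 180]")

    ca = np.zeros((n, 3))
    if seed_frame is not None:
        ca[:3] = np.asarray(seed_frame, float).reshape(3, 3)
    else:
        ca[1] = [geometry.d_bb[0], 0.0, 0.0]
        t0 = np.radians(theta[0])
        ca[2] = ca[1] + geometry.d_bb[1] * np.array(
            [-np.cos(t0), np.sin(t0), 0.0])
    for i in range(3, n):
        ca[i] = internal.nerf_extend(
            ca[i - 3], ca[i - 2], ca[i - 1],
            geometry.d_bb[i - 1], theta[i - 2], gamma[i - 3])

    sc = ca.copy()
    for i in range(1, n - 1):
        d = geometry.d_sc[i]
        if d > 1e-9 and np.isfinite(geometry.alpha[i]):
            sc[i] = internal.place_sc(ca[i - 1], ca[i], ca[i + 1], d,
                                      geometry.alpha[i], geometry.beta[i])
    # terminal side chains: axial placement along the chain end direction
    # (their alpha/beta are undefined without two backbone neighbours)
    for i, nb in ((0, 1), (n - 1, n - 2)):
        d = geometry.d_sc[i]
        if d > 1e-9:
            axis = ca[i] - ca[nb]
            sc[i] = ca[i] + d * axis / np.linalg.norm(axis)
    seq = sequence if sequence is not None else "A" * n
    return CGProtein(seq, ca, sc)
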