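"""Effective energy function of the reduced representation.

Assembles the total energy as a weighted sum of component potentials —
Gay-Berne side-chain interactions, side-chain/peptide-group excluded
volume, peptide-peptide Lennard-Jones, bonded terms, a dynamic disulfide
double well, nanoparticle terms — with temperature coefficients f_n(T)
applied to the second- and third-order cumulant terms.  Analytic forces
are provided for every enabled term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import internal
from .nanoparticle import (alignment_energy, implicit_interaction_energy,
                           restraint_energy)
from .params import ForceFieldParams, GayBerneParams
from .system import System

_F2_TERMS = {"U_pp_el", "U_tor"}
_F3_TERMS = {"U_corr3", "U_turn3"}
_UNSCALED = {"U_restraint", "U_nano"}

TERM_NAMES = ("U_SCSC", "U_SCp", "U_pp_VDW", "U_pp_el", "U_tor", "U_b",
              "U_rot", "U_bond", "U_ssbond", "U_corr3", "U_turn3",
              "U_restraint", "U_nano")


# ---------------------------------------------------------------------------
# elementary potentials
# ---------------------------------------------------------------------------

def temperature_factor(n: int, T: float, T0: float = 300.0) -> float:
    """Temperature coefficient f_n(T) of the cumulant expansion.

    f_n(T) = ln(e + 1/e) / ln( exp[(T/T0)^(n-1)] + exp[-(T/T0)^(n-1)] ).
    Equals 1 exactly at T = T0 and decreases strictly with T.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError("cumulant order n must be an integer >= 2")
    if T <= 0 or T0 <= 0:
        raise ValueError("temperatures must be positive")
    x = (T / T0) ** (n - 1)
    return float(np.logaddexp(1.0, -1.0) / np.logaddexp(x, -x))


def gay_berne_energy(r, params: GayBerneParams, orientations=None):
    """Gay-Berne potential 4 eps [ (s0/(r-s+s0))^12 - (s0/(r-s+s0))^6 ].

    In the default spherical limit (sigma == sigma0, no orientations)
    this reduces to the plain Lennard-Jones potential.  With unit
    orientation vectors ``(u1, u2)`` and ``params.anisotropy_ratios``
    = (kappa, kappa_prime, mu, nu) set, the standard orientation-dependent
    sigma and epsilon of the uniaxial Gay-Berne model are used.
    """
    r = np.asarray(r, float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite distance in gay_berne_energy")
    eps, sigma, sigma0 = params.epsilon, params.sigma, params.sigma0
    if orientations is not None and params.anisotropy_ratios is not None:
        u1, u2 = (np.asarray(u, float) for u in orientations[:2])
        rhat = (np.asarray(orientations[2], float)
                if len(orientations) > 2 else None)
        sigma, eps = _gb_orientation(params, u1, u2, rhat)
    shifted = r - sigma + sigma0
    if np.any(shifted <= 0):
        raise ValueError("r <= sigma - sigma0: shifted argument singular")
    x = sigma0 / shifted
    return 4.0 * eps * (x ** 12 - x ** 6)


def _gb_orientation(params: GayBerneParams, u1, u2, rhat=None):
    """Orientation-dependent (sigma, epsilon) of the uniaxial model."""
    kappa, kappa_p, mu, nu = params.anisotropy_ratios
    chi = (kappa ** 2 - 1.0) / (kappa ** 2 + 1.0)
    chi_p = (kappa_p ** (1.0 / mu) - 1.0) / (kappa_p ** (1.0 / mu) + 1.0)
    if rhat is None:
        rhat = np.array([0.0, 0.0, 1.0])
    a, b, c = rhat @ u1, rhat @ u2, u1 @ u2
    g = 0.5 * chi * ((a + b) ** 2 / (1 + chi * c)
                     + (a - b) ** 2 / (1 - chi * c))
    sigma = params.sigma0 / np.sqrt(max(1.0 - g, 1e-12))
    eps1 = 1.0 / np.sqrt(max(1.0 - chi ** 2 * c ** 2, 1e-12))
    gp = 0.5 * chi_p * ((a + b) ** 2 / (1 + chi_p * c)
                        + (a - b) ** 2 / (1 - chi_p * c))
    eps = params.epsilon * eps1 ** nu * (1.0 - gp) ** mu
    return sigma, eps


def _lj_pair(r, eps, sigma0, sigma=None):
    """Shifted-LJ energy and dU/dr for vectorized pair loops."""
    sigma = sigma0 if sigma is None else sigma
    shifted = r - sigma + sigma0
    if np.any(shifted <= 0):
        raise ValueError("pair distance at or inside the singular shift")
    x = sigma0 / shifted
    u = 4.0 * eps * (x ** 12 - x ** 6)
    dudr = 4.0 * eps * (-12.0 * x ** 12 + 6.0 * x ** 6) / shifted
    return u, dudr


def _rep12(r, eps, sigma):
    """Purely repulsive (sigma/r)^12 energy and dU/dr."""
    if np.any(r <= 0):
        raise ValueError("zero distance in excluded-volume term")
    x = sigma / r
    u = eps * x ** 12
    return u, -12.0 * u / r


def excluded_volume_energy(sc_sites, pg_sites, params: ForceFieldParams):
    """Repulsive SC-p excluded-volume energy over all cross pairs."""
    sc = np.asarray(sc_sites, float).reshape(-1, 3)
    pg = np.asarray(pg_sites, float).reshape(-1, 3)
    if sc.size == 0 or pg.size == 0:
        return 0.0
    d = np.linalg.norm(sc[:, None, :] - pg[None, :, :], axis=-1)
    u, _ = _rep12(d.ravel(), params.eps_rep, params.sigma_rep)
    return float(u.sum())


def disulfide_potential(d, params: ForceFieldParams):
    """Dynamic disulfide double-well energy and dU/dd at SC-SC distance d.

    Piecewise C1: a quartic well of depth -ss_depth at d_ss0 rising to a
    barrier ss_barrier at d_ss0 + ss_x_barrier, a cubic smoothstep down to
    an exactly-zero dissociated plateau at d_ss0 + ss_x_plateau, and a
    harmonic repulsive continuation at short range.  All joins have zero
    slope, so energy and first derivative are continuous everywhere.
    """
    x = float(d) - params.d_ss0
    xb, xp = params.ss_x_barrier, params.ss_x_plateau
    depth, barrier = params.ss_depth, params.ss_barrier
    if x < -xb:
        k_core = 10.0 * (depth + barrier) / xb ** 2
        return barrier + k_core * (x + xb) ** 2, 2.0 * k_core * (x + xb)
    if x <= xb:
        t = x / xb
        u = -depth + (depth + barrier) * t * t * (2.0 - t * t)
        du = 4.0 * (depth + barrier) * t * (1.0 - t * t) / xb
        return u, du
    if x < xp:
        t = (x - xb) / (xp - xb)
        s = t * t * (3.0 - 2.0 * t)
        return barrier * (1.0 - s), -barrier * 6.0 * t * (1.0 - t) / (xp - xb)
    return 0.0, 0.0


def disulfide_energy(pairs, sequence, sc_xyz, params: ForceFieldParams,
                     with_forces: bool = False):
    """Disulfide term over Cys-Cys pairs; returns (energy, bonded_flags).

    A pair is flagged bonded when its SC-SC distance is below the
    switching threshold (the local maximum at d_ss0 + ss_x_barrier).
    """
    sc_xyz = np.asarray(sc_xyz, float)
    energy = 0.0
    flags = []
    forces = np.zeros_like(sc_xyz)
    threshold = params.d_ss0 + params.ss_x_barrier
    for i, j in pairs:
        if sequence[i] != "C" or sequence[j] != "C":
            raise ValueError(f"disulfide pair ({i}, {j}) is not Cys-Cys")
        dvec = sc_xyz[i] - sc_xyz[j]
        d = np.linalg.norm(dvec)
        u, du = disulfide_potential(d, params)
        energy += u
        flags.append(bool(d < threshold))
        if with_forces and d > 1e-12:
            f = -du * dvec / d
            forces[i] += f
            forces[j] -= f
    if with_forces:
        return energy, flags, forces
    return energy, flags


# ---------------------------------------------------------------------------
# bonded terms on a full system
# ---------------------------------------------------------------------------

def _torsion_series(gamma_rad, a_coef, b_coef):
    """Fourier torsion energy and dU/dgamma."""
    u = 0.0
    du = 0.0
    for m, a in enumerate(a_coef, start=1):
        u += a * np.cos(m * gamma_rad)
        du += -a * m * np.sin(m * gamma_rad)
    for m, b in enumerate(b_coef, start=1):
        u += b * np.sin(m * gamma_rad)
        du += b * m * np.cos(m * gamma_rad)
    return u, du


def bonded_energy(protein, geometry, params: ForceFieldParams) -> dict:
    """Bonded energy terms from measured internal coordinates.

    U_bond = sum 1/2 k (d-d0)^2 over backbone and Ca-SC virtual bonds;
    U_b = sum 1/2 k_theta (theta-theta0)^2; U_tor a cosine/sine series in
    gamma; U_rot = sum 1/2 k_alpha (alpha-alpha0)^2
    + 1/2 k_beta (1 - cos(beta-beta0)).
    """
    params.require_types(set(protein.sequence))
    u_bond = float(np.sum(0.5 * params.k_bond_bb
                          * (geometry.d_bb - params.d_bb0) ** 2))
    d_sc0 = np.array([params.d_sc0[s] for s in protein.sequence])
    u_bond += float(np.sum(0.5 * params.k_bond_sc
                           * (geometry.d_sc - d_sc0) ** 2))
    th = np.radians(geometry.theta)
    u_b = float(np.sum(0.5 * params.k_theta
                       * (th - np.radians(params.theta0)) ** 2))
    u_tor = 0.0
    for g in geometry.gamma:
        if np.isfinite(g):
            u_tor += _torsion_series(np.radians(g), params.tor_a,
                                     params.tor_b)[0]
    u_rot = 0.0
    a0 = np.radians(params.alpha0)
    b0 = np.radians(params.beta0)
    for i in range(protein.n_residues):
        if np.isfinite(geometry.alpha[i]) and d_sc0[i] > 0:
            al = np.radians(geometry.alpha[i])
            be = np.radians(geometry.beta[i])
            u_rot += 0.5 * params.k_alpha * (al - a0) ** 2
            u_rot += 0.5 * params.k_beta * (1.0 - np.cos(be - b0))
    return {"U_bond": u_bond, "U_b": float(u_b), "U_tor": float(u_tor),
            "U_rot": float(u_rot)}


# ---------------------------------------------------------------------------
# energy breakdown container
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """Per-term energies (unweighted), applied scale factors, and total.

    total = sum over terms of scale(term) * U(term), where scale carries
    the weight w_x and, for second/third-order cumulant terms, the
    temperature factor f_n(T); nanoparticle terms are unscaled.
    """

    terms: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    disabled: set = field(default_factory=set)
    T: float = 300.0
    total: float = 0.0

    def __getattr__(self, name):
        if name in TERM_NAMES:
            return self.__dict__.get("terms", {}).get(name, 0.0)
        raise AttributeError(name)

    def resum(self) -> float:
        return float(sum(self.scales.get(k, 1.0) * v
                         for k, v in self.terms.items()))


def _scales(weights, T):
    f2 = temperature_factor(2, T)
    f3 = temperature_factor(3, T)
    out = {}
    for name in TERM_NAMES:
        if name in _UNSCALED:
            out[name] = 1.0
            continue
        w = getattr(weights, "w_SC" if name == "U_SCSC" else "w_" + name[2:])
        if name in _F2_TERMS:
            w *= f2
        elif name in _F3_TERMS:
            w *= f3
        out[name] = w
    return out


# ---------------------------------------------------------------------------
# full-system evaluation
# ---------------------------------------------------------------------------

def _pair_accumulate(coords, forces_list, idx_a, idx_b, eps, sigma,
                     kind, scale, cutoff=0.0):
    """Vectorized pair energy with scaled force accumulation.

    kind: 'lj' (full LJ) or 'rep' (r^-12 repulsion).  With a positive
    cutoff the energy is shifted so U(cutoff) = 0 and pairs beyond it are
    skipped.
    """
    if len(idx_a) == 0:
        return 0.0
    ra = coords[idx_a]
    rb = coords[idx_b]
    dvec = ra - rb
    d = np.linalg.norm(dvec, axis=1)
    fun = _lj_pair if kind == "lj" else _rep12
    u, dudr = fun(d, eps, sigma)
    if cutoff and cutoff > 0:
        mask = d < cutoff
        ushift = fun(np.full(1, cutoff), eps, sigma)[0]
        ushift = np.broadcast_to(ushift, u.shape) if np.ndim(ushift) else ushift
        u = np.where(mask, u - ushift, 0.0)
        dudr = np.where(mask, dudr, 0.0)
    energy = float(np.sum(u))
    if forces_list is not None:
        fpair = (-dudr / d)[:, None] * dvec
        np.add.at(forces_list, idx_a, fpair * scale)
        np.add.at(forces_list, idx_b, -fpair * scale)
    return energy


def total_energy(system: System, T: float = 300.0, coords=None,
                 with_forces: bool = False):
    """Evaluate the effective energy (and optionally analytic forces).

    Returns an :class:`EnergyBreakdown`; with ``with_forces=True`` returns
    ``(breakdown, forces)`` with forces of shape (n_sites, 3) in
    kcal/mol/Å, including the weight and temperature-factor scaling, with
    peptide-group contributions redistributed onto flanking Calphas.
    """
    x = system.coords() if coords is None else \
        np.asarray(coords, float).reshape(system.n_sites, 3)
    scales = _scales(system.weights, T)
    terms = {name: 0.0 for name in TERM_NAMES}
    F = np.zeros_like(x) if with_forces else None
    prot = system.protein
    n = system.n_res
    params = system.params

    # ---- peptide-group geometry (derived sites) ---------------------------
    if prot is not None:
        ca = x[system.ca_slice()]
        sc = x[system.sc_slice()]
        flanks = prot.pg_flanks()
        pg = 0.5 * (ca[flanks[:, 0]] + ca[flanks[:, 1]]) \
            if len(flanks) else np.empty((0, 3))
        F_pg = np.zeros_like(pg) if with_forces else None
        F_ca = np.zeros((n, 3)) if with_forces else None
        F_sc = np.zeros((n, 3)) if with_forces else None

    # ---- protein bonded terms ---------------------------------------------
    if prot is not None:
        params.require_types(set(prot.sequence))
        d_sc0 = np.array([params.d_sc0[s] for s in prot.sequence])
        s_bond = scales["U_bond"]
        # backbone virtual bonds
        for a, b in prot.chain_slices():
            i = np.arange(a, b - 1)
            dvec = ca[i + 1] - ca[i]
            d = np.linalg.norm(dvec, axis=1)
            terms["U_bond"] += float(np.sum(
                0.5 * params.k_bond_bb * (d - params.d_bb0) ** 2))
            if with_forces:
                dUdd = params.k_bond_bb * (d - params.d_bb0)
                f = (dUdd / d)[:, None] * dvec
                np.add.at(F_ca, i, f * s_bond)
                np.add.at(F_ca, i + 1, -f * s_bond)
        # Ca-SC virtual bonds (zero-length reference handled harmonically)
        w = sc - ca
        d = np.linalg.norm(w, axis=1)
        terms["U_bond"] += float(np.sum(
            0.5 * params.k_bond_sc * (d - d_sc0) ** 2))
        if with_forces:
            safe = np.where(d > 1e-12, d, 1.0)
            dUdd = params.k_bond_sc * (d - d_sc0)
            f = np.where(d[:, None] > 1e-12, (dUdd / safe)[:, None] * w, 0.0)
            F_sc -= f * s_bond
            F_ca += f * s_bond

        # virtual bond angles
        th0 = np.radians(params.theta0)
        s_b = scales["U_b"]
        for a, b in prot.chain_slices():
            for i in range(a + 1, b - 1):
                if with_forces:
                    th, g3 = internal.bond_angle_grad(ca[i - 1], ca[i], ca[i + 1])
                    dU = params.k_theta * (th - th0)
                    for off, g in zip((-1, 0, 1), g3):
                        F_ca[i + off] -= dU * g * s_b
                else:
                    th = np.radians(internal.bond_angle(ca[i - 1], ca[i], ca[i + 1]))
                terms["U_b"] += 0.5 * params.k_theta * (th - th0) ** 2

        # backbone torsions
        s_tor = scales["U_tor"]
        for a, b in prot.chain_slices():
            for i in range(a + 1, b - 2):
                quad = (ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
                try:
                    if with_forces:
                        ph, g4 = internal.dihedral_grad(*quad)
                    else:
                        ph = internal.dihedral(*quad)
                        if np.isnan(ph):
                            continue
                        ph = np.radians(ph)
                except ValueError:
                    continue  # collinear: torsion undefined, skipped
                u, du = _torsion_series(ph, params.tor_a, params.tor_b)
                terms["U_tor"] += u
                if with_forces:
                    for off, g in zip((-1, 0, 1, 2), g4):
                        F_ca[i + off] -= du * g * s_tor

        # side-chain rotamer surrogate
        a0 = np.radians(params.alpha0)
        b0 = np.radians(params.beta0)
        s_rot = scales["U_rot"]
        for a, b in prot.chain_slices():
            for i in range(a + 1, b - 1):
                if d_sc0[i] <= 0:
                    continue
                pts = (ca[i - 1], ca[i], ca[i + 1], sc[i])
                try:
                    if with_forces:
                        al, be, _, G = internal.measure_sc_grad(*pts)
                    else:
                        al, be, _ = internal.measure_sc(*pts)
                        al, be = np.radians(al), np.radians(be)
                except ValueError:
                    continue  # collinear frame: term undefined, skipped
                terms["U_rot"] += 0.5 * params.k_alpha * (al - a0) ** 2
                terms["U_rot"] += 0.5 * params.k_beta * (1.0 - np.cos(be - b0))
                if with_forces:
                    dUa = params.k_alpha * (al - a0)
                    dUb = 0.5 * params.k_beta * np.sin(be - b0)
                    grad = dUa * G["alpha"] + dUb * G["beta"]
                    for row, target, idx in zip(
                            range(4), (F_ca, F_ca, F_ca, F_sc),
                            (i - 1, i, i + 1, i)):
                        target[idx] -= grad[row] * s_rot

        # disulfide double well
        if prot.disulfide_pairs:
            if with_forces:
                u_ss, _, f_ss = disulfide_energy(
                    prot.disulfide_pairs, prot.sequence, sc, params,
                    with_forces=True)
                F_sc += f_ss * scales["U_ssbond"]
            else:
                u_ss, _ = disulfide_energy(prot.disulfide_pairs,
                                           prot.sequence, sc, params)
            terms["U_ssbond"] += u_ss

    # ---- protein nonbonded -------------------------------------------------
    if prot is not None and n >= 2:
        types = list(prot.sequence)
        sig = np.array([params.sigma0[t] for t in types])
        epsv = np.array([params.epsilon[t] for t in types])
        iu, ju = np.triu_indices(n, k=1)
        pair_sig = 0.5 * (sig[iu] + sig[ju])
        pair_eps = np.sqrt(epsv[iu] * epsv[ju])
        dvec = sc[iu] - sc[ju]
        d = np.linalg.norm(dvec, axis=1)
        u, dudr = _lj_pair(d, pair_eps, pair_sig)
        if params.cutoff and params.cutoff > 0:
            mask = d < params.cutoff
            ushift = _lj_pair(np.full_like(d, params.cutoff),
                              pair_eps, pair_sig)[0]
            u = np.where(mask, u - ushift, 0.0)
            dudr = np.where(mask, dudr, 0.0)
        terms["U_SCSC"] += float(np.sum(u))
        if with_forces:
            fpair = (-dudr / d)[:, None] * dvec * scales["U_SCSC"]
            np.add.at(F_sc, iu, fpair)
            np.add.at(F_sc, ju, -fpair)

        # SC - peptide-group excluded volume (flanking groups excluded)
        if len(flanks):
            sc_i, pg_j = [], []
            for i in range(n):
                for j in range(len(flanks)):
                    if i in (flanks[j, 0], flanks[j, 1]):
                        continue
                    sc_i.append(i)
                    pg_j.append(j)
            sc_i = np.array(sc_i, int)
            pg_j = np.array(pg_j, int)
            if len(sc_i):
                dvec = sc[sc_i] - pg[pg_j]
                d = np.linalg.norm(dvec, axis=1)
                u, dudr = _rep12(d, params.eps_rep, params.sigma_rep)
                terms["U_SCp"] += float(np.sum(u))
                if with_forces:
                    fpair = (-dudr / d)[:, None] * dvec * scales["U_SCp"]
                    np.add.at(F_sc, sc_i, fpair)
                    np.add.at(F_pg, pg_j, -fpair)

        # peptide-peptide Lennard-Jones over non-adjacent groups
        m = len(flanks)
        if m >= 2:
            ip, jp = np.triu_indices(m, k=1)
            pg_chain = np.array([prot.chain_ids[f] for f in flanks[:, 0]])
            keep = (jp - ip >= 2) | (pg_chain[ip] != pg_chain[jp])
            ip, jp = ip[keep], jp[keep]
            if len(ip):
                dvec = pg[ip] - pg[jp]
                d = np.linalg.norm(dvec, axis=1)
                u, dudr = _lj_pair(d, params.eps_pp, params.sigma_pp)
                terms["U_pp_VDW"] += float(np.sum(u))
                if with_forces:
                    fpair = (-dudr / d)[:, None] * dvec * scales["U_pp_VDW"]
                    np.add.at(F_pg, ip, fpair)
                    np.add.at(F_pg, jp, -fpair)

    # ---- explicit nanoparticles -------------------------------------------
    for k, part in enumerate(system.particles):
        anc = x[system.anchor_slice(k)]
        cen = x[system.center_slice(k)]
        if with_forces:
            e_r, f_r = restraint_energy(part, anc, with_forces=True)
            F[system.anchor_slice(k)] += f_r * scales["U_restraint"]
        else:
            e_r = restraint_energy(part, anc)
        # anchor-center attachment (radial alignment), restraint ledger
        if with_forces:
            e_al, f_a, f_c = alignment_energy(part, anc, cen,
                                              with_forces=True)
            F[system.anchor_slice(k)] += f_a * scales["U_restraint"]
            F[system.center_slice(k)] += f_c * scales["U_restraint"]
        else:
            e_al = alignment_energy(part, anc, cen)
        terms["U_restraint"] += e_r + e_al

        ct = part.center_type
        # particle centers vs protein side chains (Gay-Berne)
        if prot is not None:
            pair = params.gb_pair(ct, ct)
            for i in range(n):
                pij = params.gb_pair(prot.sequence[i], ct)
                dvec = sc[i] - cen
                d = np.linalg.norm(dvec, axis=1)
                u, dudr = _lj_pair(d, pij.epsilon, pij.sigma0)
                terms["U_nano"] += float(np.sum(u))
                if with_forces:
                    fpair = (-dudr / d)[:, None] * dvec * scales["U_nano"]
                    F_sc[i] += fpair.sum(axis=0)
                    F[system.center_slice(k)] -= fpair
            # particle centers vs protein peptide groups (excluded volume)
            if len(flanks):
                dall = np.linalg.norm(cen[:, None, :] - pg[None, :, :], axis=-1)
                u, dudr = _rep12(dall.ravel(), params.eps_rep, params.sigma_rep)
                terms["U_nano"] += float(np.sum(u))
                if with_forces:
                    dvec = (cen[:, None, :] - pg[None, :, :]).reshape(-1, 3)
                    d = dall.ravel()
                    fpair = (-dudr / d)[:, None] * dvec * scales["U_nano"]
                    F[system.center_slice(k)] += fpair.reshape(20, -1, 3).sum(axis=1)
                    np.add.at(F_pg, np.tile(np.arange(len(flanks)), 20),
                              -fpair)
            del pair
        # intra-particle center-center nonbonded (optional)
        if system.particle_intra_nonbonded:
            pij = params.gb_pair(ct, ct)
            iu, ju = np.triu_indices(20, k=1)
            base = system.center_slice(k).start
            terms["U_nano"] += _pair_accumulate(
                x, F, iu + base, ju + base, pij.epsilon, pij.sigma0,
                "lj", scales["U_nano"])
        # particle-particle cross terms
        for k2 in range(k + 1, len(system.particles)):
            pij = params.gb_pair(ct, system.particles[k2].center_type)
            b1 = system.center_slice(k).start
            b2 = system.center_slice(k2).start
            ii, jj = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
            terms["U_nano"] += _pair_accumulate(
                x, F, ii.ravel() + b1, jj.ravel() + b2,
                pij.epsilon, pij.sigma0, "lj", scales["U_nano"])

    # ---- implicit sphere ---------------------------------------------------
    if system.sphere is not None:
        site_blocks = []
        if prot is not None:
            site_blocks.append(("sc", sc))
            if len(flanks):
                site_blocks.append(("pg", pg))
        for k in range(len(system.particles)):
            site_blocks.append((("cen", k), x[system.center_slice(k)]))
        for tag, sites in site_blocks:
            if with_forces:
                e, _, f = implicit_interaction_energy(
                    sites, system.sphere, with_forces=True)
                f = f * scales["U_nano"]
                if tag == "sc":
                    F_sc += f
                elif tag == "pg":
                    F_pg += f
                else:
                    F[system.center_slice(tag[1])] += f
            else:
                e, _ = implicit_interaction_energy(sites, system.sphere)
            terms["U_nano"] += e

    # ---- pluggable mean-field / multibody terms ---------------------------
    for name, term in (("U_pp_el", system.pp_el_term),
                       ("U_corr3", system.corr3_term),
                       ("U_turn3", system.turn3_term)):
        if term is None:
            continue
        out = term(system, x)
        if isinstance(out, tuple):
            e, f = out
            if with_forces:
                F += np.asarray(f, float) * scales[name]
        else:
            e = out
        terms[name] += float(e)

    # ---- assemble ----------------------------------------------------------
    for name, val in terms.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite energy in term {name}")
    disabled = {name for name, term in
                (("U_pp_el", system.pp_el_term),
                 ("U_corr3", system.corr3_term),
                 ("U_turn3", system.turn3_term)) if term is None}
    bd = EnergyBreakdown(terms=terms, scales=scales, disabled=disabled, T=T)
    bd.total = bd.resum()
    if not with_forces:
        return bd
    # fold protein sub-arrays and peptide-group forces back in
    if prot is not None:
        if len(flanks):
            np.add.at(F_ca, flanks[:, 0], 0.5 * F_pg)
            np.add.at(F_ca, flanks[:, 1], 0.5 * F_pg)
        F[system.ca_slice()] += F_ca
        F[system.sc_slice()] += F_sc
    return bd, F


def forces(system: System, T: float = 300.0, coords=None) -> np.ndarray:
    """Analytic forces, -grad of the weighted total energy."""
    return total_energy(system, T=T, coords=coords, with_forces=True)[1]
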