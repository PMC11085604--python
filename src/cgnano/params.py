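"""Force-field parameter set: defaults, key-value file I/O.

The shipped defaults are a clearly-labelled surrogate parameterization:
the functional forms follow the united-residue effective energy function,
but the published per-residue tables are not reproduced here.  Every
value is configurable through a sectioned key-value text file
(see :func:`save_params` / :func:`load_params`).

Units: lengths Å, energies kcal/mol, force constants kcal/mol/Å^2 or
kcal/mol/rad^2, angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import CA_CA_BOND

AA = "ACDEFGHIKLMNPQRSTVWY"

# Surrogate per-residue Gay-Berne side-chain parameters (spherical limit):
# sigma0 loosely tracks side-chain size, epsilon hydrophobicity.
SIGMA0 = {
    "G": 3.0, "A": 3.5, "S": 3.6, "C": 3.9, "T": 3.9, "V": 4.2,
    "P": 4.1, "L": 4.6, "I": 4.6, "M": 4.8, "F": 5.0, "Y": 5.1,
    "W": 5.4, "D": 4.0, "E": 4.4, "N": 4.1, "Q": 4.5, "K": 4.6,
    "R": 5.0, "H": 4.6,
}
EPSILON = {
    "G": 0.5, "A": 0.8, "S": 0.5, "C": 1.0, "T": 0.6, "V": 1.0,
    "P": 0.7, "L": 1.2, "I": 1.2, "M": 1.2, "F": 1.5, "Y": 1.3,
    "W": 1.6, "D": 0.4, "E": 0.4, "N": 0.6, "Q": 0.6, "K": 0.4,
    "R": 0.4, "H": 0.9,
}
# Calpha to side-chain-centroid virtual bond lengths, Å.
D_SC0 = {
    "G": 0.0, "A": 1.53, "S": 1.9, "C": 2.1, "T": 1.9, "V": 1.96,
    "P": 1.9, "L": 2.6, "I": 2.3, "M": 2.9, "F": 3.4, "Y": 3.8,
    "W": 3.9, "D": 2.5, "E": 3.1, "N": 2.5, "Q": 3.1, "K": 3.5,
    "R": 4.1, "H": 3.1,
}


@dataclass
class GayBerneParams:
    """Gay-Berne pair parameters (spherical limit: sigma == sigma0)."""

    epsilon: float = 1.0
    sigma0: float = 4.0
    sigma: float = None
    anisotropy_ratios: tuple = None  # (kappa, kappa_prime, mu, nu)

    def __post_init__(self):
        if self.sigma is None:
            self.sigma = self.sigma0
        if self.epsilon < 0 or self.sigma0 <= 0 or self.sigma <= 0:
            raise ValueError("Gay-Berne parameters must be positive "
                             "(epsilon >= 0, sigma0 > 0, sigma > 0)")


@dataclass
class KiharaParams:
    """Kihara potential parameters (surrogate phenylalanine-like defaults)."""

    epsilon: float = 1.0
    sigma: float = 3.55

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("Kihara epsilon and sigma must be positive")


@dataclass
class EnergyWeights:
    """Dimensionless multipliers of the effective-energy terms."""

    w_SC: float = 1.0
    w_SCp: float = 1.0
    w_pp_VDW: float = 1.0
    w_pp_el: float = 1.0
    w_tor: float = 1.0
    w_b: float = 1.0
    w_rot: float = 1.0
    w_bond: float = 1.0
    w_ssbond: float = 1.0
    w_corr3: float = 1.0
    w_turn3: float = 1.0

    def __post_init__(self):
        for k, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"weight {k} is not finite")


@dataclass
class ForceFieldParams:
    """Complete surrogate parameter set for the CG energy function."""

    # nonbonded side-chain (Gay-Berne spherical limit) per residue type
    sigma0: dict = field(default_factory=lambda: dict(SIGMA0))
    epsilon: dict = field(default_factory=lambda: dict(EPSILON))
    # bonded
    d_bb0: float = CA_CA_BOND
    k_bond_bb: float = 100.0
    d_sc0: dict = field(default_factory=lambda: dict(D_SC0))
    k_bond_sc: float = 50.0
    theta0: float = 105.0
    k_theta: float = 10.0           # kcal/mol/rad^2
    tor_a: tuple = (0.5,)           # cosine series a_m, m = 1..
    tor_b: tuple = (0.0,)           # sine series b_m
    alpha0: float = 120.0
    k_alpha: float = 5.0            # kcal/mol/rad^2
    beta0: float = 0.0
    k_beta: float = 2.0             # kcal/mol
    # side-chain / peptide-group excluded volume
    eps_rep: float = 0.3
    sigma_rep: float = 3.4
    # peptide-peptide Lennard-Jones
    eps_pp: float = 0.3
    sigma_pp: float = 3.7
    # dynamic disulfide double well
    ss_depth: float = 6.0           # E_ss, kcal/mol
    ss_barrier: float = 1.0         # barrier height above the plateau
    d_ss0: float = 4.0              # bonded SC-SC distance, Å
    ss_x_barrier: float = 1.5       # barrier offset from d_ss0, Å
    ss_x_plateau: float = 3.0       # plateau offset, Å
    # implicit-sphere Kihara (surrogate phenylalanine-like)
    kihara_eps: float = 1.0
    kihara_sigma: float = 3.55
    # optional nonbonded cutoff, Å (None/0 = no cutoff); energy-shifted
    cutoff: float = 0.0

    def gb_pair(self, type_i: str, type_j: str) -> GayBerneParams:
        """Pair parameters via Lorentz (sigma) / Berthelot (epsilon) rules."""
        s = 0.5 * (self.sigma0[type_i] + self.sigma0[type_j])
        e = float(np.sqrt(self.epsilon[type_i] * self.epsilon[type_j]))
        return GayBerneParams(epsilon=e, sigma0=s)

    def require_types(self, types):
        missing = sorted({t for t in types if t not in self.sigma0
                          or t not in self.epsilon or t not in self.d_sc0})
        if missing:
            raise KeyError(f"parameter set missing residue type(s): {missing}")


_SECTIONS = {
    "bonded": ["d_bb0", "k_bond_bb", "k_bond_sc", "theta0", "k_theta",
               "alpha0", "k_alpha", "beta0", "k_beta"],
    "torsion": ["tor_a", "tor_b"],
    "excluded_volume": ["eps_rep", "sigma_rep"],
    "peptide_lj": ["eps_pp", "sigma_pp"],
    "disulfide": ["ss_depth", "ss_barrier", "d_ss0", "ss_x_barrier",
                  "ss_x_plateau"],
    "kihara": ["kihara_eps", "kihara_sigma"],
    "nonbonded": ["cutoff"],
}


def save_params(params: ForceFieldParams, path):
    """Write the parameter set as a sectioned key-value text file."""
    lines = [
        "# cgnano force-field parameters (surrogate defaults)",
        "# units: Å, kcal/mol, kcal/mol/Å^2, kcal/mol/rad^2, degrees",
    ]
    for sec, keys in _SECTIONS.items():
        lines.append(f"[{sec}]")
        for k in keys:
            v = getattr(params, k)
            if isinstance(v, (tuple, list)):
                v = ",".join(str(x) for x in v)
            lines.append(f"{k} = {v}")
    lines.append("[sidechain_sigma0]")
    lines += [f"{t} = {params.sigma0[t]}" for t in sorted(params.sigma0)]
    lines.append("[sidechain_epsilon]")
    lines += [f"{t} = {params.epsilon[t]}" for t in sorted(params.epsilon)]
    lines.append("[sidechain_d_sc0]")
    lines += [f"{t} = {params.d_sc0[t]}" for t in sorted(params.d_sc0)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_params(path) -> ForceFieldParams:
    """Read a parameter file written by :func:`save_params`."""
    params = ForceFieldParams()
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                continue
            if "=" not in line:
                raise ValueError(f"malformed parameter line: {raw.rstrip()!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if section == "sidechain_sigma0":
                params.sigma0[key] = float(val)
            elif section == "sidechain_epsilon":
                params.epsilon[key] = float(val)
            elif section == "sidechain_d_sc0":
                params.d_sc0[key] = float(val)
            elif key in ("tor_a", "tor_b"):
                setattr(params, key,
                        tuple(float(x) for x in val.split(",") if x.strip()))
            elif hasattr(params, key):
                setattr(params, key, float(val))
            else:
                raise KeyError(f"unknown parameter key {key!r}")
    return params
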