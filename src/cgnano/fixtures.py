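"""Deterministic synthetic systems for testing and demonstration.

Builds idealized CG peptides (extended chains, helices) from internal
coordinates and toy protein-nanoparticle complexes with guaranteed
initial contacts, so every operation in the package can be exercised
without any external structure files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CA_CA_BOND
from .nanoparticle import ImplicitSphere, build_explicit_c60
from .params import ForceFieldParams, KiharaParams
from .system import System
from .topology import CGGeometry, CGProtein, rebuild_cartesian

# Conventional Calpha-trace angles for an ideal helix; the precise values
# are a documented convention, not a fitted quantity.
HELIX_THETA = 90.0
HELIX_GAMMA = 50.0


@dataclass
class FixtureSpec:
    kind: str = "ideal_helix"        # ideal_helix | extended_chain
    n_residues: int = 12
    sequence: str = None             # default poly-alanine
    seed: int = 0
    d_bb: float = CA_CA_BOND
    theta: float = None              # kind default if None
    gamma: float = None
    jitter: float = 0.0              # optional seeded Cartesian noise, Å

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("fixtures need at least 4 residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def _kind_angles(spec: FixtureSpec):
    if spec.kind == "extended_chain":
        return (180.0 if spec.theta is None else spec.theta,
                180.0 if spec.gamma is None else spec.gamma)
    if spec.kind == "ideal_helix":
        return (HELIX_THETA if spec.theta is None else spec.theta,
                HELIX_GAMMA if spec.gamma is None else spec.gamma)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def build_synthetic_peptide(spec: FixtureSpec,
                            params: ForceFieldParams = None) -> CGProtein:
    """Build a CG peptide from kind-specific internal coordinates.

    The Calpha trace comes from the natural-extension construction with
    uniform (d, theta, gamma); side chains are placed at the bonded
    reference (alpha0, beta0, d_sc0 per residue type).  Identical specs
    produce bit-identical coordinates.
    """
    params = params or ForceFieldParams()
    n = spec.n_residues
    seq = spec.sequence or "A" * n
    theta_v, gamma_v = _kind_angles(spec)
    theta = np.full(n - 2, float(theta_v))
    gamma = np.full(n - 3, float(gamma_v))
    d_sc = np.array([params.d_sc0[s] for s in seq])
    alpha = np.full(n, np.nan)
    beta = np.full(n, np.nan)
    if theta_v < 180.0:
        alpha[1:n - 1] = params.alpha0
        beta[1:n - 1] = params.beta0
    geo = CGGeometry(theta, gamma, alpha, beta, np.full(n - 1, spec.d_bb),
                     d_sc, [n])
    prot = rebuild_cartesian(geo, sequence=seq)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        prot.ca_xyz += rng.normal(scale=spec.jitter, size=prot.ca_xyz.shape)
        prot.sc_xyz += rng.normal(scale=spec.jitter, size=prot.sc_xyz.shape)
    ss = [(i, j) for i in range(n) for j in range(i + 1, n)
          if seq[i] == "C" and seq[j] == "C"]
    prot.disulfide_pairs = ss[:1]  # at most the first pair by default
    return prot


def _horseshoe_protein(n_res, seq, arc_radius, params) -> CGProtein:
    """Calpha arc around the origin, side chains pointing inward."""
    step = 2.0 * np.arcsin(min(CA_CA_BOND / (2.0 * arc_radius), 1.0))
    angles = (np.arange(n_res) - (n_res - 1) / 2.0) * step
    ca = np.stack([arc_radius * np.cos(angles),
                   arc_radius * np.sin(angles),
                   np.zeros(n_res)], axis=1)
    d_sc = np.array([params.d_sc0[s] for s in seq])
    # inward with a small out-of-plane tilt: keeps the side chains facing
    # the particle while avoiding the singular anti-bisector orientation
    # of the (alpha, beta) parameterization
    inward = -ca / np.linalg.norm(ca, axis=1)[:, None]
    inward[:, 2] = 0.35
    inward /= np.linalg.norm(inward, axis=1)[:, None]
    sc = ca + d_sc[:, None] * inward
    return CGProtein(seq, ca, sc)


def build_toy_pocket_complex(n_residues: int = 10, sequence: str = None,
                             model: str = "explicit",
                             arc_radius: float = None,
                             offset=(0.0, 0.0, 0.0),
                             params: ForceFieldParams = None,
                             weights=None) -> System:
    """Horseshoe peptide partially enclosing a C60 nanoparticle.

    The peptide Calpha trace is an arc of the given radius around the
    nanoparticle center (plus ``offset``); side chains point at the
    particle, guaranteeing protein-nanoparticle contacts at the 8 Å
    cutoff for the default geometry.  ``model`` selects the explicit
    dodecahedral particle or the implicit Kihara sphere.
    """
    params = params or ForceFieldParams()
    seq = sequence or "A" * n_residues
    if arc_radius is None:
        # explicit: side chains in the Gay-Berne well of the particle
        # surface; implicit: inside the Kihara attraction and the 8 Å
        # center-distance contact convention
        arc_radius = 9.0 if model == "explicit" else 9.3
    prot = _horseshoe_protein(n_residues, seq, arc_radius, params)
    offset = np.asarray(offset, float)
    kwargs = {"params": params}
    if weights is not None:
        kwargs["weights"] = weights
    if model == "explicit":
        part = build_explicit_c60()
        part.sc_xyz = part.sc_xyz + offset
        part.ca_xyz = part.ca_xyz + offset
        return System(protein=prot, particles=[part], **kwargs)
    if model == "implicit":
        sphere = ImplicitSphere(center=offset, R0=3.5,
                                kihara=KiharaParams(params.kihara_eps,
                                                    params.kihara_sigma))
        r = np.linalg.norm(
            np.concatenate([prot.ca_xyz, prot.sc_xyz, prot.pg_xyz])
            - sphere.center, axis=1)
        if np.any(r <= sphere.R0):
            raise ValueError("steric overlap: protein site inside the "
                             "implicit nanoparticle core")
        return System(protein=prot, sphere=sphere, **kwargs)
    raise ValueError(f"unknown model {model!r} (explicit | implicit)")
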