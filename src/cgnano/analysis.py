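"""Trajectory-ensemble analyses.

Contact probability from the fullerene and protein perspectives, contact
counts, superposed RMSD, mass-weighted RMSF, radius of gyration (with the
per-frame maximum site-to-center distance), a coarse-grained
Shrake-Rupley solvent-accessible surface area, native-contact fractions,
and disulfide-distance distributions.  Contact analyses use the 8 Å
cutoff convention unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import System

DEFAULT_CUTOFF = 8.0


# ---------------------------------------------------------------------------
# site selection helpers
# ---------------------------------------------------------------------------

def protein_site_indices(system: System, sc_only: bool = False):
    """Indices of protein interaction sites in the dynamic coordinate array.

    By default Calpha and SC sites (peptide groups are derived and added
    separately by the distance helpers); with ``sc_only`` just SC sites.
    """
    n = system.n_res
    if sc_only:
        return np.arange(n, 2 * n)
    return np.arange(0, 2 * n)


def _protein_points(system: System, frame, sc_only=False):
    """Protein site coordinates (including derived peptide groups)."""
    n = system.n_res
    ca = frame[:n]
    sc = frame[n:2 * n]
    if sc_only:
        return sc
    flanks = system.protein.pg_flanks()
    pg = (0.5 * (ca[flanks[:, 0]] + ca[flanks[:, 1]])
          if len(flanks) else np.empty((0, 3)))
    return np.concatenate([ca, sc, pg])


def nanoparticle_centers(system: System, frame):
    """Fullerene interaction-center coordinates for one frame.

    Explicit particles contribute their 20 centers each; an implicit
    sphere contributes its fixed center.
    """
    blocks = [frame[system.center_slice(k)]
              for k in range(len(system.particles))]
    if system.sphere is not None:
        blocks.append(system.sphere.center[None, :])
    if not blocks:
        raise ValueError("system has no nanoparticle")
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactProbabilityMatrix:
    axis_a: np.ndarray          # center indices (fullerene) / residues (protein)
    axis_b: np.ndarray          # time-bin index (or the single aggregate 0)
    values: np.ndarray          # probabilities in [0, 1], shape (a, b)
    cutoff: float
    n_trajectories: int
    perspective: str


def contact_probability(trajectories, system: System,
                        cutoff: float = DEFAULT_CUTOFF,
                        perspective: str = "fullerene",
                        n_time_bins: int = 1,
                        sc_only: bool = False) -> ContactProbabilityMatrix:
    """Ensemble contact probability from either perspective.

    Fullerene perspective: per nanoparticle center, the fraction of
    (frame, trajectory) samples in which at least one protein site lies
    within the cutoff.  Protein perspective: per residue, the fraction in
    which at least one center lies within the cutoff.  The ensemble value
    is the arithmetic mean of per-trajectory indicator means; optional
    equal-width time bins resolve the probability along the trajectory.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not trajectories:
        raise ValueError("need at least one trajectory")
    trajectories = list(np.atleast_1d(trajectories))
    n_sites = {t.frames.shape[1] for t in trajectories}
    if len(n_sites) != 1 or n_sites.pop() != system.n_sites:
        raise ValueError("trajectories do not match the system definition")

    n_axis = (nanoparticle_centers(system, trajectories[0].frames[0]).shape[0]
              if perspective == "fullerene" else system.n_res)
    per_traj = np.zeros((len(trajectories), n_axis, n_time_bins))
    for t_i, traj in enumerate(trajectories):
        nf = traj.n_frames
        bins = np.minimum((np.arange(nf) * n_time_bins) // max(nf, 1),
                          n_time_bins - 1)
        counts = np.zeros((n_axis, n_time_bins))
        totals = np.zeros(n_time_bins)
        for f_i, frame in enumerate(traj.frames):
            centers = nanoparticle_centers(system, frame)
            prot = _protein_points(system, frame, sc_only)
            dmat = np.linalg.norm(centers[:, None, :] - prot[None, :, :],
                                  axis=-1)
            if perspective == "fullerene":
                hit = (dmat <= cutoff).any(axis=1)
            elif perspective == "protein":
                site_hit = (dmat <= cutoff).any(axis=0)
                hit = _fold_sites_to_residues(system, site_hit, sc_only)
            else:
                raise ValueError("perspective must be 'fullerene' or 'protein'")
            counts[:, bins[f_i]] += hit
            totals[bins[f_i]] += 1
        per_traj[t_i] = counts / np.maximum(totals, 1)
    values = per_traj.mean(axis=0)
    return ContactProbabilityMatrix(np.arange(n_axis), np.arange(n_time_bins),
                                    values, cutoff, len(trajectories),
                                    perspective)


def _fold_sites_to_residues(system, site_hit, sc_only):
    """OR site-level contact indicators into per-residue indicators."""
    n = system.n_res
    if sc_only:
        return site_hit.astype(float)
    res_hit = site_hit[:n] | site_hit[n:2 * n]
    flanks = system.protein.pg_flanks()
    for j, (i1, i2) in enumerate(flanks):
        if site_hit[2 * n + j]:
            res_hit[i1] = res_hit[i2] = True
    return res_hit.astype(float)


def contacts_count_series(trajectory, system: System,
                          cutoff: float = DEFAULT_CUTOFF,
                          sc_only: bool = False) -> np.ndarray:
    """Per-frame count of protein residues in contact with the nanoparticle."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = np.zeros(trajectory.n_frames, int)
    for f_i, frame in enumerate(trajectory.frames):
        centers = nanoparticle_centers(system, frame)
        prot = _protein_points(system, frame, sc_only)
        dmat = np.linalg.norm(centers[:, None, :] - prot[None, :, :], axis=-1)
        site_hit = (dmat <= cutoff).any(axis=0)
        out[f_i] = int(_fold_sites_to_residues(system, site_hit, sc_only).sum())
    return out


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile, reference, weights=None):
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates.  Standard SVD solution of the
    weighted least-squares rotation problem.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 sites")
    w = (np.ones(len(mobile)) if weights is None
         else np.asarray(weights, float))
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return P @ R.T + rc


def rmsd(mobile, reference, weights=None, superpose=True):
    """(Optionally superposed) root-mean-square deviation, Å."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if superpose:
        mobile = kabsch_superpose(mobile, reference, weights)
    w = (np.ones(len(mobile)) if weights is None
         else np.asarray(weights, float))
    w = w / w.sum()
    return float(np.sqrt(np.sum(w * np.sum((mobile - reference) ** 2, axis=1))))


def rmsd_series(trajectory, reference, selection=None, weights=None):
    """Per-frame Calpha (or selected-site) RMSD after optimal superposition."""
    reference = np.asarray(reference, float)
    sel = (np.arange(reference.shape[0]) if selection is None
           else np.asarray(selection, int))
    ref = reference if selection is None else reference
    if ref.shape[0] != len(sel):
        raise ValueError("reference must match the selection size")
    return np.array([rmsd(frame[sel], ref, weights)
                     for frame in trajectory.frames])


def rmsf(trajectories, selection, masses=None, n_iter: int = 3):
    """Mass-weighted RMSF about the ensemble-average structure, per site.

    Frames are iteratively superposed (mass-weighted fit) onto the running
    average structure; RMSF_i = sqrt(<|r_i - <r_i>|^2>).  For several
    trajectories the per-trajectory RMSF profiles are averaged.
    """
    trajectories = list(np.atleast_1d(trajectories))
    sel = np.asarray(selection, int)
    profiles = []
    for traj in trajectories:
        X = traj.frames[:, sel, :]
        if X.shape[0] < 2:
            raise ValueError("RMSF needs at least 2 frames")
        mean = X[0]
        for _ in range(max(n_iter, 50)):
            fitted = np.array([kabsch_superpose(f, mean, masses) for f in X])
            new_mean = fitted.mean(axis=0)
            delta = np.abs(new_mean - mean).max()
            mean = new_mean
            if n_iter <= 1 or delta < 1e-12:
                break
        profiles.append(np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0)))
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# size and surface
# ---------------------------------------------------------------------------

def radius_of_gyration(coords, masses=None):
    """(Rg, max_Rg): mass-weighted radius of gyration and the per-frame
    maximum site-to-center-of-mass distance, Å."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    m = (np.ones(len(coords)) if masses is None
         else np.asarray(masses, float))
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    r2 = np.sum((coords - com) ** 2, axis=1)
    rg = float(np.sqrt(np.sum(m * r2) / m.sum()))
    return rg, float(np.sqrt(r2.max()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sample point")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sasa(coords, radii, probe: float = 1.4, n_points: int = 960):
    """Shrake-Rupley solvent-accessible surface area over CG spheres.

    Each site is a sphere of the given radius; test points on the
    probe-inflated sphere count as accessible when outside every other
    site's inflated sphere.  Deterministic for a fixed ``n_points``.
    Returns (total, per_site) in Å^2.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("site radii must be positive")
    if n_points < 1:
        raise ValueError("need at least one sample point")
    unit = fibonacci_sphere(n_points)
    R = radii + probe
    per_site = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + R[i] * unit
        accessible = np.ones(n_points, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= R[i] + R[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > R[j] ** 2
        per_site[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return float(per_site.sum()), per_site


# ---------------------------------------------------------------------------
# native contacts, disulfides
# ---------------------------------------------------------------------------

def native_contact_fraction(trajectory, reference, cutoff: float = DEFAULT_CUTOFF,
                            min_sequence_separation: int = 3,
                            selection=None):
    """Per-frame fraction of native pairs still within the cutoff.

    The native set is every site pair of the reference within the cutoff
    with sequence separation >= ``min_sequence_separation``.
    """
    reference = np.asarray(reference, float)
    sel = (np.arange(reference.shape[0]) if selection is None
           else np.asarray(selection, int))
    n = len(sel)
    iu, ju = np.triu_indices(n, k=min_sequence_separation)
    dref = np.linalg.norm(reference[iu] - reference[ju], axis=1)
    native = dref <= cutoff
    if not native.any():
        raise ValueError("empty native contact set")
    ni, nj = iu[native], ju[native]
    out = np.zeros(trajectory.n_frames)
    for f_i, frame in enumerate(trajectory.frames):
        x = frame[sel]
        d = np.linalg.norm(x[ni] - x[nj], axis=1)
        out[f_i] = float((d <= cutoff).mean())
    return out


def ss_distance_distribution(trajectories, system: System, pairs=None,
                             quantiles=(5, 25, 50, 75, 95)):
    """Cys SC-SC distance samples pooled over frames and trajectories.

    Returns {pair: {"samples": array, "quantiles": {q: value}}}.
    """
    prot = system.protein
    pairs = prot.disulfide_pairs if pairs is None else pairs
    for i, j in pairs:
        if prot.sequence[i] != "C" or prot.sequence[j] != "C":
            raise ValueError(f"pair ({i}, {j}) is not Cys-Cys")
    trajectories = list(np.atleast_1d(trajectories))
    n = system.n_res
    out = {}
    for i, j in pairs:
        samples = np.concatenate([
            np.linalg.norm(t.frames[:, n + i, :] - t.frames[:, n + j, :],
                           axis=1)
            for t in trajectories])
        out[(i, j)] = {
            "samples": samples,
            "quantiles": {q: float(np.percentile(samples, q))
                          for q in quantiles},
        }
    return out
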