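"""Protein-nanoparticle binding-energy estimation and cross correlations.

Explicit model: per frame, E_binding = E_complex - (E_protein + E_nano),
where the protein and particle energies are re-evaluated on the frozen
complex coordinates with the partner removed, so intramolecular terms
cancel exactly and E_binding reduces to the cross-interaction energy.

Implicit model: the binding energy is read directly from the Kihara
interaction potential summed over protein sites.

Trajectories that end dissociated (a sustained contact-free terminal
window at the 8 Å cutoff) are excluded from ensemble averages, mirroring
the convention that averages are computed only over trajectories in
which dissociation was not observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .analysis import DEFAULT_CUTOFF, contacts_count_series
from .energy import total_energy
from .nanoparticle import implicit_interaction_energy
from .system import System


@dataclass
class BindingEnergyResult:
    per_frame: list                      # one energy array per trajectory
    mean: float
    sd: float
    n_frames_used: int
    dissociated: list                    # bool per trajectory
    excluded_trajectories: list = field(default_factory=list)
    per_trajectory_mean: list = field(default_factory=list)


def detect_dissociation(trajectory, system: System,
                        cutoff: float = DEFAULT_CUTOFF,
                        window: int = None):
    """Sustained terminal loss of all protein-nanoparticle contacts.

    The trajectory is dissociated when its final ``window`` frames
    (default: the last 10% of frames, at least 1) are all contact-free at
    the cutoff.  Returns (dissociated, first_frame) where first_frame is
    the first frame of the terminal contact-free run (None if bound).
    Intermittent contact loss shorter than the window does not count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counts = contacts_count_series(trajectory, system, cutoff)
    if len(counts) == 0:
        raise ValueError("empty trajectory")
    if window is None:
        window = max(1, len(counts) // 10)
    if np.any(counts[-window:] > 0):
        return False, None
    first = len(counts)
    while first > 0 and counts[first - 1] == 0:
        first -= 1
    return True, first


def _frame_range(n_frames, frames):
    if frames == "second_half":
        return range(n_frames // 2, n_frames)
    if frames == "all":
        return range(n_frames)
    return frames


def _aggregate(per_frame, dissociated, exclude):
    kept = [i for i in range(len(per_frame))
            if not (exclude and dissociated[i])]
    excluded = [i for i in range(len(per_frame)) if i not in kept]
    traj_means = [float(np.mean(per_frame[i])) for i in kept]
    if traj_means:
        mean = float(np.mean(traj_means))
        # spread over trajectory means (single trajectory: over frames)
        sd = (float(np.std(traj_means, ddof=1)) if len(traj_means) > 1
              else float(np.std(per_frame[kept[0]])))
    else:
        mean, sd = float("nan"), float("nan")
    n_used = sum(len(per_frame[i]) for i in kept)
    return mean, sd, n_used, excluded, traj_means


def binding_energy_explicit(trajectories, system: System, T: float = 260.0,
                            frames="second_half",
                            exclude_dissociated: bool = True,
                            cutoff: float = DEFAULT_CUTOFF) -> BindingEnergyResult:
    """Binding energy of the explicit-particle complex.

    E_complex is the full-system energy; E_protein and E_nano are
    evaluated on identical frozen coordinates with the partner deleted.
    Statistics default to the second half of each trajectory; the mean
    and sd are taken over per-trajectory means, excluding trajectories
    flagged dissociated.
    """
    if system.protein is None or not system.particles:
        raise ValueError("explicit binding energy needs a protein and an "
                         "explicit nanoparticle in the system")
    trajectories = list(np.atleast_1d(trajectories))
    sub_p = system.protein_only()
    sub_n = system.particles_only()
    n2 = 2 * system.n_res
    per_frame, dissoc = [], []
    for traj in trajectories:
        rows = []
        for f_i in _frame_range(traj.n_frames, frames):
            x = traj.frames[f_i]
            e_complex = total_energy(system, T=T, coords=x).total
            e_prot = total_energy(sub_p, T=T, coords=x[:n2]).total
            e_nano = total_energy(sub_n, T=T, coords=x[n2:]).total
            rows.append(e_complex - (e_prot + e_nano))
        per_frame.append(np.array(rows))
        dissoc.append(detect_dissociation(traj, system, cutoff)[0])
    mean, sd, n_used, excluded, tmeans = _aggregate(per_frame, dissoc,
                                                    exclude_dissociated)
    return BindingEnergyResult(per_frame, mean, sd, n_used, dissoc,
                               excluded, tmeans)


def binding_energy_implicit(trajectories, system: System,
                            frames="second_half",
                            exclude_dissociated: bool = False,
                            cutoff: float = DEFAULT_CUTOFF) -> BindingEnergyResult:
    """Binding energy of the implicit-sphere model.

    Read directly from the interaction potential: the per-frame sum of
    Kihara terms over protein SC and peptide-group sites.
    """
    if system.sphere is None:
        raise ValueError("system has no implicit sphere")
    trajectories = list(np.atleast_1d(trajectories))
    n = system.n_res
    flanks = system.protein.pg_flanks()
    per_frame, dissoc = [], []
    for traj in trajectories:
        rows = []
        for f_i in _frame_range(traj.n_frames, frames):
            x = traj.frames[f_i]
            sc = x[n:2 * n]
            sites = [sc]
            if len(flanks):
                sites.append(0.5 * (x[flanks[:, 0]] + x[flanks[:, 1]]))
            e, _ = implicit_interaction_energy(np.concatenate(sites),
                                               system.sphere)
            rows.append(e)
        per_frame.append(np.array(rows))
        dissoc.append(detect_dissociation(traj, system, cutoff)[0])
    mean, sd, n_used, excluded, tmeans = _aggregate(per_frame, dissoc,
                                                    exclude_dissociated)
    return BindingEnergyResult(per_frame, mean, sd, n_used, dissoc,
                               excluded, tmeans)


def correlate_energies(x, y, exclude=None):
    """Ordinary least squares y = slope*x + intercept with R^2.

    R^2 is the squared Pearson correlation (symmetric under swapping the
    arguments); ``exclude`` drops the listed indices from both columns
    before fitting (e.g. to leave out named systems).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if exclude is not None:
        keep = np.setdiff1d(np.arange(len(x)), np.asarray(exclude, int))
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)
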