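"""Shared fixtures: synthetic peptides, toy complexes, short trajectories.

Everything is generated programmatically and deterministically; expensive
objects (minimized systems, short MD runs) are session-scoped.
"""

import numpy as np
import pytest

from cgnano import (FixtureSpec, SimulationConfig, System,
                    build_synthetic_peptide, build_toy_pocket_complex,
                    minimize, run_md)


@pytest.fixture(scope="session")
def helix10():
    return build_synthetic_peptide(FixtureSpec(kind="ideal_helix",
                                               n_residues=10))


@pytest.fixture(scope="session")
def extended8():
    return build_synthetic_peptide(FixtureSpec(kind="extended_chain",
                                               n_residues=8))


@pytest.fixture(scope="session")
def minimized_helix(helix10):
    sys_ = System(protein=helix10.copy())
    minimize(sys_, grad_tol=1e-5, max_iter=1000)
    return sys_


@pytest.fixture(scope="session")
def explicit_complex():
    sys_ = build_toy_pocket_complex(n_residues=10, model="explicit")
    minimize(sys_, grad_tol=1e-3, max_iter=400)
    return sys_


@pytest.fixture(scope="session")
def implicit_complex():
    sys_ = build_toy_pocket_complex(n_residues=10, model="implicit")
    minimize(sys_, grad_tol=1e-3, max_iter=400)
    return sys_


@pytest.fixture(scope="session")
def explicit_trajectory(explicit_complex):
    sys_ = explicit_complex.copy()
    traj = run_md(sys_, SimulationConfig(n_steps=2000, save_every=100,
                                         seed=11))
    return traj, explicit_complex


@pytest.fixture(scope="session")
def implicit_trajectory(implicit_complex):
    sys_ = implicit_complex.copy()
    traj = run_md(sys_, SimulationConfig(n_steps=2000, save_every=100,
                                         seed=12))
    return traj, implicit_complex


def static_trajectory(system, n_frames=4):
    """Trajectory whose frames all equal the current coordinates."""
    from cgnano.dynamics import Trajectory
    x = system.coords()
    cfg = SimulationConfig(n_steps=n_frames - 1, save_every=1)
    return Trajectory(np.array([x] * n_frames),
                      np.arange(n_frames, dtype=float) + 1.0,
                      [None] * n_frames, np.zeros(n_frames), cfg)


@pytest.fixture
def make_static_trajectory():
    return static_trajectory
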