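"""Energy minimization and thermostatted coarse-grained MD.

Velocity-Verlet integration in (Å, fs, amu, kcal/mol) units with
Maxwell-Boltzmann initial velocities, optional Berendsen weak-coupling or
Langevin thermostats, and deterministic seeding: an identical seed and
configuration reproduce a trajectory bit-exactly on one machine.

The "speed-up factor" of the coarse-grained effective energy (default
1000) is bookkeeping only: it converts integration time to reported
laboratory time and is never applied to forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import ACC_CONVERSION, KB
from .energy import total_energy
from .system import System


@dataclass
class SimulationConfig:
    dt: float = 4.89                 # fs
    n_steps: int = 10000
    temperature: float = 260.0       # K
    thermostat: str = "berendsen"    # berendsen | langevin | none
    tau_berendsen: float = 500.0     # fs (0.5 ps)
    gamma_langevin: float = 0.01     # fs^-1
    seed: int = 0
    save_every: int = 100
    speedup_factor: float = 1000.0
    energy_bound: float = 1e9        # abort threshold, kcal/mol
    n_trajectories: int = 20
    remove_com_motion: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.thermostat not in ("berendsen", "langevin", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.temperature <= 0:
            raise ValueError("temperature must be positive when thermostatted")


@dataclass
class Trajectory:
    """Ordered coordinate frames for all dynamic sites plus a log."""

    frames: np.ndarray               # (n_frames, n_sites, 3)
    times: np.ndarray                # fs
    energies: list                   # EnergyBreakdown per saved frame
    temperatures: np.ndarray         # instantaneous K
    config: SimulationConfig
    trajectory_id: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self):
        return self.frames.shape[0]


class EnergyExplosionError(RuntimeError):
    def __init__(self, step, energy):
        super().__init__(
            f"energy {energy:.3e} kcal/mol exceeded bound at step {step}")
        self.step = step
        self.energy = energy


def berendsen_scale(T_inst: float, T_target: float, dt: float,
                    tau: float) -> float:
    """Berendsen weak-coupling velocity scaling factor.

    lambda = sqrt(1 + (dt/tau)(T_target/T_inst - 1)), clamped to
    [0.8, 1.25] per step for stability on small systems.
    """
    if T_inst <= 0:
        raise ValueError("instantaneous temperature must be positive")
    lam = np.sqrt(1.0 + (dt / tau) * (T_target / T_inst - 1.0))
    return float(np.clip(lam, 0.8, 1.25))


def laboratory_time(config: SimulationConfig, n_trajectories: int = 1) -> float:
    """Reported laboratory time in microseconds.

    n_steps x dt x speedup_factor per trajectory, times the number of
    trajectories (1 fs = 1e-9 us).
    """
    per_traj = config.n_steps * config.dt * config.speedup_factor * 1e-9
    return per_traj * n_trajectories


def kinetic_temperature(vel, masses, n_dof=None):
    """Instantaneous temperature from velocities (Å/fs) and masses (amu)."""
    ke = 0.5 * np.sum(masses[:, None] * vel ** 2) / ACC_CONVERSION
    if n_dof is None:
        n_dof = 3 * len(masses)
    return 2.0 * ke / (n_dof * KB)


def maxwell_boltzmann_velocities(masses, T, rng, remove_com=True):
    """Velocities (Å/fs) drawn from the Maxwell-Boltzmann distribution."""
    sigma = np.sqrt(KB * T * ACC_CONVERSION / masses)
    vel = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    if remove_com:
        p = (masses[:, None] * vel).sum(axis=0)
        vel -= p / masses.sum()
    return vel


def minimize(system: System, grad_tol: float = 1e-4, max_iter: int = 2000,
             T: float = 300.0):
    """Minimize the effective energy; returns (system, info).

    Quasi-Newton (L-BFGS-B) with analytic gradients; converged when the
    gradient max-norm drops below ``grad_tol`` (kcal/mol/Å) or after
    ``max_iter`` iterations (reported in ``info``).  The system is
    updated in place with the minimized coordinates.
    """
    x0 = system.coords()
    shape = x0.shape
    e0 = total_energy(system, T=T, coords=x0).total
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy")

    def fun(xf):
        bd, F = total_energy(system, T=T, coords=xf.reshape(shape),
                             with_forces=True)
        if not np.isfinite(bd.total):
            raise FloatingPointError("non-finite energy during line search")
        return bd.total, -F.ravel()

    res = _scipy_minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iter, "gtol": grad_tol,
                                   "ftol": 1e-14})
    x_min = res.x.reshape(shape)
    e_min = float(res.fun)
    if e_min > e0 + 1e-9:     # never accept an uphill result
        x_min, e_min = x0, e0
    system.set_coords(x_min)
    grad_max = float(np.abs(res.jac).max())
    info = {"energy": e_min, "initial_energy": float(e0),
            "n_iterations": int(res.nit), "grad_max": grad_max,
            "converged": bool(grad_max <= grad_tol or res.success)}
    return system, info


def run_md(system: System, config: SimulationConfig) -> Trajectory:
    """Velocity-Verlet MD; returns the trajectory (system updated in place).

    The implicit sphere, if present, exerts forces but never moves.
    Saved frames are step 0 and every ``save_every`` steps, so the frame
    count is floor(n_steps / save_every) + 1.
    """
    rng = np.random.default_rng(config.seed)
    x = system.coords()
    masses = system.masses()
    # Langevin noise re-injects center-of-mass motion, so all 3N degrees
    # of freedom are thermalized; otherwise the removed COM drops 3.
    if config.thermostat == "langevin" or not config.remove_com_motion:
        n_dof = 3 * len(masses)
    else:
        n_dof = 3 * len(masses) - 3
    T_target = config.temperature
    vel = maxwell_boltzmann_velocities(masses, T_target, rng,
                                       config.remove_com_motion)
    bd, F = total_energy(system, T=T_target, coords=x, with_forces=True)

    inv_m = (ACC_CONVERSION / masses)[:, None]
    frames, times, energies, temps = [], [], [], []

    def record(step):
        frames.append(x.copy())
        times.append(step * config.dt)
        energies.append(bd)
        temps.append(kinetic_temperature(vel, masses, n_dof))

    record(0)
    dt = config.dt
    if config.thermostat == "langevin":
        c1 = np.exp(-config.gamma_langevin * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * T_target
                     * ACC_CONVERSION / masses)[:, None]
    for step in range(1, config.n_steps + 1):
        vel = vel + 0.5 * dt * F * inv_m
        x = x + dt * vel
        bd, F = total_energy(system, T=T_target, coords=x, with_forces=True)
        if abs(bd.total) > config.energy_bound:
            raise EnergyExplosionError(step, bd.total)
        vel = vel + 0.5 * dt * F * inv_m
        if config.thermostat == "berendsen":
            T_inst = kinetic_temperature(vel, masses, n_dof)
            vel = vel * berendsen_scale(T_inst, T_target, dt,
                                        config.tau_berendsen)
        elif config.thermostat == "langevin":
            vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        if step % config.save_every == 0:
            record(step)
    system.set_coords(x)
    return Trajectory(np.array(frames), np.array(times), energies,
                      np.array(temps), config)


def run_ensemble(system: System, config: SimulationConfig,
                 n_trajectories: int = None) -> list:
    """Run N independent trajectories from the same start.

    Trajectory k uses seed ``config.seed + k`` and gets trajectory_id k;
    each starts from the current system coordinates.
    """
    n = config.n_trajectories if n_trajectories is None else n_trajectories
    x0 = system.coords()
    out = []
    for k in range(n):
        system.set_coords(x0)
        cfg = replace(config, seed=config.seed + k)
        traj = run_md(system, cfg)
        traj.trajectory_id = k
        out.append(traj)
    system.set_coords(x0)
    return out
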