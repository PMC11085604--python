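"""File formats: PDB and XYZ structures/trajectories, config, manifest.

PDB reading goes through biotite (altloc resolved by occupancy); CG
structures are written with Calpha sites as "CA" records and side-chain
sites as "CB" pseudo-atoms, explicit nanoparticles as HETATM records with
residue name "C60".  A file containing only CA/CB records is auto-
detected as a CG structure on read.  Trajectories are written as
multi-MODEL PDB or XYZ with frame times (fs) in the comment lines;
coordinates survive round trips at PDB format precision (1e-3 Å).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .constants import ONE_TO_THREE, THREE_TO_ONE
from .system import System
from .topology import CGProtein


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path):
    """Read a PDB file -> CGProtein (CG convention) or biotite AtomArray.

    A file whose amino-acid residues contain only CA/CB atom records is
    interpreted as a coarse-grained structure; anything richer is
    returned as an all-atom biotite AtomArray (first altloc by occupancy).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    aa = atoms[struc.filter_amino_acids(atoms)]
    if aa.array_length() == 0:
        raise ValueError(f"no residues found in {path}")
    names = set(aa.atom_name)
    if names <= {"CA", "CB"}:
        return _cg_from_atoms(aa)
    return atoms


def _cg_from_atoms(aa) -> CGProtein:
    import biotite.structure as struc

    seq, chains, nums, ca, sc = [], [], [], [], []
    for res in struc.residue_iter(aa):
        name3 = res.res_name[0]
        if name3 not in THREE_TO_ONE:
            raise ValueError(f"unknown residue code {name3!r}")
        ca_mask = res.atom_name == "CA"
        if not ca_mask.any():
            raise ValueError(f"CG residue {res.res_id[0]} lacks a CA record")
        cb_mask = res.atom_name == "CB"
        seq.append(THREE_TO_ONE[name3])
        chains.append(str(res.chain_id[0]))
        nums.append(int(res.res_id[0]))
        ca.append(res.coord[ca_mask][0])
        sc.append(res.coord[cb_mask][0] if cb_mask.any()
                  else res.coord[ca_mask][0])
    return CGProtein("".join(seq), np.array(ca), np.array(sc), chains,
                     [], np.array(nums))


def _pdb_atom_line(serial, name, resname, chain, resid, xyz, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:>5d} {name_field:4s} {resname:>3s} {chain:1s}"
            f"{resid:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00")


def _structure_lines(system_or_protein, coords=None, include_pg=False):
    """PDB ATOM/HETATM lines for a CG protein or a full system."""
    if isinstance(system_or_protein, CGProtein):
        system = None
        protein = system_or_protein
    else:
        system = system_or_protein
        protein = system.protein
    lines = []
    serial = 1
    if protein is not None:
        n = protein.n_residues
        ca = coords[:n] if coords is not None else protein.ca_xyz
        sc = coords[n:2 * n] if coords is not None else protein.sc_xyz
        for i in range(n):
            res3 = ONE_TO_THREE[protein.sequence[i]]
            lines.append(_pdb_atom_line(serial, "CA", res3,
                                        protein.chain_ids[i],
                                        int(protein.residue_numbers[i]),
                                        ca[i]))
            serial += 1
            lines.append(_pdb_atom_line(serial, "CB", res3,
                                        protein.chain_ids[i],
                                        int(protein.residue_numbers[i]),
                                        sc[i]))
            serial += 1
        if include_pg:
            flanks = protein.pg_flanks()
            pg = 0.5 * (ca[flanks[:, 0]] + ca[flanks[:, 1]])
            for j in range(len(flanks)):
                lines.append(_pdb_atom_line(serial, "P", "UPG", "P",
                                            j + 1, pg[j], hetatm=True))
                serial += 1
    if system is not None:
        for k, part in enumerate(system.particles):
            anc = (coords[system.anchor_slice(k)] if coords is not None
                   else part.ca_xyz)
            cen = (coords[system.center_slice(k)] if coords is not None
                   else part.sc_xyz)
            for i in range(20):
                lines.append(_pdb_atom_line(serial, "CA", "C60", "X",
                                            i + 1, anc[i], hetatm=True))
                serial += 1
                lines.append(_pdb_atom_line(serial, "CB", "C60", "X",
                                            i + 1, cen[i], hetatm=True))
                serial += 1
    return lines


def write_cg_pdb(system_or_protein, path, include_pg: bool = False):
    """Write a CG structure (protein and/or particles) as a PDB file."""
    lines = _structure_lines(system_or_protein, include_pg=include_pg)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


def write_trajectory(trajectory, system: System, path,
                     format: str = "pdb_models"):
    """Write a trajectory as multi-MODEL PDB or XYZ.

    XYZ comment lines carry "t= <fs>"; PDB MODEL blocks are preceded by a
    REMARK with the frame time.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if format == "pdb_models":
        with open(path, "w") as fh:
            for f_i in range(trajectory.n_frames):
                fh.write(f"MODEL     {f_i + 1:>4d}\n")
                fh.write(f"REMARK   t= {trajectory.times[f_i]:.3f} fs\n")
                fh.write("\n".join(_structure_lines(
                    system, coords=trajectory.frames[f_i])))
                fh.write("\nENDMDL\n")
            fh.write("END\n")
    elif format == "xyz":
        labels = _site_labels(system)
        with open(path, "w") as fh:
            for f_i in range(trajectory.n_frames):
                fh.write(f"{system.n_sites}\n")
                fh.write(f"t= {trajectory.times[f_i]:.3f} fs\n")
                for lab, xyz in zip(labels, trajectory.frames[f_i]):
                    fh.write(f"{lab:<4s} {xyz[0]:12.6f} {xyz[1]:12.6f} "
                             f"{xyz[2]:12.6f}\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def _site_labels(system: System):
    labels = []
    if system.protein is not None:
        labels += ["CA"] * system.n_res + ["CB"] * system.n_res
    for _ in system.particles:
        labels += ["NA"] * 20 + ["NC"] * 20
    return labels


def read_xyz_trajectory(path):
    """Read an XYZ trajectory -> (frames (F, N, 3), times fs)."""
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        comment = lines[pos + 1]
        t = 0.0
        if "t=" in comment:
            t = float(comment.split("t=")[1].split()[0])
        block = lines[pos + 2:pos + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        times.append(t)
        pos += 2 + n
    return np.array(frames, float), np.array(times)


# ---------------------------------------------------------------------------
# key-value config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Sectioned key-value config -> {section: {key: string value}}."""
    out = {}
    section = "global"
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                out.setdefault(section, {})
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            out.setdefault(section, {})[key] = val
    return out


def save_config(config: dict, path):
    lines = []
    for section, entries in config.items():
        lines.append(f"[{section}]")
        lines += [f"{k} = {v}" for k, v in entries.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record: re-running from it reproduces outputs bit-exactly."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    version: str = ""

    def write(self, path):
        from . import __version__
        lines = [f"tool_version = {self.version or __version__}",
                 f"created = {datetime.datetime.now().isoformat()}",
                 f"command = {self.command}",
                 f"seeds = {','.join(str(s) for s in self.seeds)}"]
        lines += [f"input = {p}" for p in self.inputs]
        lines += [f"output = {p}" for p in self.outputs]
        for section, entries in self.config.items():
            lines.append(f"[{section}]")
            lines += [f"{k} = {v}" for k, v in entries.items()]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
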