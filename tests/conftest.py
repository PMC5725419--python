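"""Shared fixtures: hand-built frames and small generated trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clayped import Frame, GeneratorConfig, Role, Trajectory, generate


def build_frame(records, box, time=0.0):
    """Construct a Frame from (name, role, molecule_id, residue_type, xyz) tuples."""
    rows, coords = [], []
    for i, (name, role, mol, res, xyz) in enumerate(records):
        rows.append((i, name, Role(role).value, mol, res))
        coords.append(xyz)
    atoms = pd.DataFrame(rows, columns=["atom_id", "name", "role", "molecule_id", "residue_type"])
    return Frame(atoms, np.asarray(coords, dtype=float), np.asarray(box, dtype=float), time)


def frame_to_traj(*frames):
    """Stack one or more Frames (same atom table) into a Trajectory."""
    f0 = frames[0]
    coords = np.stack([f.coords for f in frames])
    box = np.stack([f.box for f in frames])
    times = np.arange(len(frames)) * 0.1
    return Trajectory(f0.atoms, coords, box, times)


def monomer(mol_id, x, y, z, residue="ALA"):
    """Bead records of a minimal amino acid: CT, OT pair, free amine NT."""
    recs = [
        ("CT", Role.C_TERM_C, mol_id, residue, (x, y, z)),
        ("OT1", Role.C_TERM_O, mol_id, residue, (x + 0.3, y, z - 0.45)),
        ("OT2", Role.C_TERM_O, mol_id, residue, (x - 0.3, y, z - 0.45)),
        ("NT", Role.BACKBONE_N, mol_id, residue, (x, y + 1.2, z + 0.9)),
    ]
    if residue == "ASP":
        recs += [
            ("OD1", Role.SIDECHAIN_O, mol_id, residue, (x + 1.1, y - 0.4, z + 0.6)),
            ("OD2", Role.SIDECHAIN_O, mol_id, residue, (x + 1.9, y + 0.4, z + 0.6)),
        ]
    return recs


def flat_surface(z, nx=8, ny=8, spacing=3.0, mol_id=0):
    """A plain grid of hydroxyl-H beads acting as one LDH face at height z."""
    recs = []
    for i in range(nx):
        for j in range(ny):
            recs.append(("HO", Role.LDH_HYDROXYL_H, mol_id, "LDH", (i * spacing, j * spacing, z)))
    return recs


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(nx=8, ny=8, n_layers=2, rng_seed=11, hydration=3)


@pytest.fixture(scope="session")
def small_traj(small_cfg):
    traj, series = generate(small_cfg, ["ALA"] * 8 + ["ASP"] * 3 + ["6LEU"] * 2, n_frames=25)
    return traj, series
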