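"""Trajectory containers, atom-role mapping, and file readers/writers.

Internal units are Angstrom and nanoseconds throughout.  A trajectory is a
fixed atom table (identity, role, molecule membership) plus per-frame
coordinates and orthorhombic box dimensions; atom ordering is identical in
every frame.

Supported on-disk dialects:

* GRO (nm, via MDAnalysis; converted to Angstrom on read)
* multi-model PDB (Angstrom, via MDAnalysis; CRYST1 carries the box)
* XYZ (Angstrom; the box and time are stored on the comment line because the
  bare format has nowhere else to put them)

Energy series are two-column CSV (frame, potential energy in kJ/mol).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Role",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "EnergySeries",
    "DEFAULT_ROLE_MAP",
    "load_role_map",
    "dump_role_map",
    "read_trajectory",
    "write_trajectory",
    "read_energy_csv",
    "write_energy_csv",
]


class Role(str, enum.Enum):
    """Functional role of a bead in the interlayer model."""

    LDH_METAL_MG = "LDH_METAL_MG"
    LDH_METAL_AL = "LDH_METAL_AL"
    LDH_HYDROXYL_O = "LDH_HYDROXYL_O"
    LDH_HYDROXYL_H = "LDH_HYDROXYL_H"
    C_TERM_C = "C_TERM_C"
    C_TERM_O = "C_TERM_O"
    BACKBONE_N = "BACKBONE_N"
    SIDECHAIN_O = "SIDECHAIN_O"
    SIDECHAIN_OTHER = "SIDECHAIN_OTHER"
    WATER_O = "WATER_O"
    WATER_H = "WATER_H"
    COUNTERION = "COUNTERION"


#: atom name -> role, the documented mapping used when reading foreign files.
#: Shipped as data so force-field naming variants can be accommodated by
#: editing a YAML copy (see :func:`dump_role_map`).
DEFAULT_ROLE_MAP: dict[str, str] = {
    "MG": Role.LDH_METAL_MG.value,
    "AL": Role.LDH_METAL_AL.value,
    "OH": Role.LDH_HYDROXYL_O.value,
    "HO": Role.LDH_HYDROXYL_H.value,
    "CT": Role.C_TERM_C.value,
    "OT1": Role.C_TERM_O.value,
    "OT2": Role.C_TERM_O.value,
    "N": Role.BACKBONE_N.value,
    "NT": Role.BACKBONE_N.value,
    "OD1": Role.SIDECHAIN_O.value,
    "OD2": Role.SIDECHAIN_O.value,
    "CB": Role.SIDECHAIN_OTHER.value,
    "OW": Role.WATER_O.value,
    "HW1": Role.WATER_H.value,
    "HW2": Role.WATER_H.value,
    "CL": Role.COUNTERION.value,
    "NA": Role.COUNTERION.value,
}


def load_role_map(path: str | Path) -> dict[str, str]:
    """Load an atom-name -> role mapping table from YAML."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    for name, role in table.items():
        Role(role)  # raises ValueError on unknown role names
    return {str(k): str(v) for k, v in table.items()}


def dump_role_map(path: str | Path, table: dict[str, str] | None = None) -> None:
    """Write the (default) role mapping as editable YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(table or DEFAULT_ROLE_MAP, fh, sort_keys=True)


@dataclass(frozen=True)
class AtomRecord:
    """One bead: identity, role, molecule membership, position (Angstrom)."""

    atom_id: int
    name: str
    role: Role
    molecule_id: int
    residue_type: str
    position: tuple[float, float, float]


@dataclass(frozen=True)
class Frame:
    """A single snapshot: coordinate view into a trajectory.

    ``coords`` is (n_atoms, 3) in Angstrom; ``box`` is (Lx, Ly, Lz) of an
    orthorhombic periodic cell; ``time`` is in ns.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    box: np.ndarray
    time: float

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom table.

    Attributes
    ----------
    atoms:
        DataFrame with columns ``atom_id, name, role, molecule_id,
        residue_type`` — one row per atom, constant across frames.
    coords:
        float array (n_frames, n_atoms, 3), Angstrom.
    box:
        float array (n_frames, 3), Angstrom.
    times:
        float array (n_frames,), ns.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table and coordinate array disagree on n_atoms")
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.atoms, self.coords[i], self.box[i], float(self.times[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def role_index(self, *roles: Role | str) -> np.ndarray:
        """Integer indices of atoms holding any of the given roles."""
        wanted = {Role(r).value for r in roles}
        return np.flatnonzero(self.atoms["role"].isin(wanted).to_numpy())

    def first_frame(self) -> Frame:
        return self.frame(0)


@dataclass
class EnergySeries:
    """Per-frame potential energy (kJ/mol) of a system with ``n_water`` waters."""

    energies: np.ndarray
    n_water: int

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1 or self.energies.size == 0:
            raise ValueError("energy series must be a non-empty 1-D array")
        if self.n_water < 0:
            raise ValueError("n_water must be non-negative")

    def __len__(self) -> int:
        return self.energies.size


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("GRO", "PDB", "XYZ")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
    else:
        fmt = path.suffix.lstrip(".").upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported trajectory format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _roles_from_names(
    names: Sequence[str], role_map: dict[str, str]
) -> list[str]:
    roles = []
    for nm in names:
        key = nm.upper()
        if key not in role_map:
            raise ValueError(
                f"atom name {nm!r} has no entry in the role mapping table; "
                "extend the table (see dump_role_map) to read this file"
            )
        roles.append(role_map[key])
    return roles


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write a trajectory as GRO (nm), multi-model PDB (Angstrom), or XYZ."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "XYZ":
        _write_xyz(traj, path)
        return
    if fmt == "GRO":
        _write_gro(traj, path)
        return
    _write_pdb(traj, path)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    """Multi-model PDB with a CRYST1 record inside every MODEL block.

    Written by hand so each frame carries its own box (per-model CRYST1 is
    what multi-frame readers consult); 1-based serials, Angstrom.
    """
    atoms = traj.atoms
    resids = (atoms["molecule_id"].to_numpy() + 1) % 10000
    with open(path, "w") as fh:
        fh.write("TITLE     clayped synthetic LDH interlayer trajectory\n")
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            bx, by, bz = traj.box[i]
            fh.write(
                f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for a, (name, resname, resid) in enumerate(
                zip(atoms["name"], atoms["residue_type"], resids)
            ):
                x, y, z = traj.coords[i, a]
                serial = (a + 1) % 100000
                nm = f" {name:<3.3s}" if len(name) < 4 else f"{name:<4.4s}"
                fh.write(
                    f"ATOM  {serial:5d} {nm} {resname:<4.4s} {resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    role_map: dict[str, str] | None = None,
) -> Trajectory:
    """Read a GRO / multi-model PDB / XYZ trajectory.

    Atom roles are derived from atom names through ``role_map``
    (:data:`DEFAULT_ROLE_MAP` by default).  GRO coordinates (nm) are converted
    to Angstrom; a PDB without a CRYST1 record is rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    role_map = role_map or DEFAULT_ROLE_MAP
    if fmt == "XYZ":
        return _read_xyz(path, role_map)
    if fmt == "GRO":
        return _read_gro(path, role_map)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    names = [a.name for a in u.atoms]
    roles = _roles_from_names(names, role_map)
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(len(names)),
            "name": names,
            "role": roles,
            "molecule_id": u.atoms.resids - 1,
            "residue_type": [a.resname for a in u.atoms],
        }
    )
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
                raise ValueError(
                    f"{path.name}: frame {ts.frame} carries no periodic box "
                    "(missing CRYST1-equivalent record)"
                )
            coords.append(ts.positions.copy())
            boxes.append(ts.dimensions[:3].copy())
            times.append(ts.time / 1000.0)  # ps -> ns
    return Trajectory(atoms, np.array(coords), np.array(boxes), np.array(times))


def _write_gro(traj: Trajectory, path: Path) -> None:
    """Concatenated-frame GRO (nm, fixed-width records, box on the last line).

    Written by hand: MDAnalysis only supports single-frame GRO, while the
    dialect itself allows stacked frames for trajectories.
    """
    atoms = traj.atoms
    resids = (atoms["molecule_id"].to_numpy() + 1) % 100000
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"clayped t= {traj.times[i] * 1000.0:.4f} ps\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for a, (name, resname, resid) in enumerate(
                zip(atoms["name"], atoms["residue_type"], resids)
            ):
                x, y, z = traj.coords[i, a] / 10.0  # Angstrom -> nm
                serial = (a + 1) % 100000
                fh.write(
                    f"{resid:5d}{resname:<5.5s}{name:>5.5s}{serial:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = traj.box[i] / 10.0
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def _read_gro(path: Path, role_map: dict[str, str]) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, boxes, times = [], [], []
    names: list[str] | None = None
    resids0: list[int] | None = None
    resnames0: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        t = 0.0
        if "t=" in title:
            try:
                t = float(title.split("t=")[1].split()[0]) / 1000.0  # ps -> ns
            except (IndexError, ValueError):
                t = 0.0
        try:
            n = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ValueError(f"{path.name}:{i + 2}: expected atom count") from exc
        fr_names, fr_resids, fr_resnames, xyz = [], [], [], []
        for j in range(n):
            ln = lines[i + 2 + j]
            try:
                fr_resids.append(int(ln[0:5]))
                fr_resnames.append(ln[5:10].strip())
                fr_names.append(ln[10:15].strip())
                xyz.append(
                    [float(ln[20:28]) * 10.0, float(ln[28:36]) * 10.0, float(ln[36:44]) * 10.0]
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{i + 3 + j}: malformed GRO record") from exc
        box_parts = lines[i + 2 + n].split()
        boxes.append([float(v) * 10.0 for v in box_parts[:3]])
        times.append(t)
        if names is None:
            names, resids0, resnames0 = fr_names, fr_resids, fr_resnames
        elif fr_names != names:
            raise ValueError(f"{path.name}: atom ordering changes between frames")
        frames.append(xyz)
        i += 3 + n
    if names is None:
        raise ValueError(f"{path.name}: empty GRO file")
    roles = _roles_from_names(names, role_map)
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(len(names)),
            "name": names,
            "role": roles,
            "molecule_id": np.asarray(resids0) - 1,
            "residue_type": resnames0,
        }
    )
    return Trajectory(atoms, np.array(frames), np.array(boxes), np.array(times))


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            bx, by, bz = traj.box[i]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box {bx:.6f} {by:.6f} {bz:.6f} time {traj.times[i]:.6f}\n")
            for name, (x, y, z) in zip(traj.atoms["name"], traj.coords[i]):
                fh.write(f"{name:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def _read_xyz(path: Path, role_map: dict[str, str]) -> Trajectory:
    frames, boxes, times = [], [], []
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path.name}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1].split()
        if len(comment) < 4 or comment[0] != "box":
            raise ValueError(
                f"{path.name}:{i + 2}: comment line must carry 'box Lx Ly Lz [time t]'"
            )
        boxes.append([float(v) for v in comment[1:4]])
        times.append(float(comment[5]) if len(comment) >= 6 and comment[4] == "time" else 0.0)
        fr_names, xyz = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path.name}:{i + 3 + j}: malformed atom record")
            fr_names.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if names is None:
            names = fr_names
        elif fr_names != names:
            raise ValueError(f"{path.name}: atom ordering changes between frames")
        frames.append(xyz)
        i += 2 + n
    if names is None:
        raise ValueError(f"{path.name}: empty XYZ file")
    roles = _roles_from_names(names, role_map)
    # XYZ has no residue info; each atom becomes its own molecule unless the
    # caller re-attaches a richer atom table afterwards.
    atoms = pd.DataFrame(
        {
            "atom_id": np.arange(len(names)),
            "name": names,
            "role": roles,
            "molecule_id": np.arange(len(names)),
            "residue_type": ["UNK"] * len(names),
        }
    )
    return Trajectory(atoms, np.array(frames), np.array(boxes), np.array(times))


def write_energy_csv(series: EnergySeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(len(series)), "potential_kJ_per_mol": series.energies}
    )
    df.to_csv(path, index=False)


def read_energy_csv(path: str | Path, n_water: int) -> EnergySeries:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (frame, energy)")
    return EnergySeries(df.iloc[:, 1].to_numpy(dtype=float), n_water)


# ---------------------------------------------------------------------------
# shared periodic-geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention displacement(s) for an orthorhombic box."""
    return d - box * np.round(d / box)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis."""
    return np.mod(coords, box)
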