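"""Synthetic LDH-interlayer trajectory generator.

Builds a bead-level model of a hydrated Mg3Al(OH)8 layered-double-hydroxide
slab with intercalated amino acids / peptides and evolves it with controlled,
known statistical structure, so that every analysis stage in this package has
a ground-truth input:

* a stack of flat hexagonal metal layers (1 Al : 3 Mg, Al dispersed on a 2x2
  superlattice), hydroxyl beads decorating both faces of each layer;
* amino-acid/peptide bead molecules carrying the labelled sites the analyses
  consult (C-terminal carbon CT, terminal oxygens OT1/OT2, backbone nitrogens
  with the free amine named NT, aspartate side-chain oxygens OD1/OD2);
* lateral random walks with an optional six-fold directional bias along the
  lattice axes;
* adsorption/desorption as a two-state Markov chain whose stationary adsorbed
  fraction equals ``residence_fraction``;
* sinusoidal layer undulations of configurable amplitude and wavelength;
* a per-frame potential-energy series following a user-supplied monotone
  profile of the water count plus Gaussian noise.

Only the sites the downstream analyses reference are generated — this is a
statistical emulator of interlayer structure and kinetics, not a force-field
simulation.  Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import EnergySeries, Frame, Role, Trajectory

__all__ = [
    "GeneratorConfig",
    "MoleculeSpec",
    "parse_species",
    "build_ldh_slab",
    "populate_interlayer",
    "evolve",
    "generate",
    "HYDRATION_LADDER",
]

#: stepwise-dehydration ladder of waters per amino acid used throughout.
HYDRATION_LADDER = (20, 15, 10, 7, 5, 3, 2, 0)

_KNOWN_RESIDUES = ("ALA", "ASP", "LEU", "LYS", "HIS", "TYR")

# net charge per residue at pH 9.5 (deprotonated per pKa); the C-terminal
# carboxylate contributes one extra negative charge per chain.
_SIDECHAIN_CHARGE = {"ALA": 0, "ASP": -1, "LEU": 0, "LYS": +1, "HIS": 0, "TYR": -1}


@dataclass(frozen=True)
class GeneratorConfig:
    """Geometry, kinetics and randomness knobs of the synthetic system.

    Lengths are Angstrom, times ns.  Defaults mirror the modelled system: a
    5-layer slab of 5.3 Angstrom layer thickness with a ~13 Angstrom repeat,
    hexagonal metal spacing 3.05 Angstrom, full hydration at 20 waters per
    amino acid, and a ~95% post-binding adsorbed fraction.
    """

    n_layers: int = 5
    layer_thickness: float = 5.3
    interlayer_gap: float = 7.7
    lattice_a: float = 3.05
    nx: int = 12
    ny: int = 12
    mg_al_ratio: float = 3.0
    hydration: float = 20.0
    water_per: str = "amino_acid"  # or "anion"
    residence_fraction: float = 0.95
    switch_rate: float = 0.2
    hex_bias: float = 0.0
    step_scale: float = 1.0
    undulation_amplitude: float = 0.0
    undulation_wavelength: float | None = None
    templated: bool = False
    adsorbed_height: float = 1.5
    dt: float = 0.1
    rng_seed: int = 0
    energy_offset: float = -500.0
    energy_per_water: float = -40.0
    energy_noise: float = 5.0

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.layer_thickness <= 0 or self.interlayer_gap <= 0 or self.lattice_a <= 0:
            raise ValueError("geometry lengths must be positive")
        if self.mg_al_ratio != 3.0:
            raise ValueError("only the Mg3Al (3:1) stoichiometry is supported")
        if self.nx % 2 or self.ny % 2:
            raise ValueError("nx and ny must be even for the 2x2 Al superlattice")
        if self.hydration < 0:
            raise ValueError("hydration must be non-negative")
        if not 0.0 <= self.residence_fraction <= 1.0:
            raise ValueError("residence_fraction must lie in [0, 1]")
        if not 0.0 <= self.hex_bias <= 1.0:
            raise ValueError("hex_bias must lie in [0, 1]")
        if self.water_per not in ("amino_acid", "anion"):
            raise ValueError("water_per must be 'amino_acid' or 'anion'")

    @property
    def period(self) -> float:
        """z repeat of the stack (layer thickness + interlayer gap)."""
        return self.layer_thickness + self.interlayer_gap

    @property
    def box(self) -> tuple[float, float, float]:
        return (
            self.nx * self.lattice_a,
            self.ny * self.lattice_a * math.sqrt(3.0) / 2.0,
            self.n_layers * self.period,
        )


@dataclass(frozen=True)
class MoleculeSpec:
    """One molecular species: residue type, chain length, copy count."""

    residue: str
    length: int = 1
    count: int = 1

    def __post_init__(self) -> None:
        if self.residue not in _KNOWN_RESIDUES:
            raise ValueError(f"unknown residue {self.residue!r}; choose from {_KNOWN_RESIDUES}")
        if self.length < 1 or self.count < 1:
            raise ValueError("length and count must be >= 1")

    @property
    def charge(self) -> int:
        return -1 + self.length * _SIDECHAIN_CHARGE[self.residue]


def parse_species(spec: str, count: int = 1) -> MoleculeSpec:
    """Parse shorthand like ``"ALA"``, ``"2ASP"`` or ``"6TYR"``."""
    spec = spec.strip().upper()
    i = 0
    while i < len(spec) and spec[i].isdigit():
        i += 1
    length = int(spec[:i]) if i else 1
    return MoleculeSpec(spec[i:], length, count)


# ---------------------------------------------------------------------------
# slab construction
# ---------------------------------------------------------------------------

def _metal_lattice(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """xy positions of one layer's metal sites and a boolean Al mask.

    Triangular lattice with spacing ``lattice_a``; Al occupies the (even, even)
    sites of a 2x2 superlattice, giving exactly 1 Al per 3 Mg, dispersed so
    that no two Al are nearest neighbours.
    """
    a = cfg.lattice_a
    ii, jj = np.meshgrid(np.arange(cfg.nx), np.arange(cfg.ny), indexing="ij")
    x = (ii + 0.5 * (jj % 2)) * a
    y = jj * a * math.sqrt(3.0) / 2.0
    al = (ii % 2 == 0) & (jj % 2 == 0)
    return np.column_stack([x.ravel(), y.ravel()]), al.ravel()


def build_ldh_slab(config: GeneratorConfig) -> Frame:
    """Construct the static LDH slab (metals + hydroxyls), flat layers.

    Metal planes sit at z = (k + 1/2) * period; hydroxyl O/H beads decorate
    both faces so that the hydroxyl z-extent of a layer equals
    ``layer_thickness``.
    """
    config.validate()
    xy, al_mask = _metal_lattice(config)
    n_site = len(xy)
    rows: list[tuple] = []
    coords: list[tuple[float, float, float]] = []
    d_oh = 0.95  # O-H bond length along z
    half = config.layer_thickness / 2.0
    atom_id = 0
    for k in range(config.n_layers):
        zc = (k + 0.5) * config.period
        for s in range(n_site):
            x, y = xy[s]
            is_al = bool(al_mask[s])
            name = "AL" if is_al else "MG"
            role = Role.LDH_METAL_AL if is_al else Role.LDH_METAL_MG
            rows.append((atom_id, name, role.value, 0, "LDH"))
            coords.append((x, y, zc))
            atom_id += 1
            for sign in (+1, -1):
                rows.append((atom_id, "OH", Role.LDH_HYDROXYL_O.value, 0, "LDH"))
                coords.append((x, y, zc + sign * (half - d_oh)))
                atom_id += 1
                rows.append((atom_id, "HO", Role.LDH_HYDROXYL_H.value, 0, "LDH"))
                coords.append((x, y, zc + sign * half))
                atom_id += 1
    atoms = pd.DataFrame(rows, columns=["atom_id", "name", "role", "molecule_id", "residue_type"])
    return Frame(atoms, np.array(coords, dtype=float), np.array(config.box), 0.0)


# ---------------------------------------------------------------------------
# interlayer population
# ---------------------------------------------------------------------------

def _molecule_template(spec: MoleculeSpec) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Bead names/roles and local coordinates for one molecule.

    Residue 0 is the C-terminal residue (CT + OT1/OT2 + backbone N); the chain
    extends along local +y in 3.5 Angstrom steps; the free amine of the
    N-terminal residue is named NT.
    """
    beads: list[tuple[str, str]] = []
    xyz: list[tuple[float, float, float]] = []
    for r in range(spec.length):
        oy = r * 3.5
        oz = 0.0 if r == 0 else 1.0
        if r == 0:
            beads += [
                ("CT", Role.C_TERM_C.value),
                ("OT1", Role.C_TERM_O.value),
                ("OT2", Role.C_TERM_O.value),
            ]
            xyz += [(0.0, 0.0, 0.0), (0.3, 0.0, -0.45), (-0.3, 0.0, -0.45)]
        n_name = "NT" if r == spec.length - 1 else "N"
        beads.append((n_name, Role.BACKBONE_N.value))
        xyz.append((0.0, oy + 1.2, oz + 0.9))
        if spec.residue == "ASP":
            beads += [("OD1", Role.SIDECHAIN_O.value), ("OD2", Role.SIDECHAIN_O.value)]
            xyz += [(1.1, oy - 0.4, oz + 0.6), (1.9, oy + 0.4, oz + 0.6)]
        else:
            beads.append(("CB", Role.SIDECHAIN_OTHER.value))
            xyz.append((1.2, oy - 0.4, oz + 1.0))
    return beads, np.asarray(xyz, dtype=float)


def populate_interlayer(
    slab: Frame,
    species: Sequence[MoleculeSpec | str],
    hydration: float | None = None,
    rng_seed: int | None = None,
    config: GeneratorConfig | None = None,
) -> Frame:
    """Add amino-acid/peptide molecules, waters and counterions to a slab.

    Molecules are distributed round-robin over the interlayer gaps on a jittered
    grid (6 Angstrom pitch); waters are single OW beads, ``hydration`` per
    amino-acid residue (or per anion when ``config.water_per == "anion"``);
    Cl- counterions top up the charge balance against the +1/unit-cell slab.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    if hydration is None:
        hydration = cfg.hydration
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    specs = [parse_species(s) if isinstance(s, str) else s for s in species]
    box = np.asarray(slab.box, dtype=float)

    n_molecules = sum(s.count for s in specs)
    n_residues = sum(s.count * s.length for s in specs)
    neg_charge = -sum(min(s.charge, 0) * s.count for s in specs)
    n_al = int((slab.atoms["role"] == Role.LDH_METAL_AL.value).sum())
    n_counter = max(0, n_al - neg_charge)
    if cfg.water_per == "anion":
        n_water = int(round(hydration * (n_molecules + n_counter)))
    else:
        n_water = int(round(hydration * n_residues))

    # placement grid inside each gap
    pitch = 6.0
    gx = int(box[0] // pitch)
    gy = int(box[1] // pitch)
    n_gaps = cfg.n_layers
    capacity = gx * gy * n_gaps
    if n_molecules > capacity:
        raise ValueError(
            f"interlayer volume insufficient: {n_molecules} molecules requested, "
            f"placement capacity {capacity}"
        )
    sites = [(g, i, j) for g in range(n_gaps) for i in range(gx) for j in range(gy)]
    order = rng.permutation(len(sites))

    rows = list(slab.atoms.itertuples(index=False, name=None))
    coords = [tuple(c) for c in slab.coords]
    atom_id = len(rows)
    mol_id = int(slab.atoms["molecule_id"].max()) + 1

    def gap_mid_z(g: int) -> float:
        # gap g lies between metal plane g and g+1 (periodic in z)
        return (g + 0.5) * cfg.period + cfg.period / 2.0

    si = 0
    for spec in specs:
        beads, local = _molecule_template(spec)
        resname = spec.residue if spec.length == 1 else f"{spec.length}{spec.residue}"
        for _ in range(spec.count):
            g, i, j = sites[order[si]]
            si += 1
            x0 = (i + 0.5) * pitch + rng.uniform(-1.0, 1.0)
            y0 = (j + 0.5) * pitch + rng.uniform(-1.0, 1.0)
            z0 = gap_mid_z(g) % box[2]
            psi = rng.uniform(0.0, 2.0 * math.pi)
            c, s_ = math.cos(psi), math.sin(psi)
            rot = np.array([[c, -s_, 0.0], [s_, c, 0.0], [0.0, 0.0, 1.0]])
            pos = local @ rot.T + np.array([x0, y0, z0])
            pos[:, :2] %= box[:2]
            for (name, role), p in zip(beads, pos):
                rows.append((atom_id, name, role, mol_id, resname))
                coords.append((p[0], p[1], p[2]))
                atom_id += 1
            mol_id += 1

    # waters and counterions: random xy, z well inside a random gap
    for kind, count in (("water", n_water), ("ion", n_counter)):
        for _ in range(count):
            g = int(rng.integers(n_gaps))
            x = rng.uniform(0.0, box[0])
            y = rng.uniform(0.0, box[1])
            z = (gap_mid_z(g) + rng.uniform(-1.0, 1.0)) % box[2]
            if kind == "water":
                rows.append((atom_id, "OW", Role.WATER_O.value, mol_id, "SOL"))
            else:
                rows.append((atom_id, "CL", Role.COUNTERION.value, mol_id, "ION"))
            coords.append((x, y, z))
            atom_id += 1
            mol_id += 1

    atoms = pd.DataFrame(rows, columns=["atom_id", "name", "role", "molecule_id", "residue_type"])
    return Frame(atoms, np.array(coords, dtype=float), box, 0.0)


# ---------------------------------------------------------------------------
# time evolution
# ---------------------------------------------------------------------------

def _hex_directions(n: int, bias: float, rng: np.random.Generator) -> np.ndarray:
    """Step directions in radians: lattice-axis multiples of 60 deg with
    probability ``bias``, uniform otherwise."""
    pick = rng.random(n) < bias
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)
    lattice = rng.integers(0, 6, size=n) * (math.pi / 3.0)
    return np.where(pick, lattice, angles)


def evolve(
    frame0: Frame,
    n_frames: int,
    config: GeneratorConfig,
    energy_profile: Callable[[float], float] | None = None,
) -> tuple[Trajectory, EnergySeries]:
    """Evolve a populated frame into a trajectory plus an energy series.

    Molecules translate rigidly in the xy-plane by Rayleigh-length steps whose
    directions carry the configured six-fold bias; a two-state Markov chain
    with stationary adsorbed fraction ``residence_fraction`` toggles each
    molecule between a surface-bound pose (terminal oxygens within H-bonding
    range of the lower hydroxyl face of its gap) and a mid-gap pose; LDH layer
    z-coordinates carry a static sinusoidal undulation; the energy series is
    ``energy_profile(n_water)`` (linear in the water count by default) plus
    Gaussian noise per frame.
    """
    config.validate()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    atoms = frame0.atoms
    box = np.asarray(frame0.box, dtype=float)
    base = np.array(frame0.coords, dtype=float)
    n_atoms = base.shape[0]

    roles = atoms["role"].to_numpy()
    ldh_mask = np.isin(
        roles,
        [
            Role.LDH_METAL_MG.value,
            Role.LDH_METAL_AL.value,
            Role.LDH_HYDROXYL_O.value,
            Role.LDH_HYDROXYL_H.value,
        ],
    )
    water_mask = roles == Role.WATER_O.value
    ion_mask = roles == Role.COUNTERION.value
    al_mask = roles == Role.LDH_METAL_AL.value

    # molecule bookkeeping: any molecule_id owning a C-terminal carbon
    ct_rows = np.flatnonzero(roles == Role.C_TERM_C.value)
    mol_ids = atoms.loc[ct_rows, "molecule_id"].to_numpy()
    mol_atoms = [
        np.flatnonzero(atoms["molecule_id"].to_numpy() == m) for m in mol_ids
    ]
    mol_ot = [
        idx[np.isin(atoms["role"].to_numpy()[idx], [Role.C_TERM_O.value])]
        for idx in mol_atoms
    ]
    n_mol = len(mol_ids)

    # which gap each molecule lives in (from its CT z)
    ct_z = base[ct_rows, 2]
    gap_of = ((ct_z - config.period / 2.0) // config.period).astype(int) % config.n_layers

    # undulation: static phase per layer, wavelength along x
    amp = config.undulation_amplitude
    wavelength = config.undulation_wavelength or box[0]
    layer_phase = rng.uniform(0.0, 2.0 * math.pi, size=config.n_layers)
    ldh_layer = (base[:, 2] // config.period).astype(int) % config.n_layers

    def surface_dz(x: np.ndarray, layer: np.ndarray | int) -> np.ndarray:
        if amp == 0.0:
            return np.zeros_like(np.asarray(x, dtype=float))
        phase = layer_phase[layer]
        return amp * np.sin(2.0 * math.pi * np.asarray(x) / wavelength + phase)

    # Markov chain: stationary adsorbed fraction p with switching scale w
    p = config.residence_fraction
    w = config.switch_rate
    p_on = min(1.0, w * p)
    p_off = min(1.0, w * (1.0 - p))
    adsorbed = np.zeros(n_mol, dtype=bool)  # everyone starts desorbed

    # lateral anchors (CT xy) and rigid molecule offsets from the anchor
    anchor = base[ct_rows, :2].copy()
    offsets = [base[idx] - base[ct]  for idx, ct in zip(mol_atoms, ct_rows)]

    al_xy = base[al_mask][:, :2]
    al_layer = ldh_layer[al_mask]

    coords_out = np.empty((n_frames, n_atoms, 3), dtype=float)
    times = np.arange(n_frames) * config.dt
    energies = np.empty(n_frames, dtype=float)
    n_water = int(water_mask.sum())
    if energy_profile is None:
        energy_profile = lambda n: config.energy_offset + config.energy_per_water * n

    # hydroxyl-H plane offsets used to pose adsorbed/desorbed molecules
    half = config.layer_thickness / 2.0
    d_surf = config.adsorbed_height

    for t in range(n_frames):
        frame = base.copy()
        # LDH undulation
        if amp != 0.0:
            frame[ldh_mask, 2] += surface_dz(frame[ldh_mask, 0], ldh_layer[ldh_mask])
        # adsorption state update (skip on frame 0 so states are inspectable)
        if t > 0:
            r = rng.random(n_mol)
            flip_on = ~adsorbed & (r < p_on)
            flip_off = adsorbed & (r < p_off)
            adsorbed = (adsorbed | flip_on) & ~flip_off
            # lateral step
            theta = _hex_directions(n_mol, config.hex_bias, rng)
            step = rng.rayleigh(config.step_scale, size=n_mol)
            anchor[:, 0] += step * np.cos(theta)
            anchor[:, 1] += step * np.sin(theta)
            anchor %= box[:2]
        xy = anchor.copy()
        if config.templated:
            # adsorbed C-termini seat on the nearest Al site (periodic xy)
            for m in np.flatnonzero(adsorbed):
                cand = al_xy[al_layer == gap_of[m]]
                if len(cand) == 0:
                    cand = al_xy
                d = cand - xy[m]
                d -= box[:2] * np.round(d / box[:2])
                xy[m] = cand[np.argmin(np.einsum("ij,ij->i", d, d))]
        # pose molecules
        for m in range(n_mol):
            g = gap_of[m]
            surf_z = (g + 0.5) * config.period + half  # lower hydroxyl-H face
            surf_z += float(surface_dz(np.array([xy[m, 0]]), g)[0])
            if adsorbed[m]:
                # OT beads sit d_surf above the face; OT local z is -0.45
                ct_zt = surf_z + d_surf + 0.45
            else:
                ct_zt = surf_z + config.interlayer_gap / 2.0
            pos = offsets[m] + np.array([xy[m, 0], xy[m, 1], ct_zt])
            pos[:, :2] %= box[:2]
            pos[:, 2] %= box[2]
            frame[mol_atoms[m]] = pos
        # waters and ions jitter laterally
        for mask in (water_mask, ion_mask):
            k = int(mask.sum())
            if k and t > 0:
                frame[mask, :2] = (
                    base[mask, :2] + rng.normal(0.0, 1.0, size=(k, 2))
                ) % box[:2]
            elif k:
                frame[mask, :2] = base[mask, :2]
        base[water_mask | ion_mask] = frame[water_mask | ion_mask]
        coords_out[t] = frame
        energies[t] = energy_profile(n_water) + rng.normal(0.0, config.energy_noise)

    boxes = np.tile(box, (n_frames, 1))
    traj = Trajectory(atoms.copy(), coords_out, boxes, times)
    return traj, EnergySeries(energies, n_water)


def generate(
    config: GeneratorConfig,
    species: Sequence[MoleculeSpec | str],
    n_frames: int = 100,
    energy_profile: Callable[[float], float] | None = None,
) -> tuple[Trajectory, EnergySeries]:
    """Convenience chain: build slab -> populate interlayer -> evolve."""
    slab = build_ldh_slab(config)
    frame0 = populate_interlayer(slab, species, config.hydration, config.rng_seed, config)
    return evolve(frame0, n_frames, config, energy_profile)
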