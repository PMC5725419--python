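"""Adsorption statistics, RDF templating signals, backbone orientation, and
reactive-pair counts.

An amino acid / peptide counts as adsorbed when either of its C-terminal
oxygens (OT1/OT2) lies within a cutoff (default 2.5 Angstrom, the first
hydration layer of the LDH surface) of a surface hydroxyl atom; aspartate
side-chain carboxylates (OD1/OD2) are scored separately.  The radial
distribution function of C-terminal oxygens against LDH aluminium probes the
lattice-templating of adsorption sites.  Backbone orientation is the
elevation of the C->N vector of the terminal residue (0 deg = perpendicular
to the layer plane, 90 deg = parallel).  A reactive pair is a geometric proxy
for a bond-forming arrangement: the C-terminus of one adsorbed molecule
within 4 Angstrom of the free amine of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Role, Trajectory, minimum_image, wrap

__all__ = [
    "Molecule",
    "molecule_table",
    "AdsorptionSeries",
    "RDFResult",
    "OrientationHistogram",
    "ReactivePairCount",
    "adsorption_fraction",
    "rdf",
    "orientation_histogram",
    "reactive_pairs",
]

_SURFACE_ROLE_SETS = {
    "hydroxyl": (Role.LDH_HYDROXYL_O.value, Role.LDH_HYDROXYL_H.value),
    "hydroxyl_o": (Role.LDH_HYDROXYL_O.value,),
    "hydroxyl_h": (Role.LDH_HYDROXYL_H.value,),
    "metal": (Role.LDH_METAL_MG.value, Role.LDH_METAL_AL.value),
}


@dataclass(frozen=True)
class Molecule:
    """Site indices of one amino-acid/peptide molecule (rows of the atom table)."""

    molecule_id: int
    residue_type: str
    ct: int
    ot: np.ndarray
    backbone_n: np.ndarray
    nt: int
    sidechain_o: np.ndarray
    n_residues: int


def molecule_table(traj: Trajectory) -> list[Molecule]:
    """Derive per-molecule site bookkeeping from the atom table.

    Molecules are the molecule_ids owning a C-terminal carbon; molecules
    lacking terminal oxygens are skipped with a warning.  The residue count of
    a chain equals its number of backbone nitrogens.
    """
    atoms = traj.atoms
    mols: list[Molecule] = []
    for mid, grp in atoms.groupby("molecule_id", sort=True):
        roles = grp["role"].to_numpy()
        ct_rows = grp.index.to_numpy()[roles == Role.C_TERM_C.value]
        if len(ct_rows) == 0:
            continue
        ot_rows = grp.index.to_numpy()[roles == Role.C_TERM_O.value]
        if len(ot_rows) == 0:
            warnings.warn(f"molecule {mid} has a C-terminal C but no OT oxygens; skipped")
            continue
        n_rows = grp.index.to_numpy()[roles == Role.BACKBONE_N.value]
        nt_rows = grp.index.to_numpy()[grp["name"].to_numpy() == "NT"]
        nt = int(nt_rows[0]) if len(nt_rows) else int(n_rows[0])
        od_rows = grp.index.to_numpy()[roles == Role.SIDECHAIN_O.value]
        mols.append(
            Molecule(
                int(mid),
                str(grp["residue_type"].iloc[0]),
                int(ct_rows[0]),
                ot_rows,
                n_rows,
                nt,
                od_rows,
                max(1, len(n_rows)),
            )
        )
    return mols


@dataclass
class AdsorptionSeries:
    """Per-frame, per-molecule adsorption state.

    ``backbone[f, m]`` — C-terminal oxygens within ``cutoff`` of the surface;
    ``sidechain[f, m]`` — any side-chain oxygen within cutoff (always False
    for molecules without side-chain oxygens).
    """

    backbone: np.ndarray
    sidechain: np.ndarray
    cutoff: float
    molecules: list[Molecule]

    @property
    def any_site(self) -> np.ndarray:
        return self.backbone | self.sidechain

    def summary(self, equil_fraction: float = 0.5) -> dict[str, float]:
        """Percent adsorbed over the equilibrated (last ``equil_fraction``)
        portion of the trajectory; peptide side-chain percentages are scaled
        down by residues-per-terminus."""
        f0 = int(round(self.backbone.shape[0] * (1.0 - equil_fraction)))
        bb = self.backbone[f0:]
        sc = self.sidechain[f0:]
        scale = np.array([m.n_residues for m in self.molecules], dtype=float)
        raw_sc = 100.0 * sc.mean(axis=0)
        return {
            "percent_backbone": float(100.0 * bb.mean()),
            "percent_sidechain_raw": float(raw_sc.mean()),
            "percent_sidechain_scaled": float((raw_sc / scale).mean()),
        }


def adsorption_fraction(
    traj: Trajectory,
    cutoff: float = 2.5,
    surface: str = "hydroxyl",
) -> AdsorptionSeries:
    """Score every molecule's adsorption state in every frame.

    Distances are periodic minimum-image from each site oxygen to the nearest
    LDH surface atom (surface definition switchable between the hydroxyl
    O+H set, its O or H subsets, and the metal planes).  A molecule is
    backbone-adsorbed if *either* OT1 or OT2 is within the cutoff.
    """
    if surface not in _SURFACE_ROLE_SETS:
        raise ValueError(f"unknown surface definition {surface!r}")
    surf_rows = traj.role_index(*_SURFACE_ROLE_SETS[surface])
    if len(surf_rows) == 0:
        raise ValueError("trajectory contains no LDH surface atoms")
    mols = molecule_table(traj)
    if not mols:
        raise ValueError("trajectory contains no molecules with C-terminal sites")
    nf = traj.n_frames
    backbone = np.zeros((nf, len(mols)), dtype=bool)
    sidechain = np.zeros((nf, len(mols)), dtype=bool)
    ot_rows = np.concatenate([m.ot for m in mols])
    ot_owner = np.concatenate([[i] * len(m.ot) for i, m in enumerate(mols)])
    od_rows = (
        np.concatenate([m.sidechain_o for m in mols if len(m.sidechain_o)])
        if any(len(m.sidechain_o) for m in mols)
        else np.empty(0, dtype=int)
    )
    od_owner = (
        np.concatenate(
            [[i] * len(m.sidechain_o) for i, m in enumerate(mols) if len(m.sidechain_o)]
        )
        if len(od_rows)
        else np.empty(0, dtype=int)
    )
    for f in range(nf):
        box = traj.box[f]
        tree = cKDTree(wrap(traj.coords[f][surf_rows], box), boxsize=box)
        d_ot, _ = tree.query(wrap(traj.coords[f][ot_rows], box))
        hit = d_ot <= cutoff
        np.logical_or.at(backbone[f], ot_owner[hit], True)
        if len(od_rows):
            d_od, _ = tree.query(wrap(traj.coords[f][od_rows], box))
            np.logical_or.at(sidechain[f], od_owner[d_od <= cutoff], True)
    return AdsorptionSeries(backbone, sidechain, cutoff, mols)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    """Pair distribution g(r) with bin centres in Angstrom."""

    r: np.ndarray
    g: np.ndarray
    pair: tuple[str, str]
    bin_width: float
    lateral: bool = False

    def first_peak(self, r_min: float = 0.0, min_height: float = 1.0) -> float:
        """Position of the first local maximum of g(r) at r >= r_min.

        A peak must exceed ``min_height`` (ideal-gas level by default); falls
        back to the global maximum if no local peak qualifies.
        """
        from scipy.signal import find_peaks

        mask = self.r >= r_min
        g, r = self.g[mask], self.r[mask]
        peaks, _ = find_peaks(g, height=min_height)
        if len(peaks):
            return float(r[peaks[0]])
        return float(r[np.argmax(g)])


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray, lateral: bool) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, box)
    if lateral:
        d = d[..., :2]
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def rdf(
    traj: Trajectory,
    pair: tuple[Role | str, Role | str],
    r_max: float,
    bin_width: float = 0.1,
    lateral: bool = False,
) -> RDFResult:
    """Radial distribution function of role_B atoms around role_A atoms.

    Standard ideal-gas normalization under periodic minimum image: shell
    volumes 4/3*pi*(r2^3-r1^3) against the mean density of B (3-D), or ring
    areas pi*(r2^2-r1^2) against the areal density of B (``lateral=True``,
    xy-projected distances — used for probing in-plane lattice templating).
    Self-pairs are excluded when A and B are the same role.
    """
    role_a, role_b = Role(pair[0]), Role(pair[1])
    rows_a = traj.role_index(role_a)
    rows_b = traj.role_index(role_b)
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError(f"roles {role_a.value}/{role_b.value} not both present")
    if r_max >= traj.box.min() / 2.0:
        raise ValueError("r_max must be below half the smallest box edge")
    same = role_a == role_b
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    vol_acc = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f]
        d = _pair_distances(traj.coords[f][rows_a], traj.coords[f][rows_b], box, lateral)
        if same:
            np.fill_diagonal(d, np.inf)
        hist += np.histogram(d.ravel(), bins=edges)[0]
        vol_acc += box[0] * box[1] if lateral else box.prod()
    n_a, n_b = len(rows_a), len(rows_b)
    mean_vol = vol_acc / traj.n_frames
    rho_b = (n_b - (1 if same else 0)) / mean_vol
    if lateral:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    else:
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (traj.n_frames * n_a * shell * rho_b)
    r = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r, g, (role_a.value, role_b.value), bin_width, lateral)


# ---------------------------------------------------------------------------
# backbone orientation
# ---------------------------------------------------------------------------

@dataclass
class OrientationHistogram:
    """Elevation of the terminal C->N vector, folded to [0, 90] deg, 1-deg bins."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_observations: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])


def orientation_histogram(
    traj: Trajectory,
    adsorbed_only: bool = False,
    adsorption: AdsorptionSeries | None = None,
) -> OrientationHistogram:
    """Histogram of backbone elevations Theta over molecules and frames.

    Theta is the angle of the C-terminal-carbon -> backbone-nitrogen vector
    (the nitrogen of the terminal residue, identified as the backbone N
    closest to the C-terminal carbon) against the z-axis, folded so that
    0 deg means perpendicular to the layer plane and 90 deg parallel.
    """
    if adsorbed_only and adsorption is None:
        raise ValueError("adsorbed_only requires an AdsorptionSeries")
    mols = molecule_table(traj)
    edges = np.arange(0.0, 91.0)
    counts = np.zeros(90, dtype=int)
    n_obs = 0
    for f in range(traj.n_frames):
        box = traj.box[f]
        for i, m in enumerate(mols):
            if adsorbed_only and not adsorption.backbone[f, i]:
                continue
            ct = traj.coords[f][m.ct]
            nvecs = minimum_image(traj.coords[f][m.backbone_n] - ct, box)
            v = nvecs[np.argmin(np.einsum("ij,ij->i", nvecs, nvecs))]
            norm = np.linalg.norm(v)
            if norm == 0.0:
                warnings.warn(f"zero-length C->N vector for molecule {m.molecule_id}; skipped")
                continue
            theta = np.degrees(np.arccos(np.clip(abs(v[2]) / norm, 0.0, 1.0)))
            counts[min(int(theta), 89)] += 1
            n_obs += 1
    return OrientationHistogram(edges, counts, n_obs)


# ---------------------------------------------------------------------------
# reactive pairs
# ---------------------------------------------------------------------------

@dataclass
class ReactivePairCount:
    """Per-frame counts of C/N-termini contacts (< cutoff) between adsorbed molecules."""

    counts: np.ndarray
    percent_participating: np.ndarray
    cutoff: float

    @property
    def mean_percent(self) -> float:
        return float(self.percent_participating.mean())


def reactive_pairs(
    traj: Trajectory,
    adsorption: AdsorptionSeries,
    cutoff: float = 4.0,
) -> ReactivePairCount:
    """Count bond-forming arrangements: C-terminus of molecule i within
    ``cutoff`` of the free amine of molecule j (i != j), both adsorbed.

    The carboxylate donor must be adsorbed through the matching site (backbone
    C-terminus for alpha pairs, aspartate side-chain for beta pairs, counted
    through the OD1/OD2 midpoint); the amine bearer must be adsorbed through
    any site.  Intramolecular closures (cyclic geometries) are excluded.
    Alpha and beta contributions are summed.  The participation percentage is
    the fraction of molecules appearing in at least one pair.
    """
    if adsorption is None:
        raise ValueError("reactive_pairs requires an AdsorptionSeries")
    mols = adsorption.molecules
    nf = traj.n_frames
    counts = np.zeros(nf, dtype=int)
    percent = np.zeros(nf)
    n_mol = len(mols)
    for f in range(nf):
        box = traj.box[f]
        coords = traj.coords[f]
        donors: list[tuple[int, np.ndarray]] = []
        for i, m in enumerate(mols):
            if adsorption.backbone[f, i]:
                donors.append((i, coords[m.ct]))
            if len(m.sidechain_o) and adsorption.sidechain[f, i]:
                for k in range(0, len(m.sidechain_o) - 1, 2):
                    mid = coords[m.sidechain_o[k : k + 2]].mean(axis=0)
                    donors.append((i, mid))
        acceptors = [
            (j, coords[m.nt])
            for j, m in enumerate(mols)
            if adsorption.backbone[f, j] or adsorption.sidechain[f, j]
        ]
        involved: set[int] = set()
        c = 0
        if donors and acceptors:
            dpos = np.array([p for _, p in donors])
            apos = np.array([p for _, p in acceptors])
            dist = _pair_distances(dpos, apos, box, lateral=False)
            for di, (i, _) in enumerate(donors):
                for aj, (j, _) in enumerate(acceptors):
                    if i != j and dist[di, aj] < cutoff:
                        c += 1
                        involved.update((i, j))
        counts[f] = c
        percent[f] = 100.0 * len(involved) / n_mol if n_mol else 0.0
    return ReactivePairCount(counts, percent, cutoff)
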