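"""Adsorption scoring, RDF, orientation, and reactive pairs against
brute-force oracles and closed-form fixtures."""

import numpy as np
import pytest

from clayped import (
    GeneratorConfig,
    Role,
    adsorption_fraction,
    generate,
    orientation_histogram,
    rdf,
    reactive_pairs,
)
from clayped.io import Trajectory, minimum_image
from conftest import build_frame, flat_surface, frame_to_traj, monomer


def surface_and_monomers(z_list, box=(24.0, 24.0, 30.0), residue="ALA"):
    """A flat hydroxyl face at z=0 plus monomers whose OT oxygens sit at the
    given heights directly above surface atoms."""
    recs = list(flat_surface(0.0))
    for i, z in enumerate(z_list):
        recs += monomer(i + 1, 3.0 * (i % 8), 3.0 * (i // 8), z + 0.45, residue)
    return build_frame(recs, box)


class TestAdsorptionFraction:
    @pytest.mark.parametrize("height, expect", [(2.4, True), (2.6, False)])
    def test_cutoff_boundary(self, height, expect):
        frame = surface_and_monomers([height])
        traj = frame_to_traj(frame)
        ads = adsorption_fraction(traj, cutoff=2.5)
        assert bool(ads.backbone[0, 0]) is expect

    def test_seventy_percent_fixture_vs_bruteforce(self):
        """7 of 10 molecules within cutoff -> 70%, cross-checked by an
        all-pairs distance loop."""
        heights = [2.0] * 7 + [4.0] * 3
        frame = surface_and_monomers(heights)
        traj = frame_to_traj(frame)
        ads = adsorption_fraction(traj, cutoff=2.5)
        assert ads.backbone[0].mean() == pytest.approx(0.7)
        # oracle: direct minimum-image distances, no KD-tree
        surf = traj.coords[0][traj.role_index(Role.LDH_HYDROXYL_O, Role.LDH_HYDROXYL_H)]
        for i, m in enumerate(ads.molecules):
            ot = traj.coords[0][m.ot]
            d = minimum_image(ot[:, None, :] - surf[None, :, :], traj.box[0])
            dmin = np.sqrt((d**2).sum(-1)).min()
            assert (dmin <= 2.5) == ads.backbone[0, i]

    def test_either_of_ot_pair_suffices(self):
        recs = list(flat_surface(0.0)) + [
            ("CT", Role.C_TERM_C, 1, "ALA", (0.0, 0.0, 6.0)),
            ("OT1", Role.C_TERM_O, 1, "ALA", (0.0, 0.0, 2.0)),  # within cutoff
            ("OT2", Role.C_TERM_O, 1, "ALA", (0.0, 0.0, 7.0)),  # far
            ("NT", Role.BACKBONE_N, 1, "ALA", (0.0, 1.2, 6.9)),
        ]
        traj = frame_to_traj(build_frame(recs, (24.0, 24.0, 30.0)))
        assert adsorption_fraction(traj).backbone[0, 0]

    def test_aspartate_sidechain_reported_separately(self):
        frame = surface_and_monomers([2.0], residue="ASP")
        traj = frame_to_traj(frame)
        ads = adsorption_fraction(traj)
        assert ads.backbone[0, 0]
        # OD pair sits ~3 A above the face in this fixture -> not adsorbed
        assert not ads.sidechain[0, 0]

    def test_hexapeptide_sidechain_scaling(self, small_traj):
        traj, _ = small_traj
        ads = adsorption_fraction(traj)
        s = ads.summary()
        # scaled percentage averages raw/residues_per_chain over molecules
        lengths = np.array([m.n_residues for m in ads.molecules], dtype=float)
        f0 = traj.n_frames - traj.n_frames // 2
        raw = 100.0 * ads.sidechain[f0:].mean(axis=0)
        assert s["percent_sidechain_scaled"] == pytest.approx((raw / lengths).mean())
        assert (lengths == 6).sum() > 0  # fixture includes hexapeptides

    def test_monotone_in_cutoff(self, small_traj):
        traj, _ = small_traj
        a_small = adsorption_fraction(traj, cutoff=2.0)
        a_large = adsorption_fraction(traj, cutoff=3.0)
        assert np.all(a_large.backbone >= a_small.backbone)

    def test_no_surface_atoms_error(self):
        traj = frame_to_traj(build_frame(monomer(1, 0, 0, 5), (10, 10, 10)))
        with pytest.raises(ValueError, match="surface"):
            adsorption_fraction(traj)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(1)
        box = (30.0, 30.0, 30.0)
        recs = [("OW", Role.WATER_O, i, "SOL", tuple(rng.uniform(0, 30, 3))) for i in range(400)]
        recs += [("CL", Role.COUNTERION, 400 + i, "ION", tuple(rng.uniform(0, 30, 3))) for i in range(400)]
        traj = frame_to_traj(*[build_frame(recs, box)])
        res = rdf(traj, (Role.WATER_O, Role.COUNTERION), r_max=12.0, bin_width=0.5)
        assert np.allclose(res.g[res.r > 2.0], 1.0, atol=0.35)
        assert np.abs(res.g[res.r > 2.0].mean() - 1.0) < 0.05

    def test_ten_atom_fixture_equals_bruteforce(self):
        """Histogram equals an O(n^2) shell count under the same normalization."""
        rng = np.random.default_rng(5)
        box = np.array([20.0, 20.0, 20.0])
        pos = rng.uniform(0, 20, size=(10, 3))
        recs = [("AL", Role.LDH_METAL_AL, 0, "LDH", tuple(p)) for p in pos]
        traj = frame_to_traj(build_frame(recs, box))
        bw = 0.25
        r_max = 9.0
        res = rdf(traj, (Role.LDH_METAL_AL, Role.LDH_METAL_AL), r_max=r_max, bin_width=bw)
        edges = np.arange(0.0, r_max + bw, bw)
        counts = np.zeros(len(edges) - 1)
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if r < edges[-1]:
                    k = int(r // bw)
                    if k < len(counts):
                        counts[k] += 1
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = 9.0 / box.prod()
        expected = counts / (10 * shell * rho)
        assert np.allclose(res.g, expected, rtol=0, atol=1e-12)

    def test_pair_count_conservation(self):
        """Integrating g(r)*rho over the probed shells recovers the exact
        number of B neighbours within r_max per A atom."""
        rng = np.random.default_rng(2)
        box = np.array([20.0, 20.0, 20.0])
        pos = rng.uniform(0, 20, size=(30, 3))
        recs = [("AL", Role.LDH_METAL_AL, 0, "LDH", tuple(p)) for p in pos]
        traj = frame_to_traj(build_frame(recs, box))
        r_max = 8.0
        res = rdf(traj, (Role.LDH_METAL_AL, Role.LDH_METAL_AL), r_max=r_max, bin_width=0.2)
        edges = np.arange(0.0, r_max + 0.2, 0.2)
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho = 29.0 / box.prod()
        recovered = (res.g * shell * rho).sum() * 30
        d = pos[:, None] - pos[None, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        exact = (r < edges[-1]).sum()
        assert recovered == pytest.approx(exact)

    def test_templated_ot_peaks_match_aluminium_lattice(self):
        """C-termini seated on Al sites make the OT-Al in-plane RDF peak at
        the Al-Al lattice spacing."""
        cfg = GeneratorConfig(
            nx=12, ny=12, n_layers=2, rng_seed=5, hydration=0, templated=True,
            residence_fraction=1.0, switch_rate=1.0,
        )
        traj, _ = generate(cfg, ["ALA"] * 16, n_frames=15)
        g_ct = rdf(traj, (Role.C_TERM_C, Role.LDH_METAL_AL), r_max=10.0, lateral=True)
        g_ot = rdf(traj, (Role.C_TERM_O, Role.LDH_METAL_AL), r_max=10.0, lateral=True)
        g_al = rdf(traj, (Role.LDH_METAL_AL, Role.LDH_METAL_AL), r_max=10.0, lateral=True)
        ref = g_al.first_peak(1.5)
        assert g_ct.first_peak(1.5) == pytest.approx(ref, abs=g_al.bin_width)
        assert g_ot.first_peak(1.5) == pytest.approx(ref, abs=0.35)  # OT offset smear

    def test_r_max_validation(self, small_traj):
        traj, _ = small_traj
        with pytest.raises(ValueError, match="half"):
            rdf(traj, (Role.C_TERM_O, Role.LDH_METAL_AL), r_max=traj.box.min())


class TestOrientation:
    def orient_frame(self, n_vec):
        recs = [
            ("CT", Role.C_TERM_C, 1, "ALA", (5.0, 5.0, 5.0)),
            ("OT1", Role.C_TERM_O, 1, "ALA", (5.3, 5.0, 4.6)),
            ("OT2", Role.C_TERM_O, 1, "ALA", (4.7, 5.0, 4.6)),
            ("NT", Role.BACKBONE_N, 1, "ALA", (5.0 + n_vec[0], 5.0 + n_vec[1], 5.0 + n_vec[2])),
        ]
        return frame_to_traj(build_frame(recs, (20.0, 20.0, 20.0)))

    @pytest.mark.parametrize(
        "vec, bin_idx",
        [((0, 0, 1.5), 0), ((1.5, 0, 0), 89), ((1.5, 0, 1.5), 45), ((0, 0, -1.5), 0)],
    )
    def test_reference_vectors(self, vec, bin_idx):
        hist = orientation_histogram(self.orient_frame(vec))
        assert hist.counts.sum() == 1
        assert hist.counts[bin_idx] == 1

    def test_count_conserved_under_z_rotation(self):
        """Elevation is invariant when whole (unwrapped) molecules rotate
        rigidly about z."""
        rng = np.random.default_rng(8)
        recs = []
        for i in range(12):
            v = rng.normal(size=3) * 1.5
            x, y = 20.0 + rng.uniform(-3, 3, 2)
            recs += [
                ("CT", Role.C_TERM_C, i + 1, "ALA", (x, y, 15.0)),
                ("OT1", Role.C_TERM_O, i + 1, "ALA", (x + 0.3, y, 14.55)),
                ("OT2", Role.C_TERM_O, i + 1, "ALA", (x - 0.3, y, 14.55)),
                ("NT", Role.BACKBONE_N, i + 1, "ALA", (x + v[0], y + v[1], 15.0 + v[2])),
            ]
        traj = frame_to_traj(build_frame(recs, (40.0, 40.0, 30.0)))
        h1 = orientation_histogram(traj)
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        center = np.array([20.0, 20.0, 0.0])
        rotated = Trajectory(
            traj.atoms, (traj.coords - center) @ rot.T + center, traj.box, traj.times
        )
        h2 = orientation_histogram(rotated)
        assert h1.counts.sum() == h2.counts.sum() == h1.n_observations == 12
        assert np.array_equal(h1.counts, h2.counts)


class TestReactivePairs:
    def pair_frame(self, cn_dist):
        """Two adsorbed monomers with controlled C->N distance."""
        recs = list(flat_surface(0.0))
        recs += monomer(1, 6.0, 6.0, 2.0)
        # place second molecule so its NT is cn_dist from molecule 1's CT
        recs += [
            ("CT", Role.C_TERM_C, 2, "ALA", (6.0 + cn_dist + 5.0, 6.0, 2.0)),
            ("OT1", Role.C_TERM_O, 2, "ALA", (6.0 + cn_dist + 5.3, 6.0, 1.55)),
            ("OT2", Role.C_TERM_O, 2, "ALA", (6.0 + cn_dist + 4.7, 6.0, 1.55)),
            ("NT", Role.BACKBONE_N, 2, "ALA", (6.0 + cn_dist, 6.0, 2.0)),
        ]
        return frame_to_traj(build_frame(recs, (40.0, 24.0, 30.0)))

    @pytest.mark.parametrize("dist, expect", [(3.9, 1), (4.1, 0)])
    def test_cutoff_boundary(self, dist, expect):
        traj = self.pair_frame(dist)
        ads = adsorption_fraction(traj)
        assert ads.backbone[0].all()
        rp = reactive_pairs(traj, ads, cutoff=4.0)
        # molecule 1's CT to molecule 2's NT is `dist`; the reverse direction is far
        assert rp.counts[0] == expect

    def test_zero_cutoff_counts_nothing(self, small_traj):
        traj, _ = small_traj
        ads = adsorption_fraction(traj)
        assert reactive_pairs(traj, ads, cutoff=0.0).counts.sum() == 0

    def test_randomized_fixture_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        recs = list(flat_surface(0.0, nx=10, ny=10))
        n_mol = 20
        z_choices = rng.choice([2.0, 5.0], size=n_mol)  # adsorbed / desorbed mix
        for i in range(n_mol):
            x, y = rng.uniform(0, 28, 2)
            recs += monomer(i + 1, x, y, float(z_choices[i]))
        traj = frame_to_traj(build_frame(recs, (30.0, 30.0, 30.0)))
        ads = adsorption_fraction(traj)
        rp = reactive_pairs(traj, ads, cutoff=4.0)
        # oracle: explicit double loop over molecules
        mols = ads.molecules
        count = 0
        involved = set()
        for i, mi in enumerate(mols):
            if not ads.backbone[0, i]:
                continue
            for j, mj in enumerate(mols):
                if i == j or not (ads.backbone[0, j] or ads.sidechain[0, j]):
                    continue
                d = traj.coords[0][mi.ct] - traj.coords[0][mj.nt]
                d -= traj.box[0] * np.round(d / traj.box[0])
                if np.linalg.norm(d) < 4.0:
                    count += 1
                    involved |= {i, j}
        assert rp.counts[0] == count
        assert rp.percent_participating[0] == pytest.approx(100.0 * len(involved) / n_mol)
        assert rp.counts[0] <= n_mol  # bounded by available termini

    def test_aspartate_alpha_plus_beta_and_cyclic_exclusion(self):
        """A side-chain-adsorbed aspartate contributes beta pairs toward a
        neighbour's amine but never toward its own."""
        recs = list(flat_surface(0.0))
        # ASP with side-chain O pair near the surface, backbone O far
        recs += [
            ("CT", Role.C_TERM_C, 1, "ASP", (6.0, 6.0, 6.0)),
            ("OT1", Role.C_TERM_O, 1, "ASP", (6.3, 6.0, 5.55)),
            ("OT2", Role.C_TERM_O, 1, "ASP", (5.7, 6.0, 5.55)),
            ("NT", Role.BACKBONE_N, 1, "ASP", (6.0, 7.2, 6.9)),
            ("OD1", Role.SIDECHAIN_O, 1, "ASP", (6.5, 5.6, 2.0)),
            ("OD2", Role.SIDECHAIN_O, 1, "ASP", (7.3, 6.4, 2.0)),
        ]
        # neighbour with its amine 3 A from the ASP side-chain midpoint
        recs += monomer(2, 6.9, 7.2, 2.0)
        traj = frame_to_traj(build_frame(recs, (24.0, 24.0, 30.0)))
        ads = adsorption_fraction(traj)
        assert ads.sidechain[0, 0] and not ads.backbone[0, 0]
        rp = reactive_pairs(traj, ads, cutoff=4.0)
        mols = ads.molecules
        beta_site = traj.coords[0][mols[0].sidechain_o].mean(axis=0)
        d_other = np.linalg.norm(beta_site - traj.coords[0][mols[1].nt])
        d_own = np.linalg.norm(beta_site - traj.coords[0][mols[0].nt])
        assert d_other < 4.0 < d_own  # fixture geometry as intended
        assert rp.counts[0] == 1  # the beta pair only; own amine excluded
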