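"""Layer clustering, d-spacing and undulation against closed forms and
brute-force oracles."""

import numpy as np
import pytest

from clayped import (
    GeneratorConfig,
    Role,
    assign_layers,
    build_ldh_slab,
    d_spacing,
    generate,
    undulation,
)
from conftest import build_frame, frame_to_traj


def metal_grid(z_fn, mol_id=0, nx=20, ny=20, spacing=1.0):
    """Metal beads on a rectangular grid with z = z_fn(x, y)."""
    return [
        ("MG", Role.LDH_METAL_MG, mol_id, "LDH", (i * spacing, j * spacing, z_fn(i * spacing, j * spacing)))
        for i in range(nx)
        for j in range(ny)
    ]


def brute_force_layers(coords, linkage=5.0):
    """Independent oracle: connected components under a 5-Angstrom linkage."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    adj = d <= linkage
    labels = -np.ones(n, dtype=int)
    cur = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = cur
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(adj[j]):
                if labels[k] < 0:
                    labels[k] = cur
                    stack.append(k)
        cur += 1
    return labels


class TestAssignLayers:
    def test_two_flat_layers(self):
        recs = metal_grid(lambda x, y: 0.0) + metal_grid(lambda x, y: 12.0)
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        assert la.n_layers == 2
        assert la.mean_z == pytest.approx([0.0, 12.0])
        assert la.n_noise == 0

    def test_generator_slab_recovers_layer_count(self):
        cfg = GeneratorConfig(nx=8, ny=8, n_layers=5)
        la = assign_layers(build_ldh_slab(cfg))
        assert la.n_layers == 5
        assert np.allclose(np.diff(la.mean_z), cfg.period)

    def test_undulated_layer_stays_single_cluster(self):
        recs = metal_grid(lambda x, y: np.sin(2 * np.pi * x / 20.0))
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        oracle = brute_force_layers(frame.coords)
        assert la.n_layers == len(np.unique(oracle)) == 1

    def test_agrees_with_connectivity_oracle_on_split_slab(self):
        recs = metal_grid(lambda x, y: 0.2 * np.sin(x)) + metal_grid(lambda x, y: 11.0 + 0.2 * np.cos(y))
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        oracle = brute_force_layers(frame.coords)
        assert la.n_layers == len(np.unique(oracle))
        # identical partition (up to label order)
        for lab in range(la.n_layers):
            members = np.unique(oracle[la.labels == lab])
            assert len(members) == 1

    def test_invariant_under_rigid_z_translation(self):
        recs = metal_grid(lambda x, y: 0.0) + metal_grid(lambda x, y: 12.0)
        frame = build_frame(recs, (20.0, 20.0, 40.0))
        shifted = build_frame(
            [(n, r, m, t, (x, y, z + 7.0)) for (n, r, m, t, (x, y, z)) in recs],
            (20.0, 20.0, 40.0),
        )
        la1, la2 = assign_layers(frame), assign_layers(shifted)
        assert np.array_equal(la1.labels, la2.labels)

    def test_no_metals_is_an_error(self):
        frame = build_frame([("OW", Role.WATER_O, 0, "SOL", (0, 0, 0))], (10, 10, 10))
        with pytest.raises(ValueError, match="metal"):
            assign_layers(frame)

    def test_unexpected_layer_count_warns(self):
        recs = metal_grid(lambda x, y: 0.0)
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        with pytest.warns(UserWarning, match="expected"):
            la = assign_layers(frame, expected=5)
        assert la.warning is not None


class TestDSpacing:
    def test_flat_layers_closed_form(self):
        recs = metal_grid(lambda x, y: 0.0) + metal_grid(lambda x, y: 12.0)
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        prof = d_spacing(la, frame)
        assert prof.mean == pytest.approx(12.0)
        assert prof.std == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(prof.local_maps[0][~np.isnan(prof.local_maps[0])], 12.0)
        # closed-form agreement with the layer mean-z difference
        assert prof.pair_mean[0] == pytest.approx(la.mean_z[1] - la.mean_z[0])

    def test_nonperiodic_map_dimensions(self):
        recs = metal_grid(lambda x, y: 0.0) + metal_grid(lambda x, y: 12.0)
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        prof = d_spacing(la, frame, window=5.0, step=1.0, periodic=False)
        n_expected = int(np.floor((20.0 - 5.0) / 1.0)) + 1
        assert prof.local_maps[0].shape == (n_expected, n_expected)

    def test_sinusoidal_upper_layer_reproduced_in_local_map(self):
        L = 40.0
        lower = metal_grid(lambda x, y: 0.0, nx=40, ny=40)
        upper = metal_grid(lambda x, y: 12.0 + np.sin(2 * np.pi * x / L), nx=40, ny=40)
        frame = build_frame(lower + upper, (L, L, 30.0))
        la = assign_layers(frame)
        prof = d_spacing(la, frame, periodic=False)
        grid = prof.local_maps[0]
        xs = np.arange(grid.shape[0]) * 1.0
        # window mean of the sinusoid over atoms at x0..x0+5 (dense sampling)
        for i in (0, 7, 19):
            window_x = xs[i] + np.arange(0, 6)
            expected = 12.0 + np.mean(np.sin(2 * np.pi * window_x / L))
            assert grid[i, 0] == pytest.approx(expected, abs=1e-9)

    def test_anticorrelated_undulation_raises_local_std(self):
        L = 40.0
        a = 0.5
        lower = metal_grid(lambda x, y: a * np.sin(2 * np.pi * x / L), nx=40, ny=40)
        upper = metal_grid(lambda x, y: 12.0 - a * np.sin(2 * np.pi * x / L), nx=40, ny=40)
        frame = build_frame(lower + upper, (L, L, 30.0))
        la = assign_layers(frame)
        prof = d_spacing(la, frame)
        traj = frame_to_traj(frame)
        und = undulation(la, traj)
        assert prof.std > und.per_layer_std.max()

    def test_single_layer_is_an_error(self):
        frame = build_frame(metal_grid(lambda x, y: 0.0), (20.0, 20.0, 30.0))
        with pytest.raises(ValueError):
            d_spacing(assign_layers(frame), frame)


class TestUndulation:
    def test_flat_layers_zero(self):
        recs = metal_grid(lambda x, y: 0.0) + metal_grid(lambda x, y: 12.0)
        frame = build_frame(recs, (20.0, 20.0, 30.0))
        la = assign_layers(frame)
        assert undulation(la, frame_to_traj(frame)).pooled_std == pytest.approx(0.0)

    def test_sinusoid_rms_recovered(self):
        """Amplitude-A sinusoidal undulation pools to A/sqrt(2)."""
        cfg = GeneratorConfig(
            nx=16, ny=16, n_layers=2, rng_seed=3, hydration=0, undulation_amplitude=1.0
        )
        traj, _ = generate(cfg, ["ALA"] * 4, n_frames=4)
        la = assign_layers(traj.first_frame())
        und = undulation(la, traj)
        assert und.pooled_std == pytest.approx(1.0 / np.sqrt(2.0), rel=0.02)

    def test_amplitude_monotonicity(self):
        stds = []
        for amp in (0.5, 2.0):
            cfg = GeneratorConfig(
                nx=16, ny=16, n_layers=2, rng_seed=3, hydration=0, undulation_amplitude=amp
            )
            traj, _ = generate(cfg, ["ALA"] * 4, n_frames=3)
            la = assign_layers(traj.first_frame())
            stds.append(undulation(la, traj).pooled_std)
        assert stds[0] < stds[1]
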