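"""Grid construction and steric/electrostatic field evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from triazqsar import fields as F
from triazqsar.prep import Conformer3D


def atom_system(coords, charges=None, symbols=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return Conformer3D(
        compound_id=0,
        symbols=symbols or ["C"] * n,
        coords=coords,
        charges=None if charges is None else np.asarray(charges, dtype=float),
    )


class TestMakeGrid:
    def test_single_atom_padding_arithmetic(self):
        grid = F.make_grid([atom_system([0, 0, 0])], spacing=2.0, margin=4.0)
        assert grid.origin == (-4.0, -4.0, -4.0)
        assert grid.dims == (5, 5, 5)

    def test_every_atom_strictly_inside(self, small_aligned):
        grid = F.make_grid(small_aligned.conformers, spacing=2.0, margin=4.0)
        lo = np.array(grid.origin)
        hi = lo + grid.spacing * (np.array(grid.dims) - 1)
        for conf in small_aligned.conformers:
            assert (conf.coords > lo).all() and (conf.coords < hi).all()

    @given(st.floats(0.5, 6.0), st.floats(0.5, 6.0))
    def test_margin_monotonicity(self, m1, m2):
        lo_m, hi_m = sorted([m1, m2])
        conf = atom_system([[0.3, -1.2, 2.7], [4.0, 2.0, -3.0]])
        d_lo = F.make_grid([conf], spacing=2.0, margin=lo_m).dims
        d_hi = F.make_grid([conf], spacing=2.0, margin=hi_m).dims
        assert all(a <= b for a, b in zip(d_lo, d_hi))

    def test_point_order_x_fastest(self):
        grid = F.GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        pts = grid.points()
        assert np.array_equal(pts[0], [0, 0, 0])
        assert np.array_equal(pts[1], [1, 0, 0])  # x moves first
        assert np.array_equal(pts[2], [0, 1, 0])
        assert np.array_equal(pts[4], [0, 0, 1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            F.make_grid([], spacing=2.0, margin=4.0)


ONE_POINT = F.GridSpec((2.0, 0.0, 0.0), 1.0, (1, 1, 1))


class TestElectrostatic:
    def test_hand_coulomb_with_truncation(self):
        # q=+0.5 e at 2 A: 332.06*0.5/2^2 = 41.5 kcal/mol, clamped to +30
        conf = atom_system([0, 0, 0], charges=[0.5])
        assert F.electrostatic_field(conf, ONE_POINT)[0] == pytest.approx(30.0)
        raw = F.electrostatic_field(conf, ONE_POINT, truncate=False)[0]
        assert raw == pytest.approx(332.06 * 0.5 / 4.0)

    def test_zero_charges_zero_field(self, small_aligned):
        conf = small_aligned.conformers[0]
        neutral = conf.with_coords(conf.coords)
        neutral.charges = np.zeros(len(conf.symbols))
        grid = F.make_grid([neutral], 2.0, 4.0)
        assert np.all(F.electrostatic_field(neutral, grid) == 0)

    def test_superposition_of_coincident_charges(self):
        one = atom_system([0, 0, 0], charges=[0.3])
        two = atom_system([[0, 0, 0], [0, 0, 0]], charges=[0.3, 0.3])
        e1 = F.electrostatic_field(one, ONE_POINT, truncate=False)
        e2 = F.electrostatic_field(two, ONE_POINT, truncate=False)
        assert e2[0] == pytest.approx(2 * e1[0])

    def test_linearity_against_bruteforce_oracle(self, rng):
        # field of a random system == brute-force pairwise sum, and is linear
        # in the charges before truncation
        coords = rng.normal(scale=3.0, size=(6, 3))
        q1 = rng.normal(size=6)
        q2 = rng.normal(size=6)
        grid = F.GridSpec((-5.0, -5.0, -5.0), 2.5, (5, 5, 5))
        cfg = F.FieldConfig()

        def brute(q):
            out = np.zeros(grid.n_points)
            for p, pt in enumerate(grid.points()):
                for i in range(len(coords)):
                    r = max(np.linalg.norm(coords[i] - pt), cfg.distance_floor)
                    out[p] += cfg.coulomb_constant * q[i] / r**2
            return out

        f1 = F.electrostatic_field(atom_system(coords, q1), grid, truncate=False)
        f2 = F.electrostatic_field(atom_system(coords, q2), grid, truncate=False)
        fsum = F.electrostatic_field(atom_system(coords, q1 + q2), grid, truncate=False)
        assert np.allclose(f1, brute(q1), atol=1e-9)
        assert np.allclose(fsum, f1 + f2, atol=1e-9)

    def test_missing_charges_rejected(self):
        with pytest.raises(ValueError, match="charges"):
            F.electrostatic_field(atom_system([0, 0, 0]), ONE_POINT)


class TestSteric:
    def test_lj_minimum_at_contact_distance(self):
        r_min = F.VDW_PARAMS["C"][0] + 1.5
        grid = F.GridSpec((r_min, 0.0, 0.0), 1.0, (1, 1, 1))
        energy = F.steric_field(atom_system([0, 0, 0]), grid)[0]
        assert energy == pytest.approx(-np.sqrt(F.VDW_PARAMS["C"][1] * 0.105))

    def test_decay_to_zero_from_below(self):
        conf = atom_system([0, 0, 0])
        r_min = F.VDW_PARAMS["C"][0] + 1.5
        radii = r_min * np.array([1.0, 1.5, 2.0, 3.0, 5.0])
        energies = [
            F.steric_field(conf, F.GridSpec((r, 0.0, 0.0), 1.0, (1, 1, 1)))[0]
            for r in radii
        ]
        assert all(e < 0 for e in energies)
        assert all(a < b for a, b in zip(energies, energies[1:]))  # monotone up
        assert abs(energies[-1]) < 1e-3

    def test_clamped_inside_atom(self):
        r_min = F.VDW_PARAMS["C"][0] + 1.5
        grid = F.GridSpec((0.5 * r_min, 0.0, 0.0), 1.0, (1, 1, 1))
        assert F.steric_field(atom_system([0, 0, 0]), grid)[0] == pytest.approx(30.0)

    def test_unparameterized_element_rejected(self):
        with pytest.raises(ValueError, match="Xe"):
            F.steric_field(atom_system([0, 0, 0], symbols=["Xe"]), ONE_POINT)


class TestTruncate:
    def test_clamp_and_idempotence(self):
        v = np.array([45.0, -60.0, 3.0])
        clamped = F.truncate_field(v, 30.0)
        assert np.array_equal(clamped, [30.0, -30.0, 3.0])
        assert np.array_equal(F.truncate_field(clamped, 30.0), clamped)

    def test_default_config_limit(self):
        assert F.FieldConfig().truncation == 30.0


class TestSymmetryAndInvariance:
    def test_mirror_symmetric_molecule_gives_symmetric_field(self):
        # two identical atoms mirror-symmetric about the x=0 plane
        conf = atom_system([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]], charges=[0.2, 0.2])
        grid = F.GridSpec((-4.0, 0.0, 0.0), 2.0, (5, 1, 1))
        for vec in (
            F.electrostatic_field(conf, grid),
            F.steric_field(conf, grid),
        ):
            assert np.allclose(vec, vec[::-1], atol=1e-12)

    def test_joint_translation_leaves_fields_unchanged(self, small_aligned):
        conf = small_aligned.conformers[0]
        grid = F.make_grid([conf], 2.0, 4.0)
        shift = np.array([7.0, -3.0, 11.0])
        conf2 = conf.with_coords(conf.coords + shift)
        conf2.charges = conf.charges
        grid2 = F.GridSpec(
            tuple(np.array(grid.origin) + shift), grid.spacing, grid.dims
        )
        assert np.allclose(
            F.electrostatic_field(conf, grid), F.electrostatic_field(conf2, grid2)
        )
        assert np.allclose(F.steric_field(conf, grid), F.steric_field(conf2, grid2))


class TestDescriptorMatrix:
    def test_shapes_bounds_and_index(self, small_descriptors):
        desc = small_descriptors
        n_cols_max = 2 * desc.grid.n_points
        assert desc.X.shape[0] == 4 and desc.X.shape[1] <= n_cols_max
        assert len(desc.columns) == desc.X.shape[1]
        # every weighted descriptor within +/- weight * truncation
        assert np.abs(desc.X).max() <= 0.5 * 30.0 + 1e-12

    def test_identical_molecules_drop_all_columns(self, small_aligned):
        conf = small_aligned.conformers[0]
        grid = F.make_grid([conf], 2.0, 4.0)
        cfg = F.FieldConfig()
        block = F.compute_field_block(conf, grid, cfg)
        import copy

        desc = F.assemble_descriptor_matrix([block, copy.deepcopy(block)], grid, cfg)
        assert desc.X.shape[1] == 0

    def test_zero_floor_keeps_everything(self, small_aligned):
        conf = small_aligned.conformers[0]
        grid = F.make_grid([conf], 2.0, 4.0)
        cfg = F.FieldConfig()
        block = F.compute_field_block(conf, grid, cfg)
        desc = F.assemble_descriptor_matrix([block], grid, cfg, variance_floor=0.0)
        assert desc.X.shape[1] == 2 * grid.n_points

    def test_grid_mismatch_rejected(self, small_aligned):
        confs = small_aligned.conformers[:2]
        g1 = F.make_grid(confs, 2.0, 4.0)
        g2 = F.make_grid(confs, 2.0, 6.0)
        cfg = F.FieldConfig()
        blocks = [
            F.compute_field_block(confs[0], g1, cfg),
            F.compute_field_block(confs[1], g2, cfg),
        ]
        with pytest.raises(ValueError, match="grid mismatch"):
            F.assemble_descriptor_matrix(blocks, g1, cfg)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            F.FieldConfig(steric_weight=0.7, electrostatic_weight=0.5)
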