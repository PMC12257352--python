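"""Warping, field inversion/composition, direct dose mapping and summation."""

import numpy as np
import pytest

from dosewarp import (ScalarVolume, VectorField, VolumeGrid, accumulate_dose_ddm,
                      compose, invert_field, sum_doses, warp_image, warp_mask)


def _grid(n=12, s=2.0):
    half = (n - 1) / 2.0 * s
    return VolumeGrid((n, n, n), (s, s, s), (-half, -half, -half))


def _zero_field(grid, tag="plan_to_mod"):
    return VectorField(grid, np.zeros(grid.size + (3,)), tag)


def _const_field(grid, vec, tag="plan_to_mod"):
    return VectorField(grid, np.broadcast_to(np.asarray(vec, float),
                                             grid.size + (3,)).copy(), tag)


def _ramp(grid, axis=0):
    coords = grid.meshgrid_mm()[axis]
    vals = np.broadcast_to(coords, grid.size).copy() + 100.0  # keep positive
    return ScalarVolume(grid, vals, "Gy")


class TestWarpImage:
    def test_zero_field_identity(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        vol = ScalarVolume(grid, rng.random(grid.size), "HU")
        out = warp_image(vol, _zero_field(grid))
        assert np.allclose(out.values, vol.values)

    def test_constant_field_shifts_ramp(self):
        grid = _grid()
        vol = _ramp(grid)
        out = warp_image(vol, _const_field(grid, (5.0, 0.0, 0.0)))
        interior = np.s_[1:-4, :, :]
        x = np.broadcast_to(grid.meshgrid_mm()[0], grid.size)
        assert np.allclose(out.values[interior], (x + 100.0 + 5.0)[interior], atol=1e-9)

    def test_mask_roundtrip_through_inverse(self, prostate_phantom, bladder_expand_field):
        _, structures, _ = prostate_phantom
        from dosewarp import dice

        inv = invert_field(bladder_expand_field, mask=structures["body"])
        for organ in ("bladder", "prostate", "rectum"):
            fwd = warp_mask(structures[organ], structures.grid, bladder_expand_field)
            back = warp_mask(fwd, structures.grid, inv)
            assert dice(structures[organ], back) > 0.98


class TestInvertField:
    def test_zero_field_inverts_to_zero(self):
        grid = _grid()
        inv = invert_field(_zero_field(grid, "mod_to_plan"))
        assert inv.magnitude.max() == 0.0
        assert inv.residual_mm == 0.0
        assert inv.direction_tag == "plan_to_mod"

    def test_translation_inverts_to_negation_interior(self):
        grid = _grid(n=16)
        t = np.array([3.0, -1.0, 2.0])
        inv = invert_field(_const_field(grid, t, "mod_to_plan"))
        interior = np.s_[3:-3, 3:-3, 3:-3]
        assert np.allclose(inv.displacements[interior], -t, atol=0.05)

    def test_affine_field_closed_form(self):
        # u(x) = 0.1 x has inverse v(x) = -x / 11 (x -> x / 1.1)
        grid = _grid(n=16)
        pts = grid.points_mm().reshape(grid.size + (3,))
        f = VectorField(grid, 0.1 * pts, "mod_to_plan")
        inv = invert_field(f)
        interior = np.s_[3:-3, 3:-3, 3:-3]
        expected = -pts / 11.0
        assert np.abs(inv.displacements[interior] - expected[interior]).max() < 0.05

    def test_double_inversion_recovers_field(self, prostate_phantom, bladder_expand_field):
        _, structures, _ = prostate_phantom
        body = structures["body"]
        inv = invert_field(bladder_expand_field, mask=body)
        back = invert_field(inv, mask=body)
        diff = np.linalg.norm(back.displacements - bladder_expand_field.displacements,
                              axis=-1)
        # each inversion adds its 0.05 mm tolerance plus the trilinear
        # sampling error of the curved field at this voxel pitch
        assert diff[body].max() < 0.5
        assert diff[body].mean() < 2 * 0.05


class TestCompose:
    def test_zero_is_identity_element(self):
        grid = _grid()
        rng = np.random.default_rng(1)
        f = VectorField(grid, rng.standard_normal(grid.size + (3,)) * 0.5, "plan_to_mod")
        z = _zero_field(grid)
        assert np.allclose(compose(f, z).displacements, f.displacements)
        # compose(zero, f) needs f's values sampled at x + f, which equals f
        # only where f's own samples stay in-grid; check the interior
        interior = np.s_[2:-2, 2:-2, 2:-2]
        assert np.allclose(compose(z, f).displacements[interior],
                           f.displacements[interior])

    def test_translations_add(self):
        grid = _grid(n=16)
        a = _const_field(grid, (2.0, 0.0, 1.0))
        b = _const_field(grid, (-1.0, 3.0, 0.0))
        interior = np.s_[3:-3, 3:-3, 3:-3]
        got = compose(a, b).displacements[interior]
        assert np.allclose(got, np.array([1.0, 3.0, 1.0]), atol=1e-9)

    def test_compose_with_inverse_is_near_zero(self, prostate_phantom,
                                               bladder_expand_field):
        _, structures, _ = prostate_phantom
        inv = invert_field(bladder_expand_field, mask=structures["body"])
        resid = compose(bladder_expand_field,
                        VectorField(inv.grid, inv.displacements,
                                    bladder_expand_field.direction_tag))
        assert resid.magnitude[structures["body"]].max() < 2 * 0.05


class TestAccumulateDDM:
    def test_zero_field_returns_fraction_dose(self):
        grid = _grid()
        rng = np.random.default_rng(2)
        dose = ScalarVolume(grid, rng.random(grid.size) * 3, "Gy")
        out = accumulate_dose_ddm(dose, _zero_field(grid))
        assert np.allclose(out.values, dose.values)

    def test_constant_field_closed_form_on_ramp(self):
        grid = _grid(n=16)
        dose = _ramp(grid)
        out = accumulate_dose_ddm(dose, _const_field(grid, (3.0, 0.0, 0.0)))
        x = np.broadcast_to(grid.meshgrid_mm()[0], grid.size)
        interior = np.s_[2:-4, :, :]
        assert np.allclose(out.values[interior], (x + 100.0 + 3.0)[interior], atol=1e-9)

    def test_direction_tag_enforced(self):
        grid = _grid()
        dose = ScalarVolume(grid, np.ones(grid.size), "Gy")
        with pytest.raises(ValueError, match="plan_to_mod"):
            accumulate_dose_ddm(dose, _zero_field(grid, "mod_to_plan"))

    def test_linearity_in_dose(self):
        grid = _grid()
        rng = np.random.default_rng(3)
        d1 = ScalarVolume(grid, rng.random(grid.size), "Gy")
        d2 = ScalarVolume(grid, rng.random(grid.size), "Gy")
        f = VectorField(grid, rng.standard_normal(grid.size + (3,)) * 0.8, "plan_to_mod")
        both = accumulate_dose_ddm(ScalarVolume(grid, d1.values + d2.values, "Gy"), f)
        sep = sum_doses([accumulate_dose_ddm(d1, f), accumulate_dose_ddm(d2, f)])
        assert np.allclose(both.values, sep.values, atol=1e-12)

    def test_range_preserved_by_trilinear_convexity(self):
        grid = _grid()
        rng = np.random.default_rng(4)
        dose = ScalarVolume(grid, rng.random(grid.size) * 5 + 1, "Gy")
        f = VectorField(grid, rng.standard_normal(grid.size + (3,)) * 1.5, "plan_to_mod")
        out = accumulate_dose_ddm(dose, f)
        assert out.values.max() <= dose.values.max() + 1e-12
        assert out.values.min() >= 0.0

    def test_accumulation_through_true_inverse_recovers_plan_dose(
            self, prostate_phantom, fraction_dose, bladder_expand_field):
        # warp the plan dose to the modified anatomy, then accumulate it back
        # through the inverted authoring field: the PTV dose must return
        _, structures, _ = prostate_phantom
        inv = invert_field(bladder_expand_field, mask=structures["body"])
        warped_fx = warp_image(fraction_dose, bladder_expand_field)
        back = accumulate_dose_ddm(warped_fx, inv)
        ptv = structures["PTV"]
        err = np.abs(back.values[ptv] - fraction_dose.values[ptv]).mean()
        # two trilinear passes across the penumbra gradient bound the error
        assert err < 0.01 * fraction_dose.values.max()


class TestSumDoses:
    def test_sum_of_one_is_identity(self):
        grid = _grid()
        d = ScalarVolume(grid, np.random.default_rng(5).random(grid.size), "Gy")
        assert np.array_equal(sum_doses([d]).values, d.values)

    def test_n_copies_scale(self):
        grid = _grid()
        d = ScalarVolume(grid, np.random.default_rng(6).random(grid.size), "Gy")
        assert np.allclose(sum_doses([d] * 4).values, 4 * d.values)

    def test_permutation_invariant(self):
        grid = _grid()
        rng = np.random.default_rng(7)
        ds = [ScalarVolume(grid, rng.random(grid.size), "Gy") for _ in range(3)]
        a = sum_doses(ds).values
        b = sum_doses(ds[::-1]).values
        # up to float addition order
        assert np.allclose(a, b, rtol=1e-13, atol=0.0)

    def test_grid_mismatch_rejected(self):
        d1 = ScalarVolume(_grid(), np.zeros((12, 12, 12)), "Gy")
        d2 = ScalarVolume(_grid(n=10), np.zeros((10, 10, 10)), "Gy")
        with pytest.raises(ValueError, match="grid"):
            sum_doses([d1, d2])
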