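"""Displacement-field algebra and diffeomorphic demons registration."""

import numpy as np
import pytest

from tbmorph.core import ImageVolume
from tbmorph.phantom import AnalyticWarp, make_analytic_warp, make_base_phantom
from tbmorph.register import (DisplacementField, RegistrationError,
                              RegistrationParams, build_groupwise_template, compose,
                              identity_field, invert, jacobian_determinant,
                              load_field, register_nonrigid, save_field, warp)

FAST = RegistrationParams(iterations=(60, 40, 20))


def translation_field(like, shift_mm):
    f = identity_field(like)
    f.u[:] = np.asarray(shift_mm, np.float32)
    return f


@pytest.fixture(scope="module")
def warp_pair(geom, base_phantom):
    """Base image plus the same anatomy carrying a ratio-1.5 local expansion."""
    img, lab = base_phantom
    idx = np.argwhere(lab.roi_mask("lateral_ventricles"))
    right = idx[idx[:, 0] > img.shape[0] // 2]
    center = right.mean(axis=0) * geom.spacing
    gen = make_analytic_warp(
        AnalyticWarp(center=tuple(center), inner_radius=2.0, outer_radius=4.0,
                     volume_ratio=1 / 1.5), img)
    later = warp(img, gen)
    ball = np.linalg.norm(
        np.stack(np.meshgrid(*[np.arange(n) * s for n, s in zip(img.shape, geom.spacing)],
                             indexing="ij"), axis=-1) - center, axis=-1) < 1.6
    return img, later, ball


class TestWarp:
    def test_identity_field_is_identity(self, base_phantom):
        img, _ = base_phantom
        out = warp(img, identity_field(img))
        assert np.allclose(out.data, img.data, atol=1e-5)

    def test_integer_translation_moves_delta_exactly(self, zero_volume):
        img = zero_volume.with_data(np.zeros(zero_volume.shape, np.float32))
        img.data[20, 20, 20] = 1.0
        # phi(x) = x + u samples the input "ahead", so the delta moves by -u
        f = translation_field(img, (3 * 0.2, 0.0, 0.0))
        out = warp(img, f)
        assert out.data[17, 20, 20] == 1.0
        assert out.data.sum() == 1.0

    def test_label_volume_requires_nearest(self, base_phantom):
        _, lab = base_phantom
        with pytest.raises(ValueError, match="nearest"):
            warp(lab, identity_field(lab), "linear")

    def test_out_of_domain_becomes_background(self, base_phantom):
        img, _ = base_phantom
        f = translation_field(img, (1000.0, 0.0, 0.0))
        assert warp(img, f).data.sum() == 0.0


class TestFieldAlgebra:
    def test_compose_with_identity(self, base_phantom):
        img, _ = base_phantom
        g = translation_field(img, (0.4, -0.2, 1.0))
        out = compose(identity_field(img), g)
        assert np.allclose(out.u, g.u, atol=1e-6)

    def test_compose_translations_adds_exactly(self, base_phantom):
        img, _ = base_phantom
        f = translation_field(img, (0.4, 0.0, 1.0))
        g = translation_field(img, (-0.2, 0.6, 0.0))
        out = compose(f, g)
        assert np.allclose(out.u, np.array([0.2, 0.6, 1.0], np.float32), atol=1e-5)

    def test_invert_translation_exact(self, base_phantom):
        img, _ = base_phantom
        f = translation_field(img, (0.4, -0.6, 0.0))
        inv = invert(f, tol=1e-6)
        assert np.allclose(inv.u, -f.u, atol=1e-5)

    def test_invert_analytic_warp_residual_small(self, zero_volume):
        spec = AnalyticWarp(center=(4.8, 4.8, 4.8), inner_radius=1.5,
                            outer_radius=3.2, volume_ratio=1.5)
        f = make_analytic_warp(spec, zero_volume)
        inv = invert(f)
        res = compose(f, inv)
        mean_vox = np.mean(np.linalg.norm(res.u, axis=-1)) / 0.2
        assert mean_vox < 0.1

    def test_compose_then_invert_roundtrip(self, zero_volume):
        spec = AnalyticWarp(center=(4.8, 4.8, 4.8), inner_radius=1.5,
                            outer_radius=3.2, volume_ratio=1.4)
        g = make_analytic_warp(spec, zero_volume)
        res = compose(g, invert(g))
        assert np.mean(np.linalg.norm(res.u, axis=-1)) / 0.2 < 0.2

    def test_geometry_mismatch_rejected(self, base_phantom, zero_volume):
        img, _ = base_phantom
        with pytest.raises(ValueError):
            compose(identity_field(img), identity_field(zero_volume))


class TestRegisterNonrigid:
    def test_self_registration_near_zero(self, base_phantom):
        img, _ = base_phantom
        f = register_nonrigid(img, img, FAST)
        assert f.magnitude_voxels().max() < 0.1

    def test_known_warp_recovered_within_15_percent(self, warp_pair):
        img, later, ball = warp_pair
        f = register_nonrigid(img, later)
        det = jacobian_determinant(f)
        mean_lj = np.log(det[ball]).mean()
        assert mean_lj == pytest.approx(np.log(1.5), rel=0.15)
        assert det.min() > 0

    def test_mse_at_least_halved(self, warp_pair):
        img, later, _ = warp_pair
        f = register_nonrigid(img, later, FAST)
        warped = warp(later, f)
        pre = np.mean((img.data - later.data)[img.mask] ** 2)
        post = np.mean((img.data - warped.data)[img.mask] ** 2)
        assert post <= 0.5 * pre

    def test_contrast_scale_invariance(self, warp_pair):
        img, later, _ = warp_pair
        f1 = register_nonrigid(img, later, FAST)
        f2 = register_nonrigid(img, later.with_data(later.data * 2.0), FAST)
        mean_change = np.mean(np.linalg.norm(f1.u - f2.u, axis=-1)) / np.mean(img.spacing)
        assert mean_change < 0.2

    def test_no_contrast_rejected(self, base_phantom):
        img, _ = base_phantom
        flat = img.with_data(np.ones_like(img.data), mask=None)
        with pytest.raises(RegistrationError):
            register_nonrigid(img, flat, FAST)

    def test_emitted_fields_never_fold(self, geom):
        """Structured vs mismatched content: either reject or emit a field
        with strictly positive Jacobian (contract enforced on every exit)."""
        rng = np.random.default_rng(0)
        img1, _ = make_base_phantom(geom, seed=1)
        noise = img1.with_data(
            np.abs(rng.normal(100, 30, img1.shape)).astype(np.float32))
        try:
            f = register_nonrigid(img1, noise, FAST)
        except RegistrationError:
            return
        assert jacobian_determinant(f)[1:-1, 1:-1, 1:-1].min() > 0


class TestGroupwise:
    def test_identical_inputs_give_input_template(self, base_phantom):
        img, _ = base_phantom
        gw = build_groupwise_template([img, img, img], FAST, n_outer_iter=2)
        assert np.allclose(gw.template.data, img.data, atol=1e-3)
        for f in gw.fields:
            assert f.magnitude_voxels().max() < 0.1

    def test_template_sits_between_two_warped_phantoms(self, warp_pair):
        from tbmorph.jacobian import log_jacobian
        img, later, ball = warp_pair
        gw = build_groupwise_template([img, later], FAST, n_outer_iter=3)
        lj = [np.mean(log_jacobian(
            register_nonrigid(gw.template, v, FAST)).values[ball]) for v in (img, later)]
        assert lj[0] * lj[1] < 0  # opposite signs
        assert abs(lj[0] + lj[1]) < 0.25 * max(abs(lj[0]), abs(lj[1]))

    def test_unbiased_mean_field(self, warp_pair):
        img, later, _ = warp_pair
        gw = build_groupwise_template([img, later], FAST, n_outer_iter=2)
        mean_u = np.mean([f.u for f in gw.fields], axis=0)
        assert np.mean(np.linalg.norm(mean_u, axis=-1)) / np.mean(img.spacing) < 0.1

    def test_template_sharper_than_naive_mean(self, geom):
        """With subject-level anatomical variability, averaging unregistered
        scans blurs structure that the group-wise template retains."""
        from scipy import ndimage

        img, _ = make_base_phantom(geom, seed=3)

        def anatomy_field(seed, max_vox=4.0):
            rng = np.random.default_rng(seed)
            coarse = tuple(max(2, n // 8) for n in geom.shape)
            u = np.empty(geom.shape + (3,), np.float32)
            for c in range(3):
                grain = rng.standard_normal(coarse)
                grain = ndimage.zoom(grain, [t / s for t, s in zip(geom.shape, coarse)],
                                     order=3)
                u[..., c] = ndimage.gaussian_filter(grain, 3.0)
            sp = np.asarray(geom.spacing)
            u *= max_vox / np.linalg.norm(u / sp, axis=-1).max()
            return DisplacementField(u=u, spacing=sp, affine=geom.affine)

        vols = [warp(img, anatomy_field(100 + i)) for i in range(6)]
        gw = build_groupwise_template(vols, FAST, n_outer_iter=2)

        def grad_energy(a):
            return sum(np.sum(np.gradient(a, axis=i) ** 2) for i in range(3))

        naive = np.mean([v.data for v in vols], axis=0)
        assert grad_energy(gw.template.data) > grad_energy(naive)


class TestSerialization:
    def test_field_roundtrip(self, zero_volume, tmp_path):
        spec = AnalyticWarp(center=(4.8, 4.8, 4.8), inner_radius=1.5,
                            outer_radius=3.2, volume_ratio=1.3)
        f = make_analytic_warp(spec, zero_volume)
        save_field(f, tmp_path / "f.nii")
        g = load_field(tmp_path / "f.nii")
        assert np.allclose(f.u, g.u, atol=1e-6)
        assert np.allclose(f.spacing, g.spacing)


class TestJacobianCrossCheck:
    def test_determinant_matches_simpleitk(self, zero_volume):
        """Independent oracle: SimpleITK's displacement-field Jacobian
        determinant on a smooth random field (isotropic grid)."""
        sitk = pytest.importorskip("SimpleITK")
        from scipy import ndimage
        rng = np.random.default_rng(4)
        u = np.stack([ndimage.gaussian_filter(rng.normal(0, 0.5, zero_volume.shape), 3)
                      for _ in range(3)], axis=-1).astype(np.float32)
        f = DisplacementField(u=u, spacing=zero_volume.spacing,
                              affine=zero_volume.affine)
        ours = jacobian_determinant(f)
        # SimpleITK uses (z,y,x) array order; vector components stay (x,y,z)
        img = sitk.GetImageFromArray(u.transpose(2, 1, 0, 3), isVector=True)
        img.SetSpacing(tuple(zero_volume.spacing))
        det = sitk.GetArrayFromImage(
            sitk.DisplacementFieldJacobianDeterminant(img)).transpose(2, 1, 0)
        interior = (slice(2, -2),) * 3
        assert np.allclose(ours[interior], det[interior], atol=5e-3)
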