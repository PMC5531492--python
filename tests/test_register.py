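import numpy as np
import pytest

from lungmech import (
    DeformationField,
    MaskSet,
    RegistrationConfig,
    ScalarVolume,
    jacobian_det_map,
    register,
    sstvd_cost,
    volume_ratio_map,
    warp_image,
)
from lungmech.register import RegistrationDomainError
from lungmech.phantom import HyperRegion, PhantomSpec, generate


def _affine_field(like: ScalarVolume, A: np.ndarray, center=None) -> DeformationField:
    """u(x) = (A - I)(x - c): T is the affine map about c."""
    idx = np.indices(like.shape).reshape(3, -1).T
    X = idx * np.asarray(like.spacing)
    c = np.zeros(3) if center is None else np.asarray(center)
    u = (X - c) @ (A - np.eye(3)).T
    return DeformationField(u.reshape(like.shape + (3,)), like.spacing, like.origin)


@pytest.fixture(scope="module")
def pair():
    return generate(PhantomSpec(shape=(24, 24, 24), spacing=(2.5,) * 3, seed=2))


class TestCost:
    def test_zero_at_identity_on_identical_images(self, pair):
        e = sstvd_cost(pair.time1, pair.time1_mask, pair.time1)
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_uniform_shift_closed_form(self):
        """A +10 HU shift inside the lung costs (10/1055 * v)^2 per voxel."""
        shape = (12, 12, 12)
        data = np.full(shape, -600.0)
        lung = np.zeros(shape, dtype=bool)
        lung[3:9, 3:9, 3:9] = True
        ref = ScalarVolume(data + 10.0 * lung, (1.5, 1.5, 1.5))
        flt = ScalarVolume(data, (1.5, 1.5, 1.5))
        mask = MaskSet(lung=lung)
        v = ref.voxel_volume
        expected = (10.0 / 1055.0 * v) ** 2 * lung.sum()
        assert sstvd_cost(ref, mask, flt) == pytest.approx(expected, rel=1e-9)

    def test_identity_is_local_minimum_on_identical_images(self, pair, rng):
        e0 = sstvd_cost(pair.time1, pair.time1_mask, pair.time1)
        u = rng.normal(0, 0.8, size=pair.time1.shape + (3,))
        field = DeformationField(u, pair.time1.spacing)
        assert e0 <= sstvd_cost(pair.time1, pair.time1_mask, pair.time1, field)

    def test_domain_error_when_mapping_outside(self, pair):
        u = np.full(pair.time1.shape + (3,), 1000.0)
        field = DeformationField(u, pair.time1.spacing)
        with pytest.raises(RegistrationDomainError):
            sstvd_cost(pair.time1, pair.time1_mask, pair.time1, field)


class TestJacobian:
    def test_identity(self, pair):
        field = DeformationField.identity(pair.time1)
        np.testing.assert_allclose(jacobian_det_map(field), 1.0, atol=1e-12)

    def test_uniform_scale(self, pair):
        A = 1.1 * np.eye(3)
        field = _affine_field(pair.time1, A, center=(10.0, 5.0, -3.0))
        np.testing.assert_allclose(jacobian_det_map(field), 1.1**3, atol=1e-6)
        np.testing.assert_allclose(volume_ratio_map(field), 1.1**-3, atol=1e-6)

    def test_anisotropic_scale(self, pair):
        A = np.diag([1.2, 1.0, 0.9])
        field = _affine_field(pair.time1, A)
        np.testing.assert_allclose(jacobian_det_map(field), 1.08, atol=1e-6)

    def test_composition_multiplies_determinants(self, pair, rng):
        A = np.eye(3) + rng.normal(0, 0.05, (3, 3))
        B = np.eye(3) + rng.normal(0, 0.05, (3, 3))
        fA = _affine_field(pair.time1, A)
        fAB = _affine_field(pair.time1, A @ B)
        detA = jacobian_det_map(fA)[2, 2, 2]
        detAB = jacobian_det_map(fAB)[2, 2, 2]
        assert detAB == pytest.approx(detA * np.linalg.det(B), rel=1e-6)


class TestWarp:
    def test_identity_warp_is_exact_at_grid_points(self, pair):
        field = DeformationField.identity(pair.time0)
        warped = warp_image(pair.time0, field)
        np.testing.assert_allclose(warped.data, pair.time0.data, atol=1e-10)

    def test_translation_by_one_voxel(self, pair):
        sp = pair.time0.spacing
        u = np.zeros(pair.time0.shape + (3,))
        u[..., 0] = sp[0]
        field = DeformationField(u, sp)
        warped = warp_image(pair.time0, field)
        np.testing.assert_allclose(
            warped.data[:-1], pair.time0.data[1:], atol=1e-10
        )

    def test_true_warp_restores_reference(self, small_hyper_pair):
        """Warping Time 0 by the generator's field reproduces Time 1 (noise apart)."""
        p = small_hyper_pair
        warped = warp_image(p.time0, p.true_field)
        lung = p.time1_mask.lung
        r = np.corrcoef(warped.data[lung], p.time1.data[lung])[0, 1]
        assert r > 0.9  # both carry independent 20 HU noise


class TestRegister:
    def test_self_registration_recovers_identity(self, pair):
        cfg = RegistrationConfig(downsample=(2, 1), max_iter=40)
        res = register(pair.time1, pair.time1, pair.time1_mask, config=cfg)
        assert np.abs(res.field.displacement).max() < 0.5 * min(pair.time1.spacing)
        assert res.negative_jacobian_fraction == 0.0

    def test_cost_history_non_increasing(self, small_hyper_pair):
        p = small_hyper_pair
        cfg = RegistrationConfig(downsample=(2, 1), max_iter=30)
        res = register(p.time1, p.time0, p.time1_mask, p.time0_mask, cfg)
        hist = res.cost_dataframe()
        for _, level in hist.groupby("level"):
            e = level["E"].to_numpy()
            assert np.all(np.diff(e) <= 1e-9 * e[0])
        # cost must drop substantially from the identity start
        e_level0 = hist[hist["level"] == 0]["E"].to_numpy()
        assert res.cost_history[-1][2] <= e_level0[0]

    def test_harder_deformation_needs_more_iterations(self):
        """A focal-expansion pair takes more optimizer work than a near-identity
        pair but still converges — mirroring cost-convergence behavior on
        metastatic vs pre-metastatic scan pairs."""
        mild = generate(PhantomSpec(shape=(32, 32, 32), spacing=(2.5,) * 3, seed=21))
        hard = generate(
            PhantomSpec(
                shape=(32, 32, 32), spacing=(2.5,) * 3, seed=21,
                hyper_region=HyperRegion(radius=18.0, target_delta_star=0.8),
            )
        )
        cfg = RegistrationConfig(downsample=(2, 1), max_iter=150)
        res_mild = register(mild.time1, mild.time0, mild.time1_mask,
                            mild.time0_mask, cfg)
        res_hard = register(hard.time1, hard.time0, hard.time1_mask,
                            hard.time0_mask, cfg)
        assert res_hard.iterations > res_mild.iterations
        assert res_hard.cost_history[-1][2] < res_hard.cost_history[0][2]

    def test_affine_scale_recovery(self):
        """A 5% uniform inflation is recovered to subvoxel accuracy in the
        lung interior."""
        import scipy.ndimage as ndi

        p = generate(
            PhantomSpec(shape=(32, 32, 32), spacing=(2.5,) * 3, seed=9,
                        deformation="affine", affine_scale=1.05)
        )
        cfg = RegistrationConfig(downsample=(2, 1), max_iter=150)
        res = register(p.time1, p.time0, p.time1_mask, p.time0_mask, cfg)
        interior = ndi.binary_erosion(p.time1_mask.lung, iterations=2)
        err = res.field.displacement[interior] - p.true_field.displacement[interior]
        rms = np.sqrt((err**2).mean())
        assert rms < min(p.time1.spacing)  # < 1 voxel RMS


def test_mass_conservation_under_recovered_warp(small_hyper_pair):
    """Total floating tissue volume sampled through the warp stays within 2%
    of the floating lung's tissue volume (tissue mass is preserved)."""
    from lungmech.density import decompose, global_volumes, tissue_fraction

    p = small_hyper_pair
    cfg = RegistrationConfig(downsample=(2, 1), max_iter=150)
    res = register(p.time1, p.time0, p.time1_mask, p.time0_mask, cfg)
    det = jacobian_det_map(res.field)
    warped = warp_image(p.time0, res.field)
    lung_r = p.time1_mask.lung
    v_r = p.time1.voxel_volume
    tis_through_warp = float(
        (v_r * det[lung_r] * tissue_fraction(warped.data[lung_r])).sum()
    )
    tis_floating = global_volumes(decompose(p.time0, p.time0_mask)).V_tissue
    assert tis_through_warp == pytest.approx(tis_floating, rel=0.02)
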