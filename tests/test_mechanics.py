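import numpy as np
import pytest

from lungmech import (
    RegistrationConfig,
    compute_maps,
    delta_air_star_map,
    delta_star_map,
    delta_tissue_star_map,
    expansion_summary,
    run_pair,
)
from lungmech.mechanics import MechanicsMaps
from lungmech.phantom import PhantomSpec, TissueLesion, generate


class TestDeltaStar:
    def test_fifty_percent_contribution_increase(self):
        """A region whose local-to-global contribution grew 50% has delta* = 0.5."""
        assert delta_star_map(np.array([1.5]), 1.0, 1.0)[0] == pytest.approx(0.5)
        assert delta_star_map(np.array([1.2]), 1.25, 1.0)[0] == pytest.approx(0.5)

    def test_no_change(self):
        assert delta_star_map(np.array([1.0]), 2000.0, 2000.0)[0] == pytest.approx(0.0)

    def test_uniform_inflation_gives_zero(self):
        # J constant at Vr/Vf cancels the global normalization exactly
        Vr, Vf = 1300.0, 1000.0
        J = np.full((4, 4), Vr / Vf)
        np.testing.assert_allclose(delta_star_map(J, Vf, Vr), 0.0, atol=1e-12)

    def test_nonpositive_volumes_rejected(self):
        with pytest.raises(ValueError):
            delta_star_map(np.ones(3), 0.0, 1.0)


class TestDeltaComponents:
    def test_trivial_zero(self):
        assert delta_air_star_map(np.array([2.0]), np.array([2.0]), 5.0, 5.0)[
            0
        ] == pytest.approx(0.0)

    def test_doubled_air(self):
        assert delta_air_star_map(np.array([2.0]), np.array([1.0]), 7.0, 7.0)[
            0
        ] == pytest.approx(1.0)

    def test_tissue_gain(self):
        assert delta_tissue_star_map(np.array([1.5]), np.array([1.0]), 3.0, 3.0)[
            0
        ] == pytest.approx(0.5)

    def test_vanishing_denominator_masked(self):
        out = delta_air_star_map(np.array([1.0, 1.0]), np.array([0.0, 1.0]), 1.0, 1.0)
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.0)

    def test_additive_identity_on_random_fields(self, rng):
        """(1+d*) v_f = (1+d_air*) v_air_f + (1+d_tis*) v_tis_f exactly."""
        n = 500
        Vf, Vr = 900.0, 1100.0
        v_r = 2.0
        J = rng.uniform(0.6, 1.8, n)
        v_f = v_r / J
        frac_r = rng.uniform(0.05, 0.95, n)
        frac_f = rng.uniform(0.05, 0.95, n)
        d = delta_star_map(J, Vf, Vr)
        d_air = delta_air_star_map(v_r * (1 - frac_r), v_f * (1 - frac_f), Vf, Vr)
        d_tis = delta_tissue_star_map(v_r * frac_r, v_f * frac_f, Vf, Vr)
        lhs = (1 + d) * v_f
        rhs = (1 + d_air) * v_f * (1 - frac_f) + (1 + d_tis) * v_f * frac_f
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


def _maps_from_delta(delta, delta_tis=None):
    shape = delta.shape
    domain = np.ones(shape, dtype=bool)
    z = np.zeros(shape)
    return MechanicsMaps(
        J=np.ones(shape), delta_star=delta,
        delta_air_star=z,
        delta_tissue_star=delta if delta_tis is None else delta_tis,
        Vr=1.0, Vf=1.0, domain=domain,
    )


class TestExpansionSummary:
    def test_counting(self):
        delta = np.zeros((10, 10, 10))
        delta.reshape(-1)[:100] = 0.6  # exactly 10% of voxels
        s = expansion_summary(_maps_from_delta(delta))
        assert s.pct_hyper_at_50 == pytest.approx(10.0)
        assert all(s.pair_hyperinflated.values())

    def test_all_zero(self):
        s = expansion_summary(_maps_from_delta(np.zeros((6, 6, 6))))
        assert all(v == 0.0 for v in s.pct_lung_hyper.values())
        assert not any(s.pair_hyperinflated.values())

    def test_threshold_monotonicity(self, rng):
        delta = rng.normal(0.3, 0.5, size=(12, 12, 12))
        s = expansion_summary(_maps_from_delta(delta), thresholds=(0.1, 0.2, 0.5, 1.0))
        pct = [s.pct_lung_hyper[t] for t in sorted(s.pct_lung_hyper)]
        assert all(a >= b for a, b in zip(pct, pct[1:]))
        flags = [s.pair_hyperinflated[c] for c in sorted(s.pair_hyperinflated)]
        assert all(a >= b for a, b in zip(flags, flags[1:]))


class TestComputeMaps:
    def test_additive_identity_with_true_field(self, small_hyper_pair):
        """The geometric/air/tissue decomposition identity holds to 1e-9
        relative on a full computed pair."""
        p = small_hyper_pair
        maps = compute_maps(p.time1, p.time1_mask, p.time0, p.time0_mask,
                            p.true_field)
        J = maps.J
        ok = (
            np.isfinite(maps.delta_star)
            & np.isfinite(maps.delta_air_star)
            & np.isfinite(maps.delta_tissue_star)
        )
        v_r = p.time1.voxel_volume
        v_f = v_r / J[ok]
        from lungmech.density import tissue_fraction
        from lungmech.register import warp_image

        frac_f = np.clip(tissue_fraction(warp_image(p.time0, p.true_field).data), 0, 1)[ok]
        lhs = (1 + maps.delta_star[ok]) * v_f
        rhs = (1 + maps.delta_air_star[ok]) * v_f * (1 - frac_f) + (
            1 + maps.delta_tissue_star[ok]
        ) * v_f * frac_f
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)

    def test_true_field_reproduces_true_delta(self, small_hyper_pair):
        """Maps computed from the generator's exact field track its ground
        truth (interpolation and noise are the only error sources)."""
        import scipy.ndimage as ndi

        p = small_hyper_pair
        maps = compute_maps(p.time1, p.time1_mask, p.time0, p.time0_mask,
                            p.true_field)
        interior = ndi.binary_erosion(p.time1_mask.lung, iterations=2)
        ok = interior & np.isfinite(maps.delta_star) & np.isfinite(p.true_delta_star)
        r = np.corrcoef(maps.delta_star[ok], p.true_delta_star[ok])[0, 1]
        assert r > 0.95

    def test_volume_weighted_consistency(self, small_hyper_pair):
        """sum(v/J) over the reference lung approximates the floating lung
        volume (global consistency of the ratio map)."""
        p = small_hyper_pair
        maps = compute_maps(p.time1, p.time1_mask, p.time0, p.time0_mask,
                            p.true_field)
        lung = p.time1_mask.lung & np.isfinite(maps.J)
        v = p.time1.voxel_volume
        vf_implied = float((v / maps.J[lung]).sum())
        assert vf_implied == pytest.approx(p.Vf, rel=0.02)


def test_run_pair_identity_phantom(small_identity_pair):
    """Identical-geometry pair: essentially no hyper-expanded lung."""
    p = small_identity_pair
    cfg = RegistrationConfig(downsample=(2, 1), max_iter=60)
    maps, summary, res = run_pair(p.time1, p.time1_mask, p.time0, p.time0_mask, cfg)
    assert summary.pct_hyper_at_50 < 0.1


def test_run_pair_inverse_consistency(small_hyper_pair):
    """Swapping the roles of the scans approximately inverts the delta* map:
    (1 + d_fwd(x)) * (1 + d_rev(T(x))) is near 1 in the lung interior."""
    import scipy.ndimage as ndi

    from lungmech._ffd import trilinear

    p = small_hyper_pair
    cfg = RegistrationConfig(downsample=(2, 1), max_iter=150)
    maps_f, _, res_f = run_pair(p.time1, p.time1_mask, p.time0, p.time0_mask, cfg)
    maps_r, _, _ = run_pair(p.time0, p.time0_mask, p.time1, p.time1_mask, cfg)

    interior = ndi.binary_erosion(p.time1_mask.lung, iterations=3)
    idx = np.argwhere(interior)
    X = idx * np.asarray(p.time1.spacing)
    target = (X + res_f.field.displacement[interior]) / np.asarray(p.time0.spacing)
    d_rev_at_T, _, inside = trilinear(np.nan_to_num(maps_r.delta_star), target)
    d_fwd = maps_f.delta_star[interior]
    ok = inside & np.isfinite(d_fwd)
    product = (1 + d_fwd[ok]) * (1 + d_rev_at_T[ok])
    assert abs(np.median(product) - 1.0) < 0.1


def test_delta_tissue_lesion_signal():
    """An implanted tissue-gain sphere shows up in the true tissue map:
    inside above 0.5, background near 0."""
    spec = PhantomSpec(
        shape=(32, 32, 32), spacing=(2.5,) * 3, seed=13,
        tissue_lesion=TissueLesion(radius=12.0, multiplier=1.6),
    )
    p = generate(spec)
    lung = p.time1_mask.lung
    inside = lung & (p.true_delta_tissue_star > 0.5)
    assert inside.sum() > 0
    background = lung & np.isclose(p.true_delta_tissue_star, p.Vf / p.Vr - 1, atol=1e-6)
    assert background.sum() > 0.5 * lung.sum()
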