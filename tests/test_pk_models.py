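import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcepk import fit_model, fit_voxels, forward_model
from dcepk.aif import PlasmaCurve
from dcepk.pk_models import exp_conv


@pytest.fixture(scope="module")
def flat_cp():
    # constant unit plasma level over 10 min, 4 s sampling
    t = np.arange(0.0, 601.0, 4.0)
    return PlasmaCurve(time_s=t, cp_mM=np.ones_like(t))


class TestForwardModel:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_zero_plasma_curve_gives_zero_tissue(self, order, spec):
        t = spec.time_grid_s
        aif0 = PlasmaCurve(time_s=t, cp_mM=np.zeros_like(t))
        kwargs = dict(vp=0.05, ktrans=0.02)
        if order == 3:
            kwargs["kep"] = 0.5
        ct = forward_model(order, aif0, **kwargs)
        np.testing.assert_array_equal(ct, 0.0)

    def test_patlak_integral_closed_form(self, flat_cp):
        # vp = 0, Ktrans = 0.01/min, Cp = 1 mM for 10 min -> Ct(10 min) = 0.1 mM
        ct = forward_model(2, flat_cp, vp=0.0, ktrans=0.01, arrival_idx=0)
        assert ct[-1] == pytest.approx(0.1, rel=1e-12)

    def test_backflux_model_reduces_to_patlak_at_small_kep(self, aif):
        ct2 = forward_model(2, aif, vp=0.03, ktrans=0.02)
        ct3 = forward_model(3, aif, vp=0.03, ktrans=0.02, kep=1e-12)
        np.testing.assert_allclose(ct3, ct2, atol=1e-9)

    def test_causality(self, aif, spec):
        ct = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
        assert np.all(ct[: spec.bolus_frame - 1] == 0.0)

    def test_invalid_order_and_kep_rejected(self, aif):
        with pytest.raises(ValueError):
            forward_model(4, aif, vp=0.1)
        with pytest.raises(ValueError):
            forward_model(3, aif, vp=0.1, ktrans=0.01, kep=0.0)
        with pytest.raises(ValueError):
            forward_model(1, aif, vp=-0.1)


class TestExpConv:
    def test_matches_quadrature_oracle(self, aif):
        # dense-grid Riemann evaluation of the convolution integral
        from dcepk.pk_models import _windowed_aif

        t, cp, _ = _windowed_aif(aif)
        kep = 0.7
        ours = exp_conv(cp, t, kep)
        for idx in (30, 80, len(t) - 1):
            fine = np.linspace(t[0], t[idx], 100_001)
            cp_fine = np.interp(fine, t, cp)
            oracle = np.trapezoid(cp_fine * np.exp(-kep * (t[idx] - fine)), fine)
            assert ours[idx] == pytest.approx(oracle, rel=1e-6)

    def test_zero_rate_equals_cumulative_trapezoid(self, aif):
        from scipy.integrate import cumulative_trapezoid

        from dcepk.pk_models import _windowed_aif

        t, cp, _ = _windowed_aif(aif)
        np.testing.assert_allclose(
            exp_conv(cp, t, 0.0),
            cumulative_trapezoid(cp, t, initial=0.0),
            atol=1e-12,
        )


class TestFitModel:
    def test_pure_vascular_voxel_exact(self, aif):
        ct = 0.03 * aif.cp_mM
        res = fit_model(1, ct, aif)
        assert res.vp1 == pytest.approx(0.03, rel=1e-12)
        assert res.sse1 < 1e-20

    def test_patlak_recovery_matches_normal_equations_oracle(self, aif):
        from scipy.integrate import cumulative_trapezoid

        from dcepk.pk_models import _windowed_aif

        vp, kt = 0.03, 0.015
        ct = forward_model(2, aif, vp=vp, ktrans=kt)
        res = fit_model(2, ct, aif)
        assert res.vp2 == pytest.approx(vp, rel=1e-8)
        assert res.ktrans2 == pytest.approx(kt, rel=1e-8)
        # independent linear-algebra route: explicit design matrix + lstsq
        t, cp, i0 = _windowed_aif(aif)
        X = np.column_stack([cp, cumulative_trapezoid(cp, t, initial=0.0)])
        beta, *_ = np.linalg.lstsq(X, ct[i0:], rcond=None)
        assert res.vp2 == pytest.approx(beta[0], rel=1e-9)
        assert res.ktrans2 == pytest.approx(beta[1], rel=1e-9)

    def test_backflux_recovery_over_parameter_grid(self, aif):
        # 27 noiseless ground-truth triples recovered to < 1e-4 relative
        vps = [0.01, 0.02, 0.04]
        kts = [0.01, 0.03, 0.06]
        keps = [0.15, 0.3, 0.6]
        triples = list(itertools.product(vps, kts, keps))
        ct = np.stack([forward_model(3, aif, vp=v, ktrans=k, kep=e) for v, k, e in triples])
        fit = fit_voxels(ct, aif)
        truth = np.array(triples)
        np.testing.assert_allclose(fit.vp3, truth[:, 0], rtol=1e-4)
        np.testing.assert_allclose(fit.ktrans3, truth[:, 1], rtol=1e-4)
        np.testing.assert_allclose(fit.kep3, truth[:, 2], rtol=1e-4)

    def test_sse_nesting_on_noisy_voxels(self, aif):
        rng = np.random.default_rng(3)
        base = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
        ct = base[None, :] + rng.normal(0, 0.01, (300, base.size))
        fit = fit_voxels(ct, aif)
        assert np.all(fit.sse1 >= fit.sse2 - 1e-12)
        assert np.all(fit.sse2 >= fit.sse3 - 1e-12)

    def test_ve_identity_exact(self, aif):
        ct = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
        fit = fit_voxels(ct[None, :], aif)
        np.testing.assert_array_equal(fit.ve3, fit.ktrans3 / fit.kep3)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_rescaling_cp_and_ct_together_leaves_parameters(self, aif, scale):
        ct = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
        scaled_aif = PlasmaCurve(time_s=aif.time_s, cp_mM=aif.cp_mM * scale)
        a = fit_voxels(ct[None, :], aif)
        b = fit_voxels((ct * scale)[None, :], scaled_aif)
        assert b.vp3[0] == pytest.approx(a.vp3[0], rel=1e-6)
        assert b.ktrans3[0] == pytest.approx(a.ktrans3[0], rel=1e-6)
        assert b.kep3[0] == pytest.approx(a.kep3[0], rel=1e-6)

    def test_uniform_weights_match_unweighted_fit(self, aif):
        rng = np.random.default_rng(8)
        ct = forward_model(3, aif, vp=0.02, ktrans=0.02, kep=0.4)
        ct = (ct + rng.normal(0, 0.005, ct.size))[None, :]
        a = fit_voxels(ct, aif)
        b = fit_voxels(ct, aif, weights=np.full(len(aif), 2.5))
        assert b.vp3[0] == pytest.approx(a.vp3[0], rel=1e-6)
        assert b.ktrans3[0] == pytest.approx(a.ktrans3[0], rel=1e-6)
        assert b.kep3[0] == pytest.approx(a.kep3[0], rel=1e-6)

    def test_flat_plasma_curve_flags_unfittable(self):
        t = np.arange(0.0, 600.0, 4.0)
        aif0 = PlasmaCurve(time_s=t, cp_mM=np.zeros_like(t))
        fit = fit_voxels(np.ones((2, t.size)), aif0)
        assert not fit.fittable.any()

    def test_misaligned_grids_rejected(self, aif):
        with pytest.raises(ValueError):
            fit_voxels(np.ones((1, 10)), aif)

    def test_reported_parameters_stay_nonnegative(self, aif):
        rng = np.random.default_rng(11)
        ct = rng.normal(0, 0.01, (200, len(aif)))  # pure noise
        fit = fit_voxels(ct, aif)
        assert np.all(fit.vp2 >= 0) and np.all(fit.ktrans2 >= 0)
        assert np.all(fit.vp3 >= 0) and np.all(fit.ktrans3 >= 0) and np.all(fit.kep3 >= 0)

    def test_parameter_bias_small_at_snr30_through_signal_chain(self, spec, aif):
        # 300 identical backflux voxels through the Rician signal chain
        from conftest import truth_from_params
        from dcepk.pipeline import analyze_study
        from dcepk.synthetic import noise_sd_for_snr, synthesize_signals

        truth = truth_from_params(np.full(300, 0.025), 0.03, 0.3)
        sd = noise_sd_for_snr(truth, spec, 30.0)
        study = synthesize_signals(truth, aif, spec, sd, np.random.default_rng(5))
        a = analyze_study(study)
        sel = a.maps["model3_mask"]
        assert sel.mean() > 0.9
        kt_bias = np.nanmedian(a.maps["ktrans"][sel]) / 0.03 - 1
        kep_bias = np.nanmedian(a.maps["kep"][sel]) / 0.3 - 1
        assert abs(kt_bias) < 0.05
        assert abs(kep_bias) < 0.10
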