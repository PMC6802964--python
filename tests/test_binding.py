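"""Sequential two-site binding, depletion, pCa fits, Forster conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endotrace import binding
from endotrace.binding import (
    CaTitrationModel,
    ForsterPair,
    SequentialBindingModel,
    distance_to_efficiency,
    efficiency_to_distance,
    free_ligand,
    occupancy,
    predict_signal,
)


def brute_force_free_ligand(total, model, tol=1e-12):
    """Independent bisection oracle: scans the mass balance directly."""
    lo, hi = 0.0, total
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f1, f2 = occupancy(mid, model)
        bound = model.reporter_total * ((f1 - f2) + 2 * f2)
        if mid + bound > total:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@pytest.fixture
def cam1_model():
    return SequentialBindingModel(K1=0.1, K2=0.68, dF1=23.0, dF2=23.0, F0=10.0, reporter_total=0.5)


class TestOccupancy:
    def test_zero_ligand(self, cam1_model):
        assert occupancy(0.0, cam1_model) == (0.0, 0.0)

    def test_saturation(self, cam1_model):
        f1, f2 = occupancy(1e9, cam1_model)
        assert f1 == pytest.approx(1.0, abs=1e-6)
        assert f2 == pytest.approx(1.0, abs=1e-6)

    def test_single_site_half_saturation(self):
        m = SequentialBindingModel(K1=0.5, K2=1e12, dF1=1.0, dF2=0.0, F0=0.0, reporter_total=0.1)
        f1, f2 = occupancy(0.5, m)
        assert f1 == pytest.approx(0.5, abs=1e-6)
        assert f2 == pytest.approx(0.0, abs=1e-6)

    @given(st.floats(0.0, 100.0), st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_ordering_and_bounds(self, ligand, k1, k2):
        m = SequentialBindingModel(K1=k1, K2=k2, dF1=1.0, dF2=1.0, F0=0.0, reporter_total=0.5)
        f1, f2 = occupancy(ligand, m)
        assert 0.0 <= f2 <= f1 <= 1.0

    def test_monotone_in_ligand(self, cam1_model):
        grid = np.linspace(0, 20, 400)
        f1, f2 = occupancy(grid, cam1_model)
        assert np.all(np.diff(f1) >= -1e-12)
        assert np.all(np.diff(f2) >= -1e-12)


class TestFreeLigand:
    def test_zero_total(self, cam1_model):
        assert free_ligand(0.0, cam1_model) == 0.0

    def test_no_binding_limit(self):
        m = SequentialBindingModel(K1=1e6, K2=1e6, dF1=1.0, dF2=1.0, F0=0.0, reporter_total=0.5)
        assert free_ligand(3.0, m) == pytest.approx(3.0, rel=1e-6)

    def test_matches_brute_force_oracle(self):
        m = SequentialBindingModel(K1=0.1, K2=0.68, dF1=1.0, dF2=1.0, F0=0.0, reporter_total=0.5)
        assert free_ligand(1.0, m) == pytest.approx(brute_force_free_ligand(1.0, m), abs=1e-8)

    def test_oracle_agreement_over_grid(self):
        k1s = [0.02, 0.1, 0.68, 5.0]
        k2s = [0.1, 0.68, 1.1, 10.0]
        totals = [0.05, 0.5, 1.0, 2.5, 10.0]
        for k1 in k1s:
            for k2 in k2s:
                for total in totals:
                    m = SequentialBindingModel(K1=k1, K2=k2, dF1=1, dF2=1, F0=0, reporter_total=0.5)
                    assert free_ligand(total, m) == pytest.approx(
                        brute_force_free_ligand(total, m), abs=1e-8
                    )

    def test_mass_conservation(self, cam1_model):
        total = 1.7
        L = free_ligand(total, cam1_model)
        f1, f2 = occupancy(L, cam1_model)
        bound = cam1_model.reporter_total * ((f1 - f2) + 2 * f2)
        assert L + bound == pytest.approx(total, rel=1e-9)


class TestPredictSignal:
    def test_zero_amplitudes_constant(self):
        m = SequentialBindingModel(K1=0.1, K2=0.68, dF1=0.0, dF2=0.0, F0=7.0, reporter_total=0.5)
        np.testing.assert_allclose(predict_signal([0.0, 1.0, 10.0], m), 7.0)

    def test_saturation_sums_amplitudes(self, cam1_model):
        val = predict_signal([1e5], cam1_model)[0]
        assert val == pytest.approx(cam1_model.F0 + cam1_model.dF1 + cam1_model.dF2, rel=1e-4)

    def test_half_change_between_k1_and_k2(self, cam1_model):
        # with equal amplitudes the midpoint of the total change falls
        # between the two step constants (in free-ligand terms)
        conc = np.linspace(0.0, 50.0, 2000)
        y = predict_signal(conc, cam1_model)
        half = cam1_model.F0 + 0.5 * (cam1_model.dF1 + cam1_model.dF2)
        c_half = conc[np.argmin(np.abs(y - half))]
        L_half = free_ligand(c_half, cam1_model)
        assert cam1_model.K1 / 3 < L_half < cam1_model.K2 * 3

    def test_no_depletion_limit(self):
        # reporter << K1: depletion-corrected curve matches the closed form
        m = SequentialBindingModel(K1=1.0, K2=5.0, dF1=10.0, dF2=10.0, F0=0.0, reporter_total=0.01)
        conc = np.linspace(0.01, 20, 40)
        f1, f2 = occupancy(conc, m)  # free == total in this limit
        np.testing.assert_allclose(predict_signal(conc, m), m.dF1 * f1 + m.dF2 * f2, rtol=0.01)


class TestFitTitration:
    def test_noiseless_one_site_exact(self):
        m = SequentialBindingModel(K1=1.2, K2=np.inf, dF1=30.0, dF2=0.0, F0=5.0, reporter_total=0.1)
        conc = np.array([0, 0.2, 0.5, 1.0, 1.5, 2.5, 4.0, 7.0, 12.0, 20.0])
        y = predict_signal(conc, m)
        fit = binding.fit_titration(conc, y, reporter_total=0.1, model_spec="one_site", seed=0, multistart=8)
        assert fit.model.K1 == pytest.approx(1.2, rel=1e-4)
        assert fit.model.dF1 == pytest.approx(30.0, rel=1e-4)

    def test_noiseless_two_site_recovery(self):
        m = SequentialBindingModel(K1=0.05, K2=0.68, dF1=23.0, dF2=23.0, F0=10.0, reporter_total=0.5)
        conc = np.array([0, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0])
        y = predict_signal(conc, m)
        fit = binding.fit_titration(conc, y, reporter_total=0.5, seed=1, multistart=24)
        assert fit.model.K2 == pytest.approx(0.68, rel=1e-3)
        assert fit.k1_is_upper_bound  # K1 tighter than reporter/5
        assert "K1 <" in fit.K1_report

    def test_affine_signal_rescaling_leaves_kds(self):
        m = SequentialBindingModel(K1=0.05, K2=0.68, dF1=23.0, dF2=23.0, F0=10.0, reporter_total=0.5)
        conc = np.array([0, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0])
        y = predict_signal(conc, m)
        f1 = binding.fit_titration(conc, y, reporter_total=0.5, seed=2, multistart=12)
        f2 = binding.fit_titration(conc, 3.0 * y + 40.0, reporter_total=0.5, seed=2, multistart=12)
        assert f2.model.K2 == pytest.approx(f1.model.K2, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            binding.fit_titration(np.arange(5.0), np.arange(5.0), reporter_total=0.5)


class TestFitPca:
    def test_noiseless_hill_exact(self):
        m = CaTitrationModel(pCa50=5.87, hill_n=2.0, Ymax=100.0, Ymin=20.0)
        pca = np.linspace(4.5, 7.5, 10)
        fit = binding.fit_pca(pca, m.predict(pca))
        assert fit.model.pCa50 == pytest.approx(5.87, abs=1e-5)
        assert fit.model.hill_n == pytest.approx(2.0, rel=1e-4)

    def test_falling_direction_inferred(self):
        m = CaTitrationModel(pCa50=6.12, hill_n=1.5, Ymax=10.0, Ymin=90.0)
        pca = np.linspace(4.5, 7.5, 12)
        fit = binding.fit_pca(pca, m.predict(pca))
        assert fit.model.pCa50 == pytest.approx(6.12, abs=1e-4)
        assert fit.model.Ymax < fit.model.Ymin

    def test_non_bracketing_data_rejected(self):
        m = CaTitrationModel(pCa50=5.87, hill_n=2.0, Ymax=100.0, Ymin=20.0)
        pca = np.linspace(7.0, 8.5, 8)  # entirely above the midpoint
        with pytest.raises(ValueError):
            binding.fit_pca(pca, m.predict(pca))

    def test_fixed_hill_coefficient_misfit_detectable(self, rng):
        # data generated with n=2 but fitted with n fixed to 1 leave
        # structured residuals (sign runs), unlike the free fit
        m = CaTitrationModel(pCa50=5.87, hill_n=2.0, Ymax=100.0, Ymin=20.0)
        pca = np.linspace(4.5, 7.5, 16)
        y = m.predict(pca) * (1 + rng.normal(0, 0.005, 16))
        fixed = binding.fit_pca(pca, y, hill_n=1.0)
        free = binding.fit_pca(pca, y)
        assert fixed.chisqr > 5.0 * free.chisqr


class TestForster:
    def test_half_efficiency_is_r0(self):
        pair = ForsterPair(R0=5.301)
        assert efficiency_to_distance(0.5, pair) == pytest.approx(5.301)

    def test_neck_length_efficiency(self):
        # 4.6 nm with the CyPet-YPet R0 of 5.301 nm
        e = distance_to_efficiency(4.6, ForsterPair(R0=5.301))
        assert e == pytest.approx(0.701, abs=0.002)

    @given(st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, e):
        pair = ForsterPair(R0=5.301)
        assert distance_to_efficiency(efficiency_to_distance(e, pair), pair) == pytest.approx(e, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            efficiency_to_distance(bad)
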