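"""Parameter-estimation tests: exact recovery on noiseless data, failure modes."""
import numpy as np
import pytest

import httime as ht
from httime.timecourse import FitFailureError

from conftest import hydro_curves


def step_curve(T, tg_h, psi=0.0, n=10):
    """Dish whose interpolated tg(50) is exactly ``tg_h`` (linear 0->n ramp)."""
    t1, t2 = (tg_h - 12.0) / 24.0, (tg_h + 12.0) / 24.0
    return ht.GerminationTimeCourse(
        temperature=T, water_potential=psi,
        times=(t1, t2), cumulative_counts=(0, n), n_seeds=n,
    )


class TestThermalFit:
    def test_exact_suboptimal_line(self):
        Tb, theta1 = 6.8, 300.0
        curves = [step_curve(T, theta1 / (T - Tb)) for T in (10, 15, 20)]
        with pytest.warns(UserWarning, match="supra"):
            params, diag = ht.fit_thermal(curves)
        assert params.Tb == pytest.approx(Tb, rel=1e-6)
        assert params.thetaT1 == pytest.approx(theta1, rel=1e-6)
        assert diag.r_squared == pytest.approx(1.0)

    def test_exact_two_branch_cardinals(self):
        Tb, Tc, To = 10.0, 45.0, 20.0
        theta1, theta2 = 300.0, 750.0  # chosen so branches meet at To
        def gr(T):
            return min((T - Tb) / theta1, (Tc - T) / theta2)
        curves = [step_curve(T, 1.0 / gr(T)) for T in (12, 16, 20, 28, 36)]
        params, _ = ht.fit_thermal(curves)
        assert params.Tb == pytest.approx(Tb, rel=1e-9)
        assert params.Tc == pytest.approx(Tc, rel=1e-9)
        assert params.To == pytest.approx(To, rel=1e-9)
        assert params.thetaT1 == pytest.approx(theta1, rel=1e-9)
        assert params.thetaT2 == pytest.approx(theta2, rel=1e-9)

    def test_single_temperature_fails(self):
        with pytest.raises(FitFailureError):
            ht.fit_thermal([step_curve(20, 30.0)])


class TestHydrotimeProbitFit:
    def test_recovers_known_parameters(self):
        params, diag = ht.fit_hydrotime_probit(
            hydro_curves(thetaH=56.43, psib50=-0.87, sigma=0.20)
        )
        assert params.thetaH == pytest.approx(56.43, rel=0.01)
        assert params.psib50 == pytest.approx(-0.87, rel=0.01)
        assert params.sigma_psib == pytest.approx(0.20, rel=0.01)
        assert diag.r_squared >= 0.999

    def test_no_psi_signal_fails(self, make_tc):
        curves = [make_tc((5, 5, 5), psi=psi) for psi in (0.0, -0.3, -0.6)]
        with pytest.raises(FitFailureError):
            ht.fit_hydrotime_probit(curves)

    def test_saturated_fractions_fail(self, make_tc):
        curves = [make_tc((10, 10, 10), psi=psi) for psi in (0.0, -0.3, -0.6)]
        with pytest.raises(FitFailureError, match="probit-transformable"):
            ht.fit_hydrotime_probit(curves)

    def test_needs_three_water_potentials(self, make_tc):
        curves = [make_tc((2, 5, 8), psi=psi) for psi in (0.0, -0.3)]
        with pytest.raises(FitFailureError, match="water potentials"):
            ht.fit_hydrotime_probit(curves)

    def test_mixed_temperatures_rejected(self, make_tc):
        curves = [make_tc((2, 5, 8), psi=-0.3, T=T) for T in (15.0, 20.0, 25.0)]
        with pytest.raises(FitFailureError, match="single temperature"):
            ht.fit_hydrotime_probit(curves)


class TestHTTFit:
    def test_roundtrip_on_expected_counts(self, noiseless_study):
        courses, truth = noiseless_study
        params, diag = ht.fit_htt(courses)
        assert diag.r_squared >= 0.999
        for name in ("thetaHTT", "Tb", "psib50", "sigma_psib", "kT"):
            assert getattr(params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            ), name
        assert params.To == truth.To
        assert params.thetaH_at_To == pytest.approx(truth.thetaH_at_To, rel=0.01)

    def test_zero_kt_truth_recovered_small(self):
        truth = ht.HTTParams(thetaHTT=600.0, Tb=8.0, psib50=-0.9,
                             sigma_psib=0.18, kT=0.0, To=20.0)
        cfg = ht.SimulationConfig(true_params=truth, noise_mode="none",
                                  n_seeds_per_dish=10_000, n_replicates=1)
        courses, _ = ht.simulate_study(cfg)
        params, _ = ht.fit_htt(courses, To=20.0)
        assert params.kT <= 0.005

    def test_no_supra_temperatures_fixes_kt(self, sunflower_truth):
        cfg = ht.SimulationConfig(
            true_params=sunflower_truth, temperatures=(12.0, 16.0, 20.0),
            noise_mode="none", n_seeds_per_dish=5000, n_replicates=1,
        )
        courses, _ = ht.simulate_study(cfg)
        with pytest.warns(UserWarning, match="kT fixed at 0"):
            params, _ = ht.fit_htt(courses, To=20.0)
        assert params.kT == 0.0

    def test_too_few_temperatures(self, make_tc):
        curves = [make_tc((2, 5, 8), psi=psi) for psi in (0.0, -0.3, -0.6)]
        with pytest.raises(FitFailureError, match="temperatures"):
            ht.fit_htt(curves)


class TestTable1Grid:
    def test_matches_forward_relations(self, make_tc):
        # tg(50) = 27.2 h at 20 degC / 0 MPa reproduces the reference cell
        tg = {(20.0, 0.0): 27.2}
        df = ht.table1_from_tg(tg, Tb=10, Tc=45, psib=-1.5)
        row = df.iloc[0]
        assert row["TTsub_Ch"] == pytest.approx(272.0)
        assert row["TTsupra_Ch"] == pytest.approx(680.0)
        assert row["thetaHTT_MPaCh"] == pytest.approx(408.0)
        assert row["GR_per_h"] == pytest.approx(1 / 27.2)

    def test_undefined_markers_at_base_potential(self):
        df = ht.table1_from_tg({(20.0, -1.5): 30.0}, Tb=10, Tc=45, psib=-1.5)
        assert np.isnan(df.iloc[0]["thetaH_MPah"])
        assert np.isnan(df.iloc[0]["thetaHTT_MPaCh"])
        assert df.iloc[0]["TTsub_Ch"] == pytest.approx(300.0)

    def test_from_curves_one_cell(self, make_tc):
        tc = make_tc((0, 10), times=(1, 2), T=20.0, psi=0.0)  # tg50 = 36 h
        df = ht.table1_grid([tc], Tb=10, Tc=45, psib=-1.5)
        assert len(df) == 1
        assert df.iloc[0]["tg_h"] == pytest.approx(36.0)
        assert df.iloc[0]["thetaHTT_MPaCh"] == pytest.approx(1.5 * 10 * 36.0)
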