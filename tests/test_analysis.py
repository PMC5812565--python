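"""Ensemble MSD, log-log transform, power-law fitting and diffusivities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import crowddiff as cd
from crowddiff.analysis import (
    FLATNESS_TOL,
    read_msd_table,
    write_msd_table,
)
from crowddiff.engine import Trajectory


def _traj(times, msd, n_tracers=1):
    return Trajectory(np.asarray(times, float), np.asarray(msd, float),
                      n_tracers, "lattice", 1e-3)


def _powerlaw_profile(alpha, d=0.2e-3, n=80):
    t = np.logspace(0, 3, n)  # 1..1000 ms
    return cd.MSDProfile(t, 4 * d * t**alpha, 100, 1)


class TestEnsembleMSD:
    def test_ballistic_accumulator_plumbing(self):
        # a tracer stepping right every step: msd(t) = (t/dt)^2 dl^2
        cfg = cd.LatticeConfig.desk(10)
        fld = cd.build_obstacle_field(cfg, 0, 0)
        pop = cd.place_tracers(cfg, fld, 0.01, False, 1)
        for _ in range(7):
            cd.attempt_hop(0, "right", fld, pop)
        msd_um2 = (pop.disp_rows[0]**2 + pop.disp_cols[0]**2) * cfg.step_length_um**2
        assert msd_um2 == pytest.approx(49 * cfg.step_length_um**2)

    def test_immobile_tracers_give_zero(self):
        prof = cd.ensemble_msd([_traj([1, 2, 3], [0, 0, 0])])
        assert np.all(prof.msd_um2 == 0)

    def test_ensembles_averaged_unweighted(self):
        prof = cd.ensemble_msd([_traj([1, 2], [1.0, 2.0]),
                                _traj([1, 2], [3.0, 4.0])])
        assert np.allclose(prof.msd_um2, [2.0, 3.0])
        assert prof.n_ensembles == 2

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            cd.ensemble_msd([_traj([1, 2], [1, 2]), _traj([1, 3], [1, 2])])


class TestLogLogProfile:
    def test_normal_diffusion_is_flat_at_log4D(self):
        prof = _powerlaw_profile(1.0, d=0.2e-3)
        ll = cd.loglog_profile(prof)
        assert np.allclose(ll["log_msd_over_t"], np.log(4 * 0.2e-3))

    def test_powerlaw_slope_is_alpha_minus_one(self):
        ll = cd.loglog_profile(_powerlaw_profile(0.5))
        slope = np.polyfit(ll["log_t"], ll["log_msd_over_t"], 1)[0]
        assert slope == pytest.approx(-0.5, abs=1e-12)

    def test_plateau_slope_is_minus_one(self):
        t = np.logspace(0, 2, 30)
        ll = cd.loglog_profile(cd.MSDProfile(t, np.full_like(t, 0.3), 10, 1))
        slope = np.polyfit(ll["log_t"], ll["log_msd_over_t"], 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-12)

    def test_zero_entries_dropped_with_warning(self):
        t = np.logspace(0, 2, 20)
        m = 4e-4 * t
        m[0] = 0.0
        with pytest.warns(UserWarning):
            ll = cd.loglog_profile(cd.MSDProfile(t, m, 1, 1))
        assert len(ll) == 19


class TestFitAlpha:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_noiseless_self_inversion(self, alpha):
        char = cd.fit_alpha(cd.loglog_profile(_powerlaw_profile(alpha)))
        assert char.alpha == pytest.approx(alpha, abs=1e-9)
        assert char.d_fit_um2_per_ms == pytest.approx(0.2e-3, rel=1e-9)

    def test_pure_normal_reports_d_eff_equal_d(self):
        char = cd.fit_alpha(cd.loglog_profile(_powerlaw_profile(1.0)))
        assert char.regime == "normal"
        assert char.d_eff_um2_per_ms == pytest.approx(0.2e-3, rel=1e-9)
        assert char.d_eff_nm2_per_us == pytest.approx(0.2, rel=1e-9)

    def test_synaptic_scale_exponent_recovered(self):
        # exponent at the scale reported for receptor tracking inside synapses
        char = cd.fit_alpha(cd.loglog_profile(_powerlaw_profile(0.22)))
        assert char.alpha == pytest.approx(0.22, abs=0.01)

    def test_piecewise_crossover_detected(self):
        # sqrt growth up to 100 ms, then linear: a transition profile
        d = 0.2e-3
        t = np.logspace(0, 3, 120)
        msd = np.where(t <= 100.0, 4 * d * np.sqrt(t), 4 * d * np.sqrt(100.0) / 100.0 * t)
        char = cd.fit_alpha(cd.loglog_profile(cd.MSDProfile(t, msd, 10, 1)))
        assert char.regime == "transition"
        assert char.crossover_time_ms is not None
        # located within about one sliding-window width (0.2 of 3 decades)
        assert 100.0 / 10 ** 0.7 <= char.crossover_time_ms <= 100.0 * 10 ** 0.7

    def test_insufficient_span_rejected(self):
        t = np.linspace(1, 2, 20)
        with pytest.raises(ValueError):
            cd.fit_alpha(cd.loglog_profile(cd.MSDProfile(t, 4e-4 * t, 1, 1)))

    def test_noise_slightly_above_one_reads_normal(self):
        rng = np.random.default_rng(0)
        t = np.logspace(0, 3, 100)
        msd = 4 * 0.2e-3 * t**1.01 * np.exp(rng.normal(0, 0.005, t.size))
        char = cd.fit_alpha(cd.loglog_profile(cd.MSDProfile(t, msd, 1, 1)))
        assert char.alpha == 1.0 and char.regime == "normal"


class TestDiffusivities:
    @pytest.mark.parametrize(
        "alpha, d, t, expected",
        [(1.0, 0.3, 17.0, 0.3), (0.5, 1.0, 4.0, 0.5), (0.0, 2.0, 1000.0, 0.002)],
    )
    def test_apparent_diffusion_values(self, alpha, d, t, expected):
        assert cd.apparent_diffusion(d, alpha, t) == pytest.approx(expected)

    def test_apparent_diffusion_declines_to_zero_for_confined(self):
        vals = [cd.apparent_diffusion(1.0, 0.0, t) for t in (10, 100, 1000)]
        assert vals[0] > vals[1] > vals[2]

    @pytest.mark.parametrize(
        "alpha, d, t, expected",
        [(1.0, 0.3, 5.0, 0.3), (0.0, 1.0, 5.0, 0.0), (0.5, 1.0, 4.0, 0.25)],
    )
    def test_instantaneous_diffusion_values(self, alpha, d, t, expected):
        assert cd.instantaneous_diffusion(d, alpha, t) == pytest.approx(expected)

    @given(
        st.floats(min_value=0.0, max_value=1.05),
        st.floats(min_value=1e-8, max_value=1.0),
        st.floats(min_value=1e-3, max_value=1e4),
    )
    def test_inst_equals_alpha_times_apparent(self, alpha, d, t):
        assert cd.instantaneous_diffusion(d, alpha, t) == pytest.approx(
            alpha * cd.apparent_diffusion(d, alpha, t), rel=1e-12, abs=1e-300
        )

    def test_effective_diffusion_at_two_seconds(self):
        anomalous = cd.DiffusionCharacterization(0.5, 1.0, 0.0, "anomalous")
        assert cd.effective_diffusion(anomalous, 2000.0) == pytest.approx(0.02236, rel=1e-3)
        normal = cd.DiffusionCharacterization(1.0, 0.2e-3, 0.2e-3, "normal")
        assert cd.effective_diffusion(normal) == pytest.approx(0.2e-3)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            cd.apparent_diffusion(1.0, 0.5, 0.0)


class TestPowerlawFitter:
    def test_exact_data_exact_recovery(self):
        t = np.logspace(-1, 2, 50)
        msd = 4 * 0.05 * t**0.7
        for method in ("loglog", "nls"):
            alpha, d, *_ = cd.fit_msd_powerlaw(t, msd, method=method)
            assert alpha == pytest.approx(0.7, abs=1e-7)
            assert d == pytest.approx(0.05, rel=1e-6)

    def test_robust_to_two_percent_noise(self):
        rng = np.random.default_rng(5)
        t = np.logspace(-1, 2, 50)
        msd = 4 * 0.05 * t**0.7 * (1 + rng.normal(0, 0.02, t.size))
        alpha, _, se_alpha, _ = cd.fit_msd_powerlaw(t, msd)
        assert alpha == pytest.approx(0.7, abs=0.05)
        assert se_alpha < 0.05

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            cd.fit_msd_powerlaw([1, 2], [1, 2])
        with pytest.raises(ValueError):
            cd.fit_msd_powerlaw([1, 2, 3], [1, -2, 3])


class TestMSDTableIO:
    def test_round_trip(self, tmp_path):
        prof = _powerlaw_profile(0.5)
        path = tmp_path / "msd.csv"
        write_msd_table(prof, path)
        back = read_msd_table(path)
        assert np.allclose(back.times_ms, prof.times_ms)
        assert np.allclose(back.msd_um2, prof.msd_um2)
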