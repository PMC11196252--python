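"""Synthetic-data generators: determinism, ground-truth recovery and the
finite-difference CV simulator against its closed-form and scaling oracles."""

import numpy as np
import pytest
from scipy import stats

from voltities import (
    SimulationConfig,
    generate_calibration_series,
    generate_interference_series,
    generate_matrix_series,
    generate_partition_data,
    generate_swv_trace,
    simulate_cv_reversible,
)
from voltities.core import RANDLES_SEVCIK_COEFF, GridError
from voltities.peaks import find_peak
from voltities.synth import ITIES_SCAN_RATES_VS


def randles_sevcik_uA(cfg: SimulationConfig) -> float:
    """Closed-form reversible peak current for the donor phase, uA."""
    return (
        RANDLES_SEVCIK_COEFF
        * abs(cfg.charge) ** 1.5
        * cfg.area
        * cfg.bulk_concentration
        * np.sqrt(cfg.D_phase1 * cfg.scan_rate)
        * 1e6
    )


class TestCvSimulator:
    def test_zero_concentration_gives_zero_current(self):
        vg = simulate_cv_reversible(
            SimulationConfig(area=1.0, bulk_concentration=0.0)
        )
        assert np.all(vg.current == 0.0)

    def test_forward_peak_matches_randles_sevcik(self, default_sim):
        cfg = SimulationConfig(area=1.331)
        ip = find_peak(default_sim, "forward").peak_current
        assert ip == pytest.approx(randles_sevcik_uA(cfg), rel=0.02)

    def test_peak_separation_is_reversible(self, default_sim):
        fwd = find_peak(default_sim, "forward")
        bwd = find_peak(default_sim, "backward")
        sep = abs(fwd.peak_potential - bwd.peak_potential)
        assert 0.057 <= sep <= 0.059

    def test_identical_seed_and_config_identical_trace(self):
        cfg = SimulationConfig(area=1.0, noise_sd=0.05, seed=7,
                               n_space=120, n_time=1500)
        a = simulate_cv_reversible(cfg)
        b = simulate_cv_reversible(cfg)
        assert np.array_equal(a.current, b.current)
        c = simulate_cv_reversible(
            SimulationConfig(area=1.0, noise_sd=0.05, seed=8,
                             n_space=120, n_time=1500)
        )
        assert not np.array_equal(a.current, c.current)

    def test_unstable_grid_raises_named_error(self):
        with pytest.raises(GridError, match="diffusion number"):
            simulate_cv_reversible(
                SimulationConfig(area=1.0, n_space=400, n_time=1000)
            )

    def test_ip_scales_with_sqrt_scan_rate(self):
        """log-log slope of Ip vs v is 0.50 +- 0.02 over the study's rates."""
        ips = []
        for v in ITIES_SCAN_RATES_VS:
            cfg = SimulationConfig(area=1.331, scan_rate=v)
            ips.append(find_peak(simulate_cv_reversible(cfg), "forward").peak_current)
        fit = stats.linregress(np.log10(ITIES_SCAN_RATES_VS), np.log10(ips))
        assert fit.slope == pytest.approx(0.50, abs=0.02)
        sqrt_fit = stats.linregress(np.sqrt(ITIES_SCAN_RATES_VS), ips)
        assert sqrt_fit.rvalue**2 > 0.999

    @pytest.mark.parametrize("factor", [2.0, 5.0])
    def test_ip_proportional_to_concentration_and_area(self, factor):
        base = SimulationConfig(area=1.0, n_space=150, n_time=2500)
        ip0 = find_peak(simulate_cv_reversible(base), "forward").peak_current
        for field in ("bulk_concentration", "area"):
            cfg = SimulationConfig(
                area=base.area * (factor if field == "area" else 1.0),
                bulk_concentration=base.bulk_concentration
                * (factor if field == "bulk_concentration" else 1.0),
                n_space=150,
                n_time=2500,
            )
            ip = find_peak(simulate_cv_reversible(cfg), "forward").peak_current
            assert ip == pytest.approx(factor * ip0, rel=1e-3)

    def test_grid_convergence_at_default(self):
        """Halving the time step moves the forward peak by < 0.5 %."""
        coarse = SimulationConfig(area=1.331)
        fine = SimulationConfig(area=1.331, n_time=2 * coarse.n_time)
        ip_c = find_peak(simulate_cv_reversible(coarse), "forward").peak_current
        ip_f = find_peak(simulate_cv_reversible(fine), "forward").peak_current
        assert abs(ip_c / ip_f - 1) < 0.005


class TestSwvGenerator:
    def test_noiseless_max_equals_height(self):
        vg = generate_swv_trace(0.25, 2.0, 0.03)
        assert vg.current.max() == pytest.approx(2.0, abs=1e-15)
        assert vg.potential[np.argmax(vg.current)] == pytest.approx(0.25)

    def test_waveform_preset_in_metadata(self):
        vg = generate_swv_trace(0.25, 2.0, 0.03)
        assert vg.metadata["frequency_Hz"] == 60.0
        assert vg.metadata["amplitude_V"] == pytest.approx(0.090)
        assert vg.metadata["step_V"] == pytest.approx(0.012)
        assert vg.scan_rate == pytest.approx(0.72)

    def test_narrow_window_sets_warning_flag(self):
        vg = generate_swv_trace(0.25, 2.0, 0.05, window=(0.15, 0.35), step=0.01)
        assert vg.metadata.get("window_warning") is True

    def test_seed_reproducibility_and_noise_scale(self):
        kwargs = dict(peak_potential=0.0, peak_height=1.0, half_width=0.5,
                      step=1e-4, window=(-0.5, 0.5), noise_sd=0.1)
        a = generate_swv_trace(seed=3, **kwargs)
        b = generate_swv_trace(seed=3, **kwargs)
        assert np.array_equal(a.current, b.current)
        c = generate_swv_trace(seed=4, **kwargs)
        assert not np.array_equal(a.current, c.current)
        clean = generate_swv_trace(seed=0, **{**kwargs, "noise_sd": 0.0})
        residual_sd = np.std(a.current - clean.current)
        assert residual_sd == pytest.approx(0.1, rel=0.2)

    def test_written_trace_recovers_generator_truth(self, tmp_path):
        from voltities import read_voltammogram, write_voltammogram

        vg = generate_swv_trace(0.25, 2.0, 0.03)
        back = read_voltammogram(write_voltammogram(vg, tmp_path / "swv.csv"))
        peak = find_peak(back, "forward")
        assert peak.peak_current == pytest.approx(
            back.metadata["true_peak_height_uA"], rel=1e-9
        )
        assert peak.peak_potential == pytest.approx(
            back.metadata["true_peak_potential_V"], abs=1e-9
        )


class TestCalibrationGenerator:
    def test_noiseless_series_is_exact(self):
        data, truth = generate_calibration_series(
            [10, 20, 50, 100, 200], sensitivity=0.1, intercept=0.5
        )
        conc, cur = np.array(data).T
        np.testing.assert_allclose(cur, 0.1 * conc + 0.5, rtol=1e-12)
        assert truth["sensitivity_A_per_M"] == 0.1

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_calibration_series([10.0], sensitivity=0.1)
        with pytest.raises(ValueError, match="strictly positive"):
            generate_calibration_series([0.0, 10.0], sensitivity=0.1)

    def test_mean_recovered_slope_over_seeds(self):
        """Monte-Carlo: 200 seeds, 8 levels, 0.1 uA noise -> slope bias < 1 %."""
        from voltities import linear_calibration
        from voltities.synth import ITIES_CALIBRATION_LEVELS_UM

        slopes = []
        for seed in range(200):
            data, _ = generate_calibration_series(
                ITIES_CALIBRATION_LEVELS_UM, sensitivity=0.1022,
                noise_sd=0.1, seed=seed,
            )
            conc, cur = np.array(data).T
            slopes.append(linear_calibration(conc, cur).slope)
        assert np.mean(slopes) == pytest.approx(0.1022, rel=0.01)


class TestPartitionGenerator:
    def test_low_ph_limit_equals_phi0(self):
        data, _ = generate_partition_data(0.123, 8.50, 600.0, [2.0, 2.5, 3.0])
        for _, phi in data:
            assert phi == pytest.approx(0.123, abs=1e-4)

    def test_curve_is_flat_then_rising(self):
        data, _ = generate_partition_data(
            0.123, 8.50, 600.0, np.arange(2, 12.01, 0.5)
        )
        phi = np.array([p for _, p in data])
        assert np.all(np.diff(phi) >= -1e-12)
        assert phi[-1] - phi[0] > 0.2  # rising branch is prominent

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError, match="K_D"):
            generate_partition_data(0.123, 8.50, -5.0, [2, 4, 6])


class TestMatrixAndInterference:
    def test_suppression_validated(self):
        with pytest.raises(ValueError, match="suppression"):
            generate_matrix_series(30.0, [10, 20, 30], 0.1, suppression_factor=1.5)

    def test_noiseless_identity_for_standard_addition(self):
        from voltities import standard_addition

        series = generate_matrix_series(
            20.0, [0, 10, 20, 40], 0.1, suppression_factor=0.6
        )
        est = standard_addition(series.signals, series.additions)
        assert est.concentration == pytest.approx(20.0, rel=1e-12)

    def test_blank_carries_drift(self):
        series = generate_matrix_series(
            30.0, [10, 20, 30], 0.1, baseline_drift=2.0
        )
        E, I = series.blank.segment("forward")
        slope = np.polyfit(E, I, 1)[0]
        assert slope == pytest.approx(2.0, rel=1e-9)

    def test_interference_signals_and_flags(self):
        from voltities import interference_effect

        series = generate_interference_series(10.0, [0.0, 0.054, -0.15, 0.02])
        assert series[0][1] == pytest.approx(10.0)
        records = [
            interference_effect(10.0, s, concentration=c) for c, s in series
        ]
        assert [r.selective for r in records] == [True, True, False, True]
        assert records[1].signal_change == pytest.approx(5.4)
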