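"""Simulator: hazard law, plate structure, determinism, sampling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellshift import SimConfig, simulate_histogram_timecourse, simulate_plate
from cellshift.simulate import HazardParams, drug_effect_rate, hazard_from_rate

from conftest import constant_hazard_config


class TestShiftHazard:
    def test_zero_rate_gives_zero_probability(self):
        assert hazard_from_rate(0.0) == 0.0

    def test_ln2_rate_gives_half(self):
        assert hazard_from_rate(np.log(2.0)) == pytest.approx(0.5, abs=1e-12)

    def test_small_rate_matches_series_expansion(self):
        # 1 - exp(-x) = x - x^2/2 + ... ; at x = 0.01 the probability is
        # within 1e-4 of x itself
        p = hazard_from_rate(0.01)
        assert p == pytest.approx(0.00995, abs=5e-5)
        assert abs(p - 0.01) < 1e-4

    def test_monotone_in_rate(self):
        rates = np.linspace(0, 2, 50)
        p = hazard_from_rate(rates)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_negative_inputs_rejected(self):
        hp = HazardParams()
        with pytest.raises(ValueError):
            drug_effect_rate(-1.0, 0.0, hp)
        with pytest.raises(ValueError):
            drug_effect_rate(1.0, -0.5, hp)
        with pytest.raises(ValueError):
            hazard_from_rate(-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        dose=st.floats(0, 100),
        t=st.floats(0, 48),
        plateau=st.floats(0, 0.5),
    )
    def test_probability_bounds_property(self, dose, t, plateau):
        hp = HazardParams(gamma_plateau=plateau)
        p = hazard_from_rate(drug_effect_rate(dose, t, hp))
        assert 0.0 <= p <= 1.0


class TestSimulatePlate:
    def test_study_design_well_counts(self, default_plate):
        # 6 doses x 6 replicate wells + 36 controls, 48 hourly timepoints
        assert len(default_plate.wells) == 72
        assert sum(w.condition == "control" for w in default_plate.wells) == 36
        assert all(w.intensities.shape[1] == 48 for w in default_plate.wells)
        assert default_plate.doses == [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]

    def test_cells_per_well_in_range_and_constant(self, default_plate):
        for w in default_plate.wells:
            assert 200 <= w.n_cells <= 400

    def test_seed_determinism_byte_identical(self, small_config):
        a = simulate_plate(small_config)
        b = simulate_plate(small_config)
        for wa, wb in zip(a.wells, b.wells):
            assert wa.well_id == wb.well_id
            np.testing.assert_array_equal(wa.intensities, wb.intensities)
            np.testing.assert_array_equal(wa.latent_states, wb.latent_states)

    def test_adding_wells_preserves_existing_streams(self, small_config):
        import dataclasses

        bigger = dataclasses.replace(small_config, wells_per_dose=3, control_wells=6)
        a = simulate_plate(small_config)
        b = simulate_plate(bigger)
        by_id = {w.well_id: w for w in b.wells}
        for w in a.wells:
            np.testing.assert_array_equal(w.intensities, by_id[w.well_id].intensities)

    def test_noiseless_no_shift_controls_read_on_mode(self):
        cfg = constant_hazard_config(0.2, control_wells=2)
        plate = simulate_plate(cfg)
        for w in plate.control_wells():
            np.testing.assert_array_equal(w.intensities, np.full(w.intensities.shape, 18.0))

    def test_certain_shift_floors_all_drug_cells(self):
        cfg = constant_hazard_config(1.0)
        plate = simulate_plate(cfg)
        (w,) = plate.drug_wells(10.0)
        # baseline observation, then every cell at the floor
        np.testing.assert_array_equal(w.intensities[:, 0], np.full(w.n_cells, 18.0))
        np.testing.assert_array_equal(w.intensities[:, 1:], np.full((w.n_cells, 23), 14.0))

    def test_shifts_absorbing_without_reversion(self, small_plate):
        for w in small_plate.wells:
            assert not np.any(w.latent_states[:, :-1] & ~w.latent_states[:, 1:])
            counts = w.latent_states.sum(axis=0)
            assert np.all(np.diff(counts) >= 0)

    def test_survival_law_constant_hazard(self):
        # expected non-shifted fraction after k steps of hazard p is (1-p)^k;
        # Monte Carlo mean over 50 seeds within 3 SE
        p = 0.1
        k = 23
        fracs = []
        for seed in range(50):
            cfg = constant_hazard_config(p, master_seed=seed)
            (w,) = simulate_plate(cfg).drug_wells(10.0)
            fracs.append(1.0 - w.latent_states[:, k].mean())
        expected = (1 - p) ** k
        n_total = 200 * 50
        se = np.sqrt(expected * (1 - expected) / n_total)
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_dose_monotone_expected_shift(self):
        # averaged over seeds, shifted fraction is non-decreasing up the ladder
        doses = (1.0, 4.0, 16.0, 32.0)
        means = np.zeros(len(doses))
        for seed in range(10):
            cfg = SimConfig(
                doses=doses,
                wells_per_dose=1,
                control_wells=1,
                cells_per_well_range=(200, 200),
                n_timepoints=30,
                master_seed=seed,
            )
            plate = simulate_plate(cfg)
            for i, d in enumerate(doses):
                (w,) = plate.drug_wells(d)
                means[i] += w.latent_states[:, -1].mean() / 10
        assert np.all(np.diff(means) >= 0)

    def test_binomial_count_moments(self):
        # across many wells at fixed t, shifted counts match Binomial(N, p)
        p, k, n_wells, N = 0.05, 10, 300, 200
        counts = []
        for seed in range(n_wells):
            cfg = constant_hazard_config(p, master_seed=seed, n_timepoints=k + 1)
            (w,) = simulate_plate(cfg).drug_wells(10.0)
            counts.append(w.latent_states[:, k].sum())
        counts = np.asarray(counts, dtype=float)
        p_k = 1 - (1 - p) ** k
        mean_expected = N * p_k
        var_expected = N * p_k * (1 - p_k)
        assert abs(counts.mean() - mean_expected) < 3 * np.sqrt(var_expected / n_wells)
        # sample variance of a binomial: allow generous sampling slack
        assert var_expected * 0.7 < counts.var(ddof=1) < var_expected * 1.4

    def test_reversion_allows_unshifting(self):
        cfg = constant_hazard_config(0.5, reversion_prob=0.5, n_timepoints=20)
        plate = simulate_plate(cfg)
        (w,) = plate.drug_wells(10.0)
        reverted = w.latent_states[:, :-1] & ~w.latent_states[:, 1:]
        assert reverted.any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(doses=(-1.0,))
        with pytest.raises(ValueError):
            SimConfig(n_timepoints=0)
        with pytest.raises(ValueError):
            SimConfig(cells_per_well_range=(10, 5))
        with pytest.raises(ValueError):
            SimConfig(floor_log2=18.0, on_mode_log2=14.0)
        with pytest.raises(ValueError):
            SimConfig(doses=(), control_wells=0)


class TestHistogramTimecourse:
    def test_initial_mass_near_on_mode(self):
        cfg = constant_hazard_config(0.1, intensity_sd_log2=0.3, n_timepoints=10)
        edges, hist = simulate_histogram_timecourse(cfg, n_bins=10, support=(14.0, 19.0))
        # at t=0 a 200-cell population sits at the on-mode (log2 = 18)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert centers[np.argmax(hist[0])] == pytest.approx(18.0, abs=0.5)
        assert hist[0][centers < 16].sum() == 0.0

    def test_rows_normalised(self):
        cfg = constant_hazard_config(0.2, intensity_sd_log2=0.3, n_timepoints=12)
        _, hist = simulate_histogram_timecourse(cfg, n_bins=17)
        np.testing.assert_allclose(hist.sum(axis=1), 1.0, atol=1e-12)

    def test_mass_migrates_under_drug(self):
        cfg = constant_hazard_config(0.15, intensity_sd_log2=0.3, n_timepoints=24)
        edges, hist = simulate_histogram_timecourse(cfg, n_bins=10, support=(14.0, 19.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        low = centers < 16
        assert hist[-1][low].sum() > hist[0][low].sum() + 0.5

    def test_survival_fraction_across_seeds(self):
        # non-shifted fraction at the last grid point vs the closed form,
        # aggregated over 20 seeds and compared within 3 binomial SDs
        p, T = 0.1, 25
        obs = []
        for seed in range(20):
            cfg = constant_hazard_config(
                p, master_seed=seed, n_timepoints=T, intensity_sd_log2=0.0
            )
            _, hist = simulate_histogram_timecourse(cfg, n_bins=10, support=(14.0, 19.0))
            centers = 0.5 * (np.linspace(14, 19, 11)[:-1] + np.linspace(14, 19, 11)[1:])
            obs.append(hist[-1][centers > 16].sum())
        expected = (1 - p) ** (T - 1)
        sd = np.sqrt(expected * (1 - expected) / (200 * 20))
        assert abs(np.mean(obs) - expected) < 3 * sd

    def test_bad_inputs(self):
        cfg = constant_hazard_config(0.1)
        with pytest.raises(ValueError):
            simulate_histogram_timecourse(cfg, n_bins=1)
        with pytest.raises(ValueError):
            simulate_histogram_timecourse(cfg, dose=99.0)
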