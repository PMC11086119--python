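"""Synthetic cohort generator: solids, coupling, noise, designs."""

import numpy as np
import pandas as pd
import pytest

from lactowave.model import DomainError
from lactowave.cohort import (
    CalibrationError,
    CohortDesign,
    CouplingConfig,
    DesignError,
    SolidsDistribution,
    StageDispersion,
    sample_milk_solids,
    simulate_cohort,
    simulate_instrument_noise,
    solids_to_params,
)


class TestMilkSolids:
    def test_same_seed_reproduces_table(self):
        a = sample_milk_solids(50, seed=9)
        b = sample_milk_solids(50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sd_collapses_to_mean(self):
        dist = SolidsDistribution(fat_sd=0, protein_sd=0, lactose_sd=0)
        t = sample_milk_solids(20, seed=0, dist=dist)
        assert (t["fat_pct"] == dist.fat_mean).all()
        assert (t["lactose_pct"] == dist.lactose_mean).all()

    def test_rejects_nonpositive_n(self):
        with pytest.raises(DomainError):
            sample_milk_solids(0)

    def test_large_sample_means_match_configuration(self):
        t = sample_milk_solids(10_000, seed=123)
        assert t["fat_pct"].mean() == pytest.approx(3.37, abs=0.02)
        assert t["protein_pct"].mean() == pytest.approx(3.36, abs=0.02)
        assert t["lactose_pct"].mean() == pytest.approx(4.74, abs=0.02)


class TestFatCoupling:
    def test_explicit_slope_without_noise_gives_perfect_correlation(self):
        coupling = CouplingConfig(fat_slope=-0.5)
        for d in coupling.dispersions.values():
            d.delta_eps_sd = 0.0
        solids = sample_milk_solids(200, seed=4)
        rng = np.random.default_rng(0)
        deltas = [
            solids_to_params(solids.iloc[i], "stage1", coupling, rng).delta_eps
            for i in range(len(solids))
        ]
        r = np.corrcoef(deltas, solids["fat_pct"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_calibrated_mode_recovers_latent_correlation(self):
        """5000 latent draws realise the fit-noise-compensated coupling.

        The latent correlation is deeper than the configured measured
        target (-0.66) by the known attenuation factor, so that the
        correlation recovered after noise + fitting lands on the target.
        """
        coupling = CouplingConfig()
        assert coupling.latent_fat_r < coupling.fat_r < 0
        solids = sample_milk_solids(5000, seed=11)
        rng = np.random.default_rng(1)
        deltas = [
            solids_to_params(solids.iloc[i], "stage1", coupling, rng).delta_eps
            for i in range(len(solids))
        ]
        r = np.corrcoef(deltas, solids["fat_pct"])[0, 1]
        assert r == pytest.approx(coupling.latent_fat_r, abs=0.03)

    def test_pregnant_plateau_sd(self):
        """Stage-3 latent delta_eps dispersion sits at the 0.3 plateau."""
        coupling = CouplingConfig()
        solids = sample_milk_solids(2000, seed=21)
        rng = np.random.default_rng(2)
        deltas = np.array([
            solids_to_params(solids.iloc[i], "stage3", coupling, rng).delta_eps
            for i in range(len(solids))
        ])
        assert deltas.std(ddof=1) == pytest.approx(0.3, rel=0.05)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            CouplingConfig(fat_r=-1.5).validate()

    def test_unknown_stage_raises(self):
        with pytest.raises(DesignError):
            solids_to_params({"fat_pct": 3.4}, "stage9", CouplingConfig(), 0)


class TestInstrumentNoise:
    def test_zero_noise_is_identity(self, milk_spectrum):
        out = simulate_instrument_noise(milk_spectrum, 0.0, seed=5)
        np.testing.assert_array_equal(out.eps_real, milk_spectrum.eps_real)
        np.testing.assert_array_equal(out.eps_imag, milk_spectrum.eps_imag)

    def test_empirical_relative_sd(self, milk_spectrum):
        rng = np.random.default_rng(0)
        mid = milk_spectrum.n_points // 2
        vals = np.array([
            simulate_instrument_noise(milk_spectrum, 0.05, rng).eps_real[mid]
            for _ in range(1000)
        ])
        rel_sd = vals.std(ddof=1) / milk_spectrum.eps_real[mid]
        assert rel_sd == pytest.approx(0.05, abs=0.005)

    def test_loss_floored_at_zero(self, milk_spectrum):
        milk_spectrum.eps_imag[:] = 1e-6  # noise will push some points negative
        out = simulate_instrument_noise(milk_spectrum, 0.49, seed=1)
        assert np.all(out.eps_imag >= 0)

    def test_out_of_range_rel_sd_rejected(self, milk_spectrum):
        with pytest.raises(DomainError):
            simulate_instrument_noise(milk_spectrum, 0.5)


class TestSimulateCohort:
    def test_random_survey_counts(self):
        c = simulate_cohort(CohortDesign.random_survey(seed=0))
        assert len(c.table) == 117
        assert int(c.table["pregnant_outcome"].sum()) == 50
        assert int((~c.table["pregnant_outcome"]).sum()) == 67

    def test_pregnant_fixture_stage_counts(self):
        c = simulate_cohort(CohortDesign.pregnant_fixture(seed=1))
        counts = c.table["stage_truth"].value_counts()
        assert counts["stage1"] == 66
        assert counts["stage2"] == 8
        assert counts["stage3"] == 14

    def test_nonpregnant_fixture_group_counts(self):
        c = simulate_cohort(CohortDesign.nonpregnant_fixture(seed=1))
        counts = c.table["stage_truth"].value_counts()
        assert counts["before"] == 70
        assert counts["after"] == 69

    def test_identical_seed_identical_output(self):
        a = simulate_cohort(CohortDesign.pregnant_fixture(seed=7))
        b = simulate_cohort(CohortDesign.pregnant_fixture(seed=7))
        pd.testing.assert_frame_equal(a.table, b.table)
        ref = a.table["spectrum_ref"].iloc[0]
        np.testing.assert_array_equal(a.spectra[ref][0].eps_real,
                                      b.spectra[ref][0].eps_real)

    def test_stage_dispersion_ordering_by_construction(self):
        c = simulate_cohort(CohortDesign.pregnant_fixture(seed=3))
        sds = c.table.groupby("stage_truth")["true_delta_eps"].std(ddof=1)
        assert sds["stage1"] > sds["stage3"]

    def test_replicates_per_sample(self):
        design = CohortDesign.pregnant_fixture(seed=0)
        c = simulate_cohort(design)
        assert all(len(reps) == design.n_replicates for reps in c.spectra.values())

    def test_incompatible_fixture_counts_raise(self):
        design = CohortDesign(protocol="daily", n_cows=1, duration_days=65,
                              fraction_pregnant=1.0,
                              stage_point_counts={"stage1": 5, "stage2": 20,
                                                  "stage3": 2})
        with pytest.raises(DesignError):
            simulate_cohort(design)

    def test_protocol_mode_schedules_all_cows(self):
        c = simulate_cohort(CohortDesign(protocol="weekly", n_cows=4,
                                         duration_days=70,
                                         sampling_interval_days=7, seed=2))
        assert c.table["cow_id"].nunique() == 4
        # 70/7 + 1 sampling days per cow
        assert len(c.table) == 4 * 11

    def test_invalid_design_rejected(self):
        with pytest.raises(DesignError):
            CohortDesign(protocol="monthly").validate()
        with pytest.raises(DesignError):
            CohortDesign(duration_days=1, sampling_interval_days=7).validate()
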