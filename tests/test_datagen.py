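"""Synthetic study-data generator: covariates, dosing, censoring, determinism."""

import io

import numpy as np
import pytest
from scipy import stats

from dtmdd import (LLOQ, StudyDataset, dose_from_weight, final_model_params,
                   generate_dataset, generate_joint_dataset, sample_covariates)
from dtmdd import designs


class TestCovariateSampling:
    def test_scenario_body_weight_moments(self):
        covs, _ = sample_covariates("scenario", 10_000, seed=3)
        bw = np.array([c.BW for c in covs])
        # oracle: analytic moments of Normal(66, 15) truncated to [41, 110]
        spec = designs.SCENARIO_COVARIATES
        a = (spec.bw_lo - 66) / 15
        b = (spec.bw_hi - 66) / 15
        expected = stats.truncnorm.mean(a, b, loc=66, scale=15)
        se = stats.truncnorm.std(a, b, loc=66, scale=15) / np.sqrt(bw.size)
        assert bw.mean() == pytest.approx(expected, abs=3 * se)
        assert np.std(bw, ddof=1) == pytest.approx(
            stats.truncnorm.std(a, b, loc=66, scale=15), rel=0.05)
        assert bw.min() >= 41.0 and bw.max() <= 110.0

    def test_cd_uc_frequency(self):
        covs, _ = sample_covariates("scenario", 10_000, seed=4)
        n_uc = sum(c.disease == "UC" for c in covs)
        p = 1.0 / 6.0
        se = np.sqrt(p * (1 - p) / 10_000)
        assert n_uc / 10_000 == pytest.approx(p, abs=4 * se)

    def test_as_cohort_is_all_as(self):
        covs, _ = sample_covariates("as", 50, seed=5)
        assert all(c.disease == "AS" for c in covs)

    def test_single_draw_reproducible(self):
        a, _ = sample_covariates("ibd", 1, seed=42)
        b, _ = sample_covariates("ibd", 1, seed=42)
        assert a[0] == b[0]

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValueError):
            sample_covariates("ra", 10, seed=0)


class TestDoseFromWeight:
    @pytest.mark.parametrize("bw,expected", [(64.0, 300.0), (75.0, 400.0),
                                             (20.0, 100.0), (66.0, 300.0)])
    def test_vial_rounding(self, bw, expected):
        assert dose_from_weight(bw) == expected

    def test_half_up(self):
        assert dose_from_weight(70.0) == 400.0   # 350 -> half-up -> 400
        assert dose_from_weight(69.9) == 300.0   # 349.5 -> 300

    def test_invalid(self):
        with pytest.raises(ValueError):
            dose_from_weight(0.0)


class TestGenerateDataset:
    def test_as_design_sample_count(self, final_pop):
        ds = generate_dataset(designs.AS_RICH, final_pop, 25, seed=1)
        # 22 scheduled samples/subject, 10% dropout -> ~495 expected
        assert 420 <= ds.n_obs <= 560
        assert ds.n_subjects == 25
        assert (ds.df.loc[ds.df["EVID"] == 0, "DIS"] == 2).all()

    def test_ibd_sparse_sample_count(self, final_pop):
        ds = generate_dataset(designs.IBD_SPARSE, final_pop, 133, seed=2)
        # 7 scheduled samples/subject, 10% dropout -> ~838 expected
        assert 750 <= ds.n_obs <= 900

    def test_determinism_byte_identical(self, final_pop, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_dataset(designs.IBD_SPARSE, final_pop, 20, seed=9).to_csv(p1)
        generate_dataset(designs.IBD_SPARSE, final_pop, 20, seed=9).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_censoring_flags(self, final_pop):
        ds = generate_dataset(designs.IBD_SPARSE, final_pop, 60, seed=3)
        obs = ds.observations
        assert (obs.loc[obs["CENS"] == 0, "DV"] >= LLOQ).all()
        assert (obs.loc[obs["CENS"] == 1, "DV"] == LLOQ).all()
        # baseline troughs at t=0 fall below the quantitation limit
        assert (obs["CENS"] == 1).any()

    def test_censored_fraction_increases_with_noise(self, final_pop):
        lo = generate_dataset(designs.IBD_SPARSE, final_pop, 80, seed=5)
        hi_pop = final_pop.replace(sigma_add=4.0)
        hi = generate_dataset(designs.IBD_SPARSE, hi_pop, 80, seed=5)
        frac = lambda d: (d.observations["CENS"] == 1).mean()
        assert frac(hi) > frac(lo)

    def test_noise_free_matches_typical_predictions(self, final_pop):
        """sigma = omega = 0 reduces generation to the typical-model curve."""
        from dtmdd.datagen import _predict_conc
        from dtmdd.population import typical_params

        quiet = final_pop.replace(sigma_add=0.0, sigma_prop=0.0, omega_V1=0.0,
                                  omega_CL=0.0, omega_V2=0.0, omega_R0C=0.0,
                                  omega_R0P=0.0)
        ds = generate_dataset(designs.IBD_SPARSE, quiet, 5, seed=8,
                              missingness=0.0)
        from dtmdd.units import UnitSystem

        for rec in ds.subjects:
            typ = typical_params(quiet, rec.covariates)
            t = ds.df[(ds.df["ID"] == rec.id) & (ds.df["EVID"] == 0)]
            f = _predict_conc(typ, rec.doses, t["TIME"].to_numpy(), UnitSystem())
            expect = np.where(f < LLOQ, LLOQ, f)
            assert np.allclose(t["DV"].to_numpy(), expect, rtol=1e-8)

    def test_round_trip_through_csv(self, final_pop, tmp_path):
        ds = generate_dataset(designs.AS_RICH, final_pop, 8, seed=13)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = StudyDataset.from_csv(path)
        assert back.n_subjects == ds.n_subjects
        assert back.n_obs == ds.n_obs
        # file-level round trip is bit-identical
        path2 = tmp_path / "ds2.csv"
        back.to_csv(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_joint_dataset_structure(self, small_joint_dataset):
        ds = small_joint_dataset
        assert ds.n_subjects == 50
        dis = ds.df.groupby("ID")["DIS"].first()
        assert (dis.iloc[:10] == 2).all()       # AS block first
        assert (dis.iloc[10:] != 2).all()
        assert ds.df["ID"].is_unique is False   # multiple rows per subject
        assert set(ds.df["COHORT"].unique()) == {"as_rich", "ibd_rich"}


class TestDesignValidation:
    def test_sample_times_sorted(self):
        for d in designs.DESIGNS.values():
            times = [t for t, _ in d.sample_times]
            assert times == sorted(times)
            assert all(t >= 0 for t in times)

    def test_schedules_match_cohorts(self):
        assert designs.AS_RICH.dose_days == tuple(7.0 * w for w in (0, 2, 6, 12, 18))
        assert designs.IBD_SPARSE.dose_days == tuple(7.0 * w for w in (0, 2, 6, 14, 22))
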