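import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import swaylab as sl
from swaylab.group_stats import compare_groups, mann_whitney


class TestFbm:
    def test_deterministic_for_fixed_seed(self):
        a = sl.gen_fbm(500, 0.7, seed=42)
        b = sl.gen_fbm(500, 0.7, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sl.gen_fbm(500, 0.7, seed=43))

    def test_h_half_increments_are_uncorrelated(self):
        """At H=0.5 the path is ordinary Brownian motion: lag-1 increment
        autocorrelation should vanish."""
        acs = []
        for seed in range(20):
            inc = np.diff(sl.gen_fbm(3000, 0.5, seed=seed))
            inc = inc - inc.mean()
            acs.append(np.dot(inc[1:], inc[:-1]) / np.dot(inc, inc))
        assert abs(np.mean(acs)) < 0.05

    def test_variance_grows_along_the_path(self):
        """fBm variance scales like t^{2H}: the across-seed spread must
        increase with sample index."""
        paths = np.array([
            sl.gen_fbm(1000, 0.7, seed=s) - sl.gen_fbm(1000, 0.7, seed=s)[0]
            for s in range(50)
        ])
        idx = np.arange(50, 1000, 50)
        var = paths[:, idx].var(axis=0)
        rho, _ = stats.spearmanr(idx, var)
        assert rho > 0.95

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2])
    def test_invalid_hurst_rejected(self, hurst):
        with pytest.raises(sl.ParameterError):
            sl.gen_fbm(100, hurst, seed=0)


class TestCopGenerator:
    def test_median_path_length_hits_target(self):
        params = sl.SwayGeneratorParams()
        aps = [
            sl.path_length_axis(sl.gen_cop_trial("non_addicted", "2ec", params, seed=s).ap)
            for s in range(200)
        ]
        target = 314.5
        assert abs(np.median(aps) - target) / target < 0.15

    def test_group_target_ratio_propagates_to_cop_total(self):
        """A 1.4x contrast in configured axis targets should appear as a
        ~1.4x contrast in realized group median CoP_total."""
        base = sl.SwayGeneratorParams(target_path_ml=700.0, target_path_ap=700.0)
        boosted = dataclasses.replace(base, target_path_ml=980.0, target_path_ap=980.0)
        med = []
        for params in (base, boosted):
            totals = [
                sl.path_length_total(t.ml, t.ap)
                for t in (sl.gen_cop_trial("addicted", "eoR", params, seed=s)
                          for s in range(100))
            ]
            med.append(np.median(totals))
        assert med[1] / med[0] == pytest.approx(1.4, rel=0.10)

    def test_fixed_seed_is_bit_identical(self):
        params = sl.SwayGeneratorParams(duration=6.0)
        t1 = sl.gen_cop_trial("addicted", "ecL", params, seed=9)
        t2 = sl.gen_cop_trial("addicted", "ecL", params, seed=9)
        np.testing.assert_array_equal(t1.ml, t2.ml)
        np.testing.assert_array_equal(t1.ap, t2.ap)


class TestIMUGenerator:
    def test_zero_spread_gives_exact_baseline(self):
        params = sl.IMUGeneratorParams(
            baselines={c: float(i) for i, c in enumerate(sl.IMU_CHANNELS)},
            spreads={c: 0.0 for c in sl.IMU_CHANNELS},
            duration=2.0,
        )
        trial = sl.gen_imu_trial("non_addicted", "2eo", params, seed=0)
        summary = sl.imu_medians(trial)
        for i, c in enumerate(sl.IMU_CHANNELS):
            assert summary.as_dict()[c] == float(i)

    def test_one_sd_pitch_offset_is_detected(self):
        """A 1-pooled-SD group offset on pitch should reach p<0.05 in at
        least 80% of replicate 19 vs 28 cohorts."""
        spread = 2.0
        params = sl.IMUGeneratorParams(
            baselines={c: 0.0 for c in sl.IMU_CHANNELS},
            spreads={c: spread for c in sl.IMU_CHANNELS},
            addicted_offsets={"pitch": spread},
            duration=5.0,
        )
        wins = 0
        for rep in range(50):
            meds_a = [
                sl.imu_medians(sl.gen_imu_trial("addicted", "2eo", params,
                                                seed=sl.child_seed(rep, 0, i))).pitch
                for i in range(19)
            ]
            meds_b = [
                sl.imu_medians(sl.gen_imu_trial("non_addicted", "2eo", params,
                                                seed=sl.child_seed(rep, 1, i))).pitch
                for i in range(28)
            ]
            _, _, p = mann_whitney(meds_a, meds_b)
            wins += p < 0.05
        assert wins >= 40

    def test_fixed_seed_determinism(self):
        t1 = sl.gen_imu_trial("addicted", "ecR", seed=7)
        t2 = sl.gen_imu_trial("addicted", "ecR", seed=7)
        for c in sl.IMU_CHANNELS:
            np.testing.assert_array_equal(t1.channels[c], t2.channels[c])


class TestCohort:
    def test_default_cohort_shape(self, small_sway_params):
        cohort = sl.gen_cohort(sway=small_sway_params, master_seed=0,
                               conditions=("2eo",))
        assert len(cohort.subjects) == 47
        assert cohort.n_addicted == 19 and cohort.n_non_addicted == 28
        assert all(set(s.cop) == {"2eo"} and set(s.imu) == {"2eo"}
                   for s in cohort.subjects)

    def test_too_small_group_rejected(self):
        with pytest.raises(sl.ParameterError):
            sl.gen_cohort(0, 28)

    def test_same_master_seed_reproduces_cohort(self, small_sway_params):
        c1 = sl.gen_cohort(2, 2, sway=small_sway_params, master_seed=5,
                           conditions=("2ec",))
        c2 = sl.gen_cohort(2, 2, sway=small_sway_params, master_seed=5,
                           conditions=("2ec",))
        for s1, s2 in zip(c1.subjects, c2.subjects):
            np.testing.assert_array_equal(s1.cop["2ec"].ml, s2.cop["2ec"].ml)
            np.testing.assert_array_equal(s1.imu["2ec"].channels["yaw"],
                                          s2.imu["2ec"].channels["yaw"])

    def test_cohort_write_load_roundtrip(self, tmp_path, small_cohort):
        outdir = sl.write_cohort(small_cohort, tmp_path / "cohort")
        back = sl.load_cohort(outdir)
        assert len(back.subjects) == len(small_cohort.subjects)
        orig = {s.subject_id: s for s in small_cohort.subjects}
        for subj in back.subjects:
            for cond, trial in subj.cop.items():
                np.testing.assert_allclose(trial.ml, orig[subj.subject_id].cop[cond].ml,
                                           rtol=1e-9)

    def test_missing_trial_file_names_subject(self, tmp_path, small_cohort):
        outdir = sl.write_cohort(small_cohort, tmp_path / "cohort")
        victim = small_cohort.subjects[0].subject_id
        (outdir / f"{victim}_2eo_cop.csv").unlink()
        with pytest.raises(sl.ValidationError, match=victim):
            sl.load_cohort(outdir)
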