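import math

import numpy as np
import pytest
from scipy import stats as sps

import crpcoord as cc
from crpcoord.errors import ValidationError


AK, KP = ("ankle", "knee"), ("knee", "pelvis")


def small_params(seed=0, **kw):
    """Reduced design for fast tests."""
    cond = cc.ConditionParams(offsets={AK: 30.0, KP: 20.0}, sigma_between=5.0,
                              sigma_within=1.0, sigma_noise=0.2)
    conds = {
        ("control", "pre"): cond, ("control", "post"): cond,
        ("test", "pre"): cond, ("test", "post"): cond,
        ("target", "single"): cond,
    }
    defaults = dict(
        conditions=conds, n_subjects={"control": 2, "test": 2, "target": 2},
        trials_per_subject=3, samples_per_cycle=64, seed=seed,
    )
    defaults.update(kw)
    return cc.SimParams(**defaults)


class TestSimulateJointCycle:
    def test_zero_offset_gives_zero_crp(self, rng):
        trial = cc.simulate_joint_cycle(0.0, 0.0, 0.0, 200, rng)
        curve = cc.compute_crp(trial, AK)
        assert np.abs(curve.theta).max() < 1e-6
        assert cc.marp(curve) < 1e-6

    def test_offset_recovered_through_pipeline(self, rng):
        trial = cc.simulate_joint_cycle(45.0, 0.0, 0.0, 200, rng)
        assert cc.marp(cc.compute_crp(trial, AK)) == pytest.approx(45.0, abs=1.0)
        assert cc.marp(cc.compute_crp(trial, KP)) == pytest.approx(45.0, abs=1.0)

    def test_seed_determinism(self):
        t1 = cc.simulate_joint_cycle(30.0, 2.0, 0.5, 128, np.random.default_rng(7))
        t2 = cc.simulate_joint_cycle(30.0, 2.0, 0.5, 128, np.random.default_rng(7))
        for joint in t1.angles:
            np.testing.assert_array_equal(t1.angles[joint], t2.angles[joint])

    def test_undersampled_rejected(self, rng):
        with pytest.raises(ValidationError):
            cc.simulate_joint_cycle(30.0, 0.0, 0.0, 15, rng)

    def test_waveform_shape(self, rng):
        trial = cc.simulate_joint_cycle(20.0, 0.0, 0.0, 200, rng,
                                        amplitude_deg=30.0, baseline_deg=10.0)
        knee = trial.angles["knee"]
        assert knee.max() == pytest.approx(40.0, abs=0.1)
        assert knee.min() == pytest.approx(-20.0, abs=0.1)


class TestSimulateCohort:
    def test_default_design_counts(self):
        ds = cc.simulate_cohort(cc.study_preset(seed=0, trials_per_subject=1,
                                                samples_per_cycle=32))
        assert ds.manifest.group_counts() == {"control": 7, "test": 7, "target": 14}
        rec = ds.manifest.records
        assert len(rec[(rec.group == "control")]) == 7 * 2  # pre + post
        assert len(rec[(rec.group == "target")]) == 14
        assert set(rec[rec.group == "target"].stage) == {"single"}
        assert len(ds.trials) == len(rec)

    def test_degenerate_variance_recovers_offsets_exactly(self):
        cond = cc.ConditionParams(offsets={AK: 30.0, KP: 20.0})
        sim = small_params()
        sim = cc.SimParams(
            conditions={k: cond for k in sim.conditions},
            n_subjects={"control": 2, "test": 2, "target": 2},
            trials_per_subject=2, samples_per_cycle=64, seed=1,
        )
        ds = cc.simulate_cohort(sim)
        for metrics in cc.compute_subject_metrics(ds.trials, cc.AnalysisConfig()):
            expected = 30.0 if metrics.coupling == AK else 20.0
            assert metrics.marp == pytest.approx(expected, abs=1.0)

    def test_seed_determinism_dataset(self):
        d1 = cc.simulate_cohort(small_params(seed=3))
        d2 = cc.simulate_cohort(small_params(seed=3))
        assert d1.manifest.records.equals(d2.manifest.records)
        for a, b in zip(d1.trials, d2.trials):
            for joint in a.angles:
                np.testing.assert_array_equal(a.angles[joint], b.angles[joint])

    def test_round_trip_through_disk(self, tmp_path):
        ds = cc.simulate_cohort(small_params(seed=4))
        ds.write(tmp_path)
        manifest = cc.read_manifest(tmp_path / "manifest.csv")
        trials = cc.load_trials(manifest, tmp_path)
        assert len(trials) == len(ds.trials)
        np.testing.assert_allclose(
            trials[0].angles["ankle"], ds.trials[0].angles["ankle"], atol=1e-12
        )

    def test_dp_monotone_in_within_subject_jitter(self):
        means = []
        for sw in (0.5, 2.0, 8.0):
            vals = []
            for seed in range(3):
                cond = cc.ConditionParams(offsets={AK: 30.0, KP: 20.0},
                                          sigma_within=sw)
                sim = cc.SimParams(
                    conditions={
                        ("control", "pre"): cond, ("control", "post"): cond,
                        ("test", "pre"): cond, ("test", "post"): cond,
                        ("target", "single"): cond,
                    },
                    n_subjects={"control": 2, "test": 2, "target": 2},
                    trials_per_subject=5, samples_per_cycle=64, seed=seed,
                )
                ds = cc.simulate_cohort(sim)
                ms = cc.compute_subject_metrics(ds.trials, cc.AnalysisConfig())
                vals.extend(m.dp for m in ms if math.isfinite(m.dp))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestGroundTruth:
    def test_no_jitter_means_zero_dp(self):
        sim = small_params()
        cond = cc.ConditionParams(offsets={AK: 30.0, KP: 20.0}, sigma_within=0.0)
        sim = cc.SimParams(conditions={k: cond for k in sim.conditions},
                           n_subjects=sim.n_subjects, trials_per_subject=3,
                           samples_per_cycle=64)
        gt = cc.ground_truth(sim)
        assert gt.dp("control", "pre", AK) == 0.0

    def test_zero_offset_folded_normal(self):
        sigma = 6.0
        cond = cc.ConditionParams(offsets={AK: 0.0, KP: 0.0}, sigma_between=sigma)
        sim = cc.SimParams(
            conditions={k: cond for k in small_params().conditions},
            n_subjects={"control": 2, "test": 2, "target": 2},
            trials_per_subject=3, samples_per_cycle=64,
        )
        gt = cc.ground_truth(sim)
        assert gt.marp("control", "pre", AK) == pytest.approx(
            sigma * math.sqrt(2.0 / math.pi), rel=1e-9
        )

    def test_large_offset_small_sigma(self):
        cond = cc.ConditionParams(offsets={AK: 90.0, KP: 20.0}, sigma_between=0.5)
        sim = cc.SimParams(
            conditions={k: cond for k in small_params().conditions},
            n_subjects={"control": 2, "test": 2, "target": 2},
            trials_per_subject=3, samples_per_cycle=64,
        )
        assert cc.ground_truth(sim).marp("target", "single", AK) == pytest.approx(
            90.0, abs=0.01
        )

    def test_dp_truth_is_c4_corrected(self):
        sim = small_params()  # sigma_within = 1.0, 3 trials
        gt = cc.ground_truth(sim)
        assert gt.dp("control", "pre", AK) == pytest.approx(cc.c4(3) * 1.0, rel=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (2.0, 3.0), (40.0, 6.0)])
    def test_folded_normal_mean_matches_scipy(self, mu, sigma):
        ours = cc.folded_normal_mean(mu, sigma)
        ref = sps.foldnorm(c=mu / sigma, scale=sigma).mean()
        assert ours == pytest.approx(ref, rel=1e-9)


class TestSimParamsValidation:
    def test_offset_range_enforced(self):
        with pytest.raises(ValidationError):
            cc.ConditionParams(offsets={AK: 200.0})

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            cc.ConditionParams(offsets={AK: 10.0}, sigma_within=-1.0)

    def test_min_group_size(self):
        with pytest.raises(ValidationError):
            small_params(n_subjects={"control": 1, "test": 2, "target": 2})
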