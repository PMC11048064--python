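"""Synthetic-trial generators: construction arithmetic, determinism, cohorts."""

import numpy as np
import pandas as pd
import pytest

from mobiseg.errors import InvalidParamsError, InvalidSpecError
from mobiseg.preprocess import LOCATIONS
from mobiseg.synth import (
    CohortSpec,
    StsTrialParams,
    TugTrialParams,
    WalkTrialParams,
    default_cohort_spec,
    draw_cohort_params,
    generate_sts_trial,
    generate_tug_trial,
    generate_walk_trial,
)


def _all_samples(rec):
    return np.concatenate(
        [rec.streams[loc].ang_vel.ravel() for loc in LOCATIONS]
        + [rec.streams[loc].lin_acc.ravel() for loc in LOCATIONS]
    )


class TestTugGenerator:
    def test_reference_phase_durations_give_reference_total(self):
        # Control single-task section means: total must be 13.34 s.
        p = TugTrialParams(phase_durations=(1.37, 3.95, 1.75, 3.33, 2.94))
        _, truth = generate_tug_trial(p)
        t = truth.events["tug"]
        assert t[5] - t[0] == pytest.approx(13.34, abs=1e-9)
        for k, d in enumerate(p.phase_durations):
            assert t[k + 1] - t[k] == pytest.approx(d, abs=1e-9)

    def test_noiseless_trials_identical_across_seeds(self):
        p0 = TugTrialParams(noise_sd_acc=0.0, noise_sd_gyr=0.0, seed=1)
        p1 = TugTrialParams(noise_sd_acc=0.0, noise_sd_gyr=0.0, seed=2)
        r0, _ = generate_tug_trial(p0)
        r1, _ = generate_tug_trial(p1)
        np.testing.assert_array_equal(_all_samples(r0), _all_samples(r1))

    def test_same_seed_bit_identical(self):
        r0, _ = generate_tug_trial(TugTrialParams(seed=5))
        r1, _ = generate_tug_trial(TugTrialParams(seed=5))
        np.testing.assert_array_equal(_all_samples(r0), _all_samples(r1))

    def test_infeasible_cadence_rejected(self):
        with pytest.raises(InvalidParamsError):
            TugTrialParams(phase_durations=(1.4, 1.0, 1.7, 3.3, 2.9), steps_to_cone=8)

    def test_step_peaks_only_inside_walking_phases(self, filt):
        p = TugTrialParams(noise_sd_acc=0.0, noise_sd_gyr=0.0)
        rec, truth = generate_tug_trial(p)
        t1, t2, t3, t4, t5, t6 = truth.events["tug"]
        acc = filt(rec, "acc", "foot_R")
        acc = acc - np.median(acc)
        t = np.arange(rec.n_samples) / rec.fs
        outside = (t < t2 - 0.2) | ((t > t3 + 0.2) & (t < t4 - 0.1)) | (t > t5 + 0.2)
        assert np.abs(acc[outside]).max() < 0.5  # quiet outside walking
        walking = (t > t2) & (t < t3)
        assert acc[walking].max() > 3.0  # strong double peaks inside


class TestStsGenerator:
    def test_lobe_count_and_boundaries(self):
        p = StsTrialParams(n_cycles=5, up_duration=1.7, down_duration=1.7, inter_phase_gap=0.15)
        _, truth = generate_sts_trial(p)
        bounds = truth.events["sts_bounds"]
        assert len(bounds) == 20  # 4 boundaries per cycle
        assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))

    def test_overlapping_lobes_rejected(self):
        with pytest.raises(InvalidParamsError):
            StsTrialParams(inter_phase_gap=0.0)

    def test_rms_targets_are_realized(self, filt):
        p = StsTrialParams(trunk_rms=15.0, thigh_rms_L=30.0, thigh_rms_R=30.0,
                           pelvis_rms=12.0, noise_sd_gyr=0.0)
        rec, truth = generate_sts_trial(p)
        assert truth.features["rms_thorax"] == pytest.approx(15.0, rel=1e-6)
        # and the actual waveform reproduces it over the active interval
        x = rec.gyr_magnitude("sternum")
        fs = rec.fs
        i0 = int(truth.events["sts_bounds"][0] * fs)
        i1 = int(truth.events["sts_bounds"][-1] * fs) + 1
        assert np.sqrt(np.mean(x[i0:i1] ** 2)) == pytest.approx(15.0, rel=0.01)


class TestWalkGenerator:
    def test_to_hs_gap_is_swing_times_stride(self):
        p = WalkTrialParams(stride_duration=1.2, swing_fraction=0.38)
        _, truth = generate_walk_trial(p)
        for side in ("L", "R"):
            gaps = np.array(truth.events[f"hs_{side}"]) - np.array(truth.events[f"to_{side}"])
            np.testing.assert_allclose(gaps, 0.456, atol=1e-12)

    def test_sides_offset_by_half_stride(self):
        p = WalkTrialParams(stride_duration=1.2)
        _, truth = generate_walk_trial(p)
        offset = truth.events["to_R"][0] - truth.events["to_L"][0]
        assert offset == pytest.approx(0.6, abs=1e-12)

    def test_too_close_peaks_rejected(self):
        with pytest.raises(InvalidParamsError):
            WalkTrialParams(stride_duration=0.5, swing_fraction=0.1)

    def test_speed_identity_in_ground_truth(self):
        _, truth = generate_walk_trial(WalkTrialParams())
        f = truth.features
        assert f["gait_speed"] * f["walk_time"] == pytest.approx(10.0, rel=1e-12)


class TestCohort:
    def test_same_seed_identical_table(self):
        spec = default_cohort_spec(n_control=5, n_stroke=5, seed=11)
        t0 = draw_cohort_params(spec)
        t1 = draw_cohort_params(spec)
        pd.testing.assert_frame_equal(t0, t1)
        assert t0.to_csv() == t1.to_csv()  # byte-identical serialization

    def test_zero_sd_makes_cell_constant(self):
        params = {
            "TUG": {
                name: {c: (m, 0.0) for c in ("control_ST", "control_DT", "stroke_ST", "stroke_DT")}
                for name, m in [
                    ("sit_to_stand", 1.4), ("walk_to_cone", 4.0), ("turn_cone", 1.8),
                    ("walk_to_chair", 3.3), ("turn_and_sit", 2.9),
                    ("steps_to_cone", 6.0), ("steps_to_chair", 5.0),
                ]
            }
        }
        spec = CohortSpec(params=params, n_subjects={"control": 4, "stroke": 4}, seed=0)
        t = draw_cohort_params(spec)
        for col in ("sit_to_stand", "walk_to_cone"):
            assert t[col].nunique() == 1

    def test_missing_cell_rejected(self):
        params = {"TUG": {"sit_to_stand": {"control_ST": (1.4, 0.1)}}}
        with pytest.raises(InvalidSpecError):
            CohortSpec(params=params)

    def test_empirical_centering_realizes_cell_means(self):
        spec = default_cohort_spec(n_control=30, n_stroke=30, seed=2, tests=("TUG",))
        t = draw_cohort_params(spec)
        cell = t[(t.group == "control") & (t.condition == "ST")]
        assert cell["walk_to_cone"].mean() == pytest.approx(3.95, abs=0.02)

    def test_iid_cell_means_converge_within_one_percent_at_n500(self):
        spec = default_cohort_spec(n_control=500, n_stroke=500, seed=3, tests=("TUG",))
        spec = CohortSpec(
            params=spec.params, n_subjects=spec.n_subjects, seed=3, empirical=False
        )
        t = draw_cohort_params(spec)
        t["total"] = t[
            ["sit_to_stand", "walk_to_cone", "turn_cone", "walk_to_chair", "turn_and_sit"]
        ].sum(axis=1)
        expected = {
            ("control", "ST"): 13.34,
            ("control", "DT"): 14.80,
            ("stroke", "ST"): 16.15,
            ("stroke", "DT"): 18.44,
        }
        for key, mean in t.groupby(["group", "condition"])["total"].mean().items():
            assert mean == pytest.approx(expected[key], rel=0.01)

    def test_repeated_measures_structure(self):
        spec = default_cohort_spec(n_control=3, n_stroke=3, seed=0, tests=("STS",))
        t = draw_cohort_params(spec)
        per_subj = t.groupby("subject_id")["condition"].nunique()
        assert (per_subj == 2).all()
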