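import dataclasses
import json

import numpy as np
import pytest

from earssvep.cnn import TrainConfig
from earssvep.harness import (
    SchemeConfig,
    load_benchmark_mat,
    run_subject_dependent,
    run_subject_independent,
    sweep_windows,
)
from earssvep.metrics import itr_bits_per_min
from earssvep.synth import SimConfig, generate_dataset, write_benchmark_mat

FAST_TRAIN = TrainConfig(max_epochs=3, seed=0)


def fast_cfg(**kwargs):
    return SchemeConfig(train=FAST_TRAIN, window_seconds=1, **kwargs)


class TestConfigValidation:
    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            SchemeConfig(scheme="leave-one-trial-out")

    def test_fractions_bounded(self):
        with pytest.raises(ValueError):
            SchemeConfig(train_fraction=1.5)

    def test_test_channels_subset_of_train(self):
        with pytest.raises(ValueError, match="subset"):
            SchemeConfig(channels_train=("Oz",), channels_test=("Oz", "T7", "T8"))


class TestSubjectDependent:
    def test_missing_channel_names_subject_and_channel(self, small_dataset):
        broken = [dataclasses.replace(t, samples=dict(t.samples)) for t in small_dataset]
        broken[0].samples.pop("T7")
        with pytest.raises(ValueError, match=r"subject 0.*T7"):
            run_subject_dependent(broken, fast_cfg())

    def test_bookkeeping_and_report_shape(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        report = run_subject_dependent(trials, fast_cfg(n_folds=5, seed=2))
        assert report.n_models == 5
        assert set(report.conditions) == {"Oz", "T7", "T8", "avT7T8", "regressed"}
        frame = report.to_frame()
        assert len(frame) == 5
        # ITR column is derived from the accuracy column with T = W + 0.55
        for _, row in frame.iterrows():
            assert row["itr_bits_per_min"] == pytest.approx(
                itr_bits_per_min(row["accuracy"], 3, 1.55), abs=1e-9
            )

    def test_av_t7t8_is_per_subject_mean(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        report = run_subject_dependent(trials, fast_cfg(seed=5))
        av = report.conditions["avT7T8"].per_subject
        t7 = report.conditions["T7"].per_subject
        t8 = report.conditions["T8"].per_subject
        for s, v in av.items():
            assert v == pytest.approx(0.5 * (t7[s] + t8[s]))

    def test_determinism_under_fixed_seed(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        r1 = run_subject_dependent(trials, fast_cfg(seed=3))
        r2 = run_subject_dependent(trials, fast_cfg(seed=3))
        assert r1.to_json() == r2.to_json()


class TestSubjectIndependent:
    def test_each_subject_tested_exactly_once(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        report = run_subject_independent(trials, fast_cfg(n_groups=2, seed=1))
        assert report.n_models == 2
        for cond in ("Oz", "T7", "T8", "regressed"):
            assert sorted(report.conditions[cond].per_subject) == [0, 1, 2, 3]

    def test_indivisible_groups_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="groups"):
            run_subject_independent(small_dataset, fast_cfg(n_groups=2))

    def test_group_assignment_deterministic(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        r1 = run_subject_independent(trials, fast_cfg(n_groups=2, seed=8))
        r2 = run_subject_independent(trials, fast_cfg(n_groups=2, seed=8))
        assert r1.to_json() == r2.to_json()


class TestSweep:
    def test_reports_tagged_by_window(self, noiseless_cfg):
        trials = generate_dataset(noiseless_cfg)
        reports = sweep_windows(trials, fast_cfg(seed=4), windows=(1, 2))
        assert sorted(reports) == [1, 2]
        for w, rep in reports.items():
            assert rep.window_seconds == w
            for cond in rep.conditions.values():
                assert cond.itr == pytest.approx(
                    itr_bits_per_min(cond.mean_accuracy, 3, w + 0.55), abs=1e-9
                )

    def test_invalid_window_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="1..5"):
            sweep_windows(small_dataset, fast_cfg(), windows=(0, 2))


class TestMatAdapter:
    def test_round_trip_preserves_trials(self, tmp_path, small_cfg, small_dataset):
        subject0 = [t for t in small_dataset if t.subject_id == 0]
        path = tmp_path / "S00.mat"
        write_benchmark_mat(subject0, path)
        loaded = load_benchmark_mat(path)
        assert len(loaded) == len(subject0)
        by_key = {(t.block_id, t.label_freq): t for t in loaded}
        for t in subject0:
            clone = by_key[(t.block_id, t.label_freq)]
            assert clone.subject_id == 0
            for ch, x in t.samples.items():
                np.testing.assert_allclose(clone.samples[ch], x, atol=1e-12)

    def test_valid_segment_is_1250_samples(self, tmp_path, small_dataset):
        subject0 = [t for t in small_dataset if t.subject_id == 0]
        path = tmp_path / "S00.mat"
        write_benchmark_mat(subject0, path)
        for t in load_benchmark_mat(path):
            assert all(x.size == 1250 for x in t.samples.values())

    def test_missing_target_frequency_listed(self, tmp_path, small_dataset):
        partial = [
            t for t in small_dataset if t.subject_id == 0 and t.label_freq != 14.0
        ]
        path = tmp_path / "partial.mat"
        write_benchmark_mat(partial, path)
        with pytest.raises(ValueError, match="14"):
            load_benchmark_mat(path)

    def test_missing_channel_rejected(self, tmp_path, small_dataset):
        subject0 = [t for t in small_dataset if t.subject_id == 0]
        path = tmp_path / "S00.mat"
        write_benchmark_mat(subject0, path)
        with pytest.raises(ValueError, match="Cz"):
            load_benchmark_mat(path, channels=("Oz", "Cz"))

    def test_malformed_file_rejected(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "bad.mat"
        savemat(str(path), {"data": np.zeros((3, 4))})
        with pytest.raises(ValueError, match="lacks|channels"):
            load_benchmark_mat(path)
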