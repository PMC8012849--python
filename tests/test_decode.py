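import numpy as np
import pytest

import nirsbmi as nb


class TestSplit7030:
    def test_100_rows_per_class(self):
        y = np.array(["mwl1"] * 100 + ["mwl2"] * 100)
        train, test = nb.split_70_30((y, None), seed=0)
        for cls in ("mwl1", "mwl2"):
            assert np.sum(y[train] == cls) == 70
            assert np.sum(y[test] == cls) == 30

    def test_190_rows_rounds_toward_train(self):
        y = np.array(["mwl1"] * 190 + ["mwl2"] * 190)
        train, test = nb.split_70_30((y, None), seed=0)
        for cls in ("mwl1", "mwl2"):
            assert np.sum(y[train] == cls) == 133
            assert np.sum(y[test] == cls) == 57

    def test_deterministic_for_seed(self):
        y = np.array(["mwl1", "mwl2"] * 50)
        a = nb.split_70_30((y, None), seed=9)
        b = nb.split_70_30((y, None), seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_disjoint_and_complete(self):
        y = np.array(["mwl1", "mwl2"] * 37)
        train, test = nb.split_70_30((y, None), seed=3)
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == y.size

    def test_tiny_class_rejected(self):
        y = np.array(["mwl1", "mwl2", "mwl2"])
        with pytest.raises(ValueError):
            nb.split_70_30((y, None), seed=0)

    def test_epoch_level_split_keeps_epochs_together(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(series, dual_schedule)
        train, test = nb.split_70_30(fm, seed=0, by_epoch=True)
        assert set(fm.epoch_id[train]).isdisjoint(fm.epoch_id[test])


class TestTrainSvm:
    def test_separable_clouds_train_perfectly(self, rng):
        X = np.concatenate(
            [rng.normal(-5, 0.1, (50, 2)), rng.normal(5, 0.1, (50, 2))]
        )
        y = np.array(["mwl1"] * 50 + ["mwl2"] * 50)
        model = nb.train_svm(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_symmetric_1d_boundary_at_zero(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["mwl1", "mwl1", "mwl2", "mwl2"])
        model = nb.train_svm(X, y)
        assert model.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-6)
        assert model.predict([[-0.5]])[0] == "mwl1"
        assert model.predict([[0.5]])[0] == "mwl2"

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 2))
        y = rng.permutation(np.array(["mwl1", "mwl2"] * 200))
        train, test = nb.split_70_30((y, None), seed=1)
        model = nb.train_svm(X[train], y[train])
        acc = np.mean(model.predict(X[test]) == y[test])
        # 95% binomial band around 0.5 for n=120
        half_width = 1.96 * np.sqrt(0.25 / test.size)
        assert abs(acc - 0.5) < half_width

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            nb.train_svm(np.zeros((4, 2)), np.array(["mwl1"] * 4))


class TestEvaluateSubject:
    def test_noiseless_subject_decodes_near_perfectly(self, dual_schedule):
        # plateau windows separate perfectly; windows on the rise/fall
        # transitions are exact scalar multiples across the two levels and
        # genuinely overlap in (mean, slope) space, so a noiseless subject
        # is decoded very well but not perfectly
        cfg = nb.SubjectConfig(seed=0, noise_sd=0.0, physio=())
        rec, _ = nb.simulate_subject(cfg, dual_schedule)
        series = nb.lowpass(nb.invert_mbll(rec))
        res = nb.evaluate_subject(series, dual_schedule, seed=0)
        for chrom in ("hbo", "hbr", "hbt"):
            assert res.accuracy[chrom] >= 85.0

    def test_equal_amplitudes_give_chance_accuracy(self, dual_schedule):
        cfg = nb.SubjectConfig(seed=1, amplitude_mwl1=0.7, amplitude_mwl2=0.7)
        rec, _ = nb.simulate_subject(cfg, dual_schedule)
        series = nb.lowpass(nb.invert_mbll(rec))
        res = nb.evaluate_subject(series, dual_schedule, seed=1)
        n_test = res.test_idx.size
        band = 100 * 1.96 * np.sqrt(0.25 / n_test)
        assert abs(res.accuracy["hbo"] - 50.0) < band

    def test_accuracy_monotone_in_amplitude_gap(self, dual_schedule):
        # larger activation contrast -> easier decoding
        gaps = [0.0, 0.25, 0.5]
        means = []
        for gap in gaps:
            accs = []
            for seed in range(3):
                cfg = nb.SubjectConfig(
                    seed=seed, amplitude_mwl1=0.5, amplitude_mwl2=0.5 + gap
                )
                rec, _ = nb.simulate_subject(cfg, dual_schedule)
                series = nb.lowpass(nb.invert_mbll(rec))
                accs.append(
                    nb.evaluate_subject(series, dual_schedule, seed=seed).accuracy["hbo"]
                )
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]

    def test_train_test_rows_never_overlap(self, default_subject, dual_schedule):
        _, _, series = default_subject
        res = nb.evaluate_subject(series, dual_schedule, seed=2)
        assert np.intersect1d(res.train_idx, res.test_idx).size == 0

    def test_result_table_matches_report_format(self, default_subject, dual_schedule):
        _, _, series = default_subject
        res = nb.evaluate_subject(series, dual_schedule, seed=1)
        frame = res.to_frame("S1")
        assert list(frame.columns) == [
            "subject",
            "accuracy_hbo",
            "accuracy_hbr",
            "accuracy_hbt",
            "itr_hbo",
            "itr_hbr",
        ]


class TestTransferRates:
    @pytest.mark.parametrize(
        "P,N,expected",
        [(1.0, 2, 1.0), (0.5, 2, 0.0), (0.879, 2, 0.4677)],
    )
    def test_itr_closed_forms(self, P, N, expected):
        assert nb.itr_bits_per_trial(P, N) == pytest.approx(expected, abs=1e-4)

    def test_itr_monotone_above_chance(self):
        grid = np.linspace(0.51, 1.0, 50)
        vals = [nb.itr_bits_per_trial(p, 2) for p in grid]
        assert np.all(np.diff(vals) > 0)

    def test_itr_invalid_class_count(self):
        with pytest.raises(ValueError):
            nb.itr_bits_per_trial(0.9, 1)

    @pytest.mark.parametrize(
        "bt,T,Cn,expected",
        [(1.0, 60.0, 1, 1.0), (0.4677, 20.0, 1, 1.4031)],
    )
    def test_dtr_values(self, bt, T, Cn, expected):
        assert nb.dtr_bits_per_minute(bt, T, Cn) == pytest.approx(expected, abs=1e-3)

    def test_dtr_linear_in_classifications(self):
        assert nb.dtr_bits_per_minute(0.3, 10, 4) == pytest.approx(
            2 * nb.dtr_bits_per_minute(0.3, 10, 2)
        )

    def test_dtr_invalid_time(self):
        with pytest.raises(ValueError):
            nb.dtr_bits_per_minute(1.0, 0.0)
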