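import numpy as np
import pytest

import nirsbmi as nb
from nirsbmi.quality import _trial_windows
from nirsbmi.synthesize import hrf_kernel

FS = 8.0


def _series(rows):
    rows = np.atleast_2d(rows)
    return nb.HemodynamicSeries(hbo=rows, hbr=-rows / 3.0, sampling_rate=FS)


def _convolved_reference(schedule):
    ref = nb.reference_signal(schedule)
    return np.convolve(ref, hrf_kernel(FS))[: schedule.n_samples]


class TestReferenceSignal:
    def test_baseline_only_all_zero(self):
        s = nb.build_default_paradigm(n_trials=0)
        assert np.all(nb.reference_signal(s) == 0)

    def test_ten_runs_of_160_ones(self, single_schedule):
        ref = nb.reference_signal(single_schedule)
        padded = np.concatenate([[0], ref, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        assert starts.size == 10
        np.testing.assert_array_equal(ends - starts, 160)

    def test_consistent_with_label_vector(self, dual_schedule):
        ref = nb.reference_signal(dual_schedule)
        labels = dual_schedule.label_vector()
        np.testing.assert_array_equal(ref == 1, np.isin(labels, ["mwl1", "mwl2"]))


class TestChannelSignificance:
    def test_task_coupled_channel_passes(self, single_schedule):
        rng = np.random.default_rng(1)
        x = _convolved_reference(single_schedule) + rng.normal(
            0, 0.05, single_schedule.n_samples
        )
        report = nb.channel_significance(_series(x), single_schedule)
        assert report.passes[0]
        assert report.significance_fraction[0] >= 0.8916

    def test_white_noise_channel_fails(self, single_schedule):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, single_schedule.n_samples)
        report = nb.channel_significance(_series(x), single_schedule)
        assert not report.passes[0]
        assert report.significance_fraction[0] < 0.5

    def test_vacuous_alpha_passes_everything(self, single_schedule, rng):
        x = rng.normal(size=(3, single_schedule.n_samples))
        report = nb.channel_significance(_series(x), single_schedule, alpha=1.0)
        assert report.passes.all()

    def test_zero_variance_channel_recorded_as_degenerate_failure(
        self, single_schedule
    ):
        x = np.zeros(single_schedule.n_samples)
        report = nb.channel_significance(_series(x), single_schedule)
        assert report.degenerate[0] and not report.passes[0]

    def test_report_table_has_one_row_per_channel(self, single_schedule, rng):
        x = rng.normal(size=(4, single_schedule.n_samples))
        frame = nb.channel_significance(_series(x), single_schedule).to_frame()
        assert len(frame) == 4
        assert set(frame.columns) >= {"p_value", "significance_fraction", "passes"}


class TestRejectSubject:
    def _report(self, n=12):
        return nb.ChannelQCReport(
            channels=tuple(f"ch{i:02d}" for i in range(n)),
            t_statistic=np.zeros(n),
            p_value=np.zeros(n),
            significance_fraction=np.ones(n),
            passes=np.ones(n, dtype=bool),
            degenerate=np.zeros(n, dtype=bool),
            alpha=0.05,
            threshold=0.8916,
        )

    @pytest.mark.parametrize(
        "n_bad,retained", [(2, False), (1, True), (0, True)]
    )
    def test_ten_percent_contamination_rule(self, n_bad, retained):
        flags = np.zeros(12, dtype=bool)
        flags[:n_bad] = True
        out = nb.reject_subject(self._report(), flags)
        assert out.retained is retained
        assert out.contamination_fraction == pytest.approx(n_bad / 12)


class TestHrfAverage:
    def test_single_trial_identity(self):
        s = nb.build_default_paradigm(n_trials=1, baseline_s=20.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=s.n_samples)
        series = nb.HemodynamicSeries(
            hbo=np.stack([x, x, x]), hbr=np.zeros((3, s.n_samples)), sampling_rate=FS
        )
        avg = nb.hrf_average(series, s, "mwl1")
        task, rest = _trial_windows(s, "mwl1")[0]
        expected = x[task.start : rest.stop]
        np.testing.assert_allclose(avg.hbo, expected)

    def test_noiseless_block_response_peak_location(self, single_schedule):
        # with a 20 s boxcar the averaged response peaks where the HRF's
        # running integral does, ~11-14 s after onset for this kernel
        cfg = nb.SubjectConfig(seed=0, noise_sd=0.0, physio=())
        rec, _ = nb.simulate_subject(cfg, single_schedule)
        series = nb.invert_mbll(rec)
        avg = nb.hrf_average(series, single_schedule, "mwl1")
        assert 10.0 <= avg.time[np.argmax(avg.hbo)] <= 15.0

    def test_noise_amplitude_shrinks_like_sqrt_trials(self, single_schedule):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, single_schedule.n_samples))
        series = nb.HemodynamicSeries(
            hbo=x, hbr=np.zeros_like(x), sampling_rate=FS
        )
        avg = nb.hrf_average(series, single_schedule, "mwl1")
        ratio = np.std(avg.hbo) / np.std(x)
        assert ratio == pytest.approx(1 / np.sqrt(10), rel=0.15)

    def test_invariant_to_channel_order(self, default_subject, dual_schedule):
        _, _, series = default_subject
        avg1 = nb.hrf_average(series, dual_schedule, "mwl2")
        perm = series.select_channels(np.arange(series.n_channels)[::-1])
        avg2 = nb.hrf_average(perm, dual_schedule, "mwl2")
        np.testing.assert_allclose(avg1.hbo, avg2.hbo)

    def test_missing_level_rejected(self, single_schedule, rng):
        series = _series(rng.normal(size=single_schedule.n_samples))
        with pytest.raises(ValueError, match="absent"):
            nb.hrf_average(series, single_schedule, "mwl2")


class TestHrfModelSubstitution:
    def test_exact_model_recovers_gain(self, single_schedule):
        conv = _convolved_reference(single_schedule)
        fitted, gain = nb.hrf_model_substitution(2.0 * conv, single_schedule)
        assert gain == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(fitted, 2.0 * conv, atol=1e-9)

    def test_white_noise_gain_near_zero(self, single_schedule):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, single_schedule.n_samples)
        fitted, gain = nb.hrf_model_substitution(x, single_schedule)
        assert abs(gain) < 0.2
        assert np.ptp(fitted) < 0.2

    def test_gain_recovery_under_noise(self, single_schedule):
        rng = np.random.default_rng(3)
        conv = _convolved_reference(single_schedule)
        x = conv + rng.normal(0, 0.2, conv.size)
        _, gain = nb.hrf_model_substitution(x, single_schedule)
        assert gain == pytest.approx(1.0, rel=0.10)

    def test_all_rest_schedule_rejected(self):
        s = nb.build_default_paradigm(n_trials=0)
        with pytest.raises(ValueError, match="task"):
            nb.hrf_model_substitution(np.zeros(s.n_samples), s)
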