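"""Peri-event alignment, AUC, learning curves, omission dips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

import optopav as op
from optopav.perievent import PeriEventTensor
from optopav.simulate import kernel_peak_time, noiseless


def _flat_dff(duration_s: float, fs: float = 50.0, value: float = 0.7):
    n = int(duration_s * fs)
    return op.DffTrace(t=np.arange(n) / fs, dff=np.full(n, value), fs=fs)


def _tensor(rows: np.ndarray, fs: float, lo: float = -2.0) -> PeriEventTensor:
    rows = np.atleast_2d(rows)
    rel_t = lo + np.arange(rows.shape[1]) / fs
    return PeriEventTensor(data=rows, rel_t=rel_t, event_label=op.CUE_ONSET,
                           baseline_window_s=(-2.0, 0.0), fs=fs)


class TestAlign:
    def test_constant_trace_gives_zero_rows(self, training_config):
        sched = op.generate_schedule(training_config, seed=1)
        dff = _flat_dff(sched.end_s + 30)
        tensor = op.align(dff, sched, op.CUE_ONSET)
        assert np.allclose(tensor.data, 0.0, atol=1e-12)

    def test_laser_trial_count(self, training_config):
        sched = op.generate_schedule(training_config, seed=1)
        dff = _flat_dff(sched.end_s + 30)
        tensor = op.align(dff, sched, op.CUE_ONSET, trial_types=["laser_paired"])
        assert tensor.n_trials == 30

    def test_synthetic_row_peak_at_kernel_latency(self, omission_session,
                                                  nac_kernel):
        schedule, _, dff, _ = omission_session
        tensor = op.align(dff, schedule, op.LASER_ONSET)
        peak_t = tensor.rel_t[np.argmax(tensor.mean_trace())]
        expected = kernel_peak_time(nac_kernel.tau_rise_s, nac_kernel.tau_decay_s)
        assert peak_t == pytest.approx(expected, abs=1.5 / dff.fs)

    def test_out_of_range_trials_dropped_then_failure(self, training_config):
        sched = op.generate_schedule(training_config, seed=1)
        short = _flat_dff(sched.trials[3].cue_onset_s)  # cuts off later trials
        tensor = op.align(short, sched, op.CUE_ONSET)
        assert tensor.n_trials < len(sched)
        tiny = _flat_dff(10.0)
        with pytest.raises(op.AlignmentError):
            op.align(tiny, sched, op.CUE_ONSET)

    def test_baseline_window_must_precede_event(self, training_config):
        sched = op.generate_schedule(training_config, seed=1)
        dff = _flat_dff(sched.end_s + 30)
        with pytest.raises(op.AnalysisError):
            op.align(dff, sched, op.CUE_ONSET, baseline_window_s=(0.0, 1.0))


class TestTrialAuc:
    def test_rectangle(self):
        fs = 100.0
        rows = np.full((1, int(4 * fs) + 1), 0.5)
        tensor = _tensor(rows, fs)
        assert op.trial_auc(tensor, (0.0, 1.5))[0] == pytest.approx(0.75)

    def test_zero_rows(self):
        tensor = _tensor(np.zeros((3, 500)), fs=100.0)
        assert np.allclose(op.trial_auc(tensor, (0.0, 1.5)), 0.0)

    def test_kernel_row_matches_closed_form(self, nac_kernel):
        fs = 1000.0
        rel_t = -2.0 + np.arange(int(12 * fs)) / fs
        row = op.transient_kernel(rel_t, nac_kernel.tau_rise_s,
                                  nac_kernel.tau_decay_s)
        tensor = PeriEventTensor(data=row[None], rel_t=rel_t,
                                 event_label=op.CUE_ONSET,
                                 baseline_window_s=(-2.0, 0.0), fs=fs)
        auc = op.trial_auc(tensor, (0.0, 1.5))[0]
        expected = op.kernel_integral(nac_kernel.tau_rise_s,
                                      nac_kernel.tau_decay_s, 0.0, 1.5)
        assert auc == pytest.approx(expected, abs=1e-4)

    def test_empty_window_fails(self):
        tensor = _tensor(np.zeros((1, 500)), fs=100.0)
        with pytest.raises(op.AnalysisError):
            op.trial_auc(tensor, (1.5, 0.0))

    @given(alpha=hst.floats(-3, 3, allow_nan=False),
           beta=hst.floats(-3, 3, allow_nan=False))
    def test_linearity(self, alpha, beta):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(1, 400))
        y = rng.normal(size=(1, 400))
        fs, win = 100.0, (0.0, 1.5)
        auc = lambda rows: op.trial_auc(_tensor(rows, fs), win)[0]
        assert auc(alpha * x + beta * y) == pytest.approx(
            alpha * auc(x) + beta * auc(y), abs=1e-9)

    @given(offset=hst.floats(-5, 5, allow_nan=False))
    def test_baseline_invariance(self, offset, training_config):
        """Adding a constant to dff leaves the baselined AUC unchanged."""
        sched = op.generate_schedule(training_config, seed=2)
        rng = np.random.default_rng(3)
        n = int((sched.end_s + 30) * 50)
        base = rng.normal(0, 0.01, size=n)
        t = np.arange(n) / 50.0
        auc0 = op.trial_auc(op.align(op.DffTrace(t=t, dff=base, fs=50.0),
                                     sched, op.CUE_ONSET), (0.0, 1.5))
        auc1 = op.trial_auc(op.align(op.DffTrace(t=t, dff=base + offset, fs=50.0),
                                     sched, op.CUE_ONSET), (0.0, 1.5))
        assert np.allclose(auc0, auc1, atol=1e-10)


class TestSessionCurve:
    def _table(self, n_subj=4, n_sess=10, aucs=None):
        rows = []
        for su in range(n_subj):
            for se in range(1, n_sess + 1):
                for ty in ("laser_paired", "non_laser"):
                    rows.append({"subject": f"m{su}", "session": se,
                                 "trial_type": ty, "condition": "vehicle",
                                 "window_lo_s": 0.0, "window_hi_s": 1.5,
                                 "auc": 1.0 if aucs is None else aucs(su, se, ty)})
        return pd.DataFrame(rows)

    def test_flat_curve_and_shape(self):
        curve = op.session_curve(self._table())
        assert len(curve) == 80  # 4 subjects x 10 sessions x 2 cue types
        assert np.allclose(curve["auc_mean"], 1.0)

    def test_missing_cell_fails(self):
        table = self._table().iloc[:-1]
        with pytest.raises(op.AnalysisError, match="missing"):
            op.session_curve(table)

    def test_noiseless_laser_curve_strictly_increasing(self, omission_config,
                                                       quiet_truth, nac_kernel):
        kernel = nac_kernel
        rows = []
        for session in range(1, 11):
            sched = op.generate_schedule(op.TaskConfig(), seed=30 + session,
                                         session_index=session)
            trace, _ = op.simulate_traces(sched, kernel, quiet_truth,
                                          fs=50, seed=30 + session)
            dff = op.preprocess(trace)
            tensor = op.align(dff, sched, op.CUE_ONSET,
                              trial_types=["laser_paired"])
            rows.append(op.trial_auc(tensor, (0.0, 1.5)).mean())
        assert np.all(np.diff(rows) > 0)


class TestOmissionAuc:
    def test_zero_rows_give_zero(self):
        rel_t = -2.0 + np.arange(500) / 100.0
        tensor = PeriEventTensor(data=np.zeros((10, 500)), rel_t=rel_t,
                                 event_label=op.OMISSION_EXPECTED_LASER,
                                 baseline_window_s=(-2.0, 0.0), fs=100.0)
        assert op.omission_auc(tensor, (0.0, 2.0)) == 0.0

    def test_noiseless_dip_is_negative_with_ten_trials(self, omission_session):
        schedule, _, dff, _ = omission_session
        tensor = op.align(dff, schedule, op.OMISSION_EXPECTED_LASER)
        assert tensor.n_trials == 10
        auc = op.omission_auc(tensor, (0.0, 2.0))
        assert auc < 0

    def test_wrong_alignment_rejected(self):
        tensor = _tensor(np.zeros((2, 500)), fs=100.0)
        with pytest.raises(op.AnalysisError):
            op.omission_auc(tensor, (0.0, 2.0))
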