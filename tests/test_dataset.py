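"""Data-point extraction, grouping, protocol sampling and imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pulseinfo as pi
from pulseinfo.dataset import SLICE_MODES
from pulseinfo.preprocess import CellTrack
from pulseinfo.protocol import IntervalDistribution


def flat_track(n=200, cid=0):
    t = CellTrack(cell_id=cid, replicate_id="r0", y=np.linspace(0, 1, n),
                  cell_line=1, inhibitors=(0.0, 0.0, 0.0))
    t.s = pi.responsiveness(t.y)
    return t


class TestExtraction:
    @pytest.mark.parametrize("mode,n_diffs", [("full", 6), ("dip_only", 2),
                                              ("peak_only", 6)])
    def test_feature_width(self, mode, n_diffs):
        seq = pi.PulseSequence(np.array([5, 20, 40, 60]), total_length=100)
        ds = pi.build_dataset([flat_track()], seq, slice_mode=mode)
        assert ds.features.shape[1] == n_diffs + 6

    def test_full_mode_width_is_r_plus_six(self):
        # r = 6 differences plus log(last), s, cell line and 3 inhibitors
        seq = pi.PulseSequence(np.array([5, 20, 40]), total_length=80)
        ds = pi.build_dataset([flat_track()], seq)
        assert ds.features.shape[1] == 12

    def test_slice_beyond_track_end_dropped(self):
        seq = pi.PulseSequence(np.array([5, 20]), total_length=21)
        lo, hi = SLICE_MODES["full"]
        ds = pi.build_dataset([flat_track(n=21)], seq)
        # minute 20 is the last pulse but y[20..26] does not fit
        assert ds.last.size > 0
        assert (ds.interval == 15).all()
        assert ds.x.sum() == 0  # the k=20 diagonal point fell outside

    def test_points_start_after_first_pulse(self):
        seq = pi.PulseSequence(np.array([5, 20, 40]), total_length=80)
        ds = pi.build_dataset([flat_track()], seq)
        assert ds.x.sum() == 2  # pulses at 20 and 40; minute 5 has no last
        assert (ds.last >= 1).all()
        np.testing.assert_array_equal(ds.x == 1, ds.last == ds.interval)


class TestJointDistribution:
    def test_degenerate(self):
        d = IntervalDistribution(np.array([10]), np.array([1.0]))
        pairs, probs = pi.joint_interval_last(pi.StimulationProtocol(d))
        assert len(pairs) == 10
        np.testing.assert_allclose(probs, 0.1)

    def test_total_mass_one_and_diagonal_pulse_rate(self, exp_protocol):
        pairs, probs = pi.joint_interval_last(exp_protocol)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        diag = probs[pairs[:, 0] == pairs[:, 1]].sum()
        assert diag == pytest.approx(1.0 / exp_protocol.dist.mean_interval, abs=1e-9)


class TestSampling:
    def test_fixed_seed_identical(self, exp_sequence, exp_protocol):
        ds = pi.build_dataset([flat_track(n=exp_sequence.total_length)], exp_sequence)
        a = pi.sample_minibatch(ds, exp_protocol, 500, rng=7)
        b = pi.sample_minibatch(ds, exp_protocol, 500, rng=7)
        np.testing.assert_array_equal(a[0], b[0])

    def test_group_frequencies_match_joint(self, exp_sequence, exp_protocol):
        from scipy import stats
        ds = pi.build_dataset([flat_track(n=exp_sequence.total_length, cid=i)
                               for i in range(3)], exp_sequence)
        n = 200_000
        rows, x, last = pi.sample_minibatch(ds, exp_protocol, n, rng=0)
        pairs, probs = pi.joint_interval_last(exp_protocol)
        obs_interval = ds.interval[rows]
        # chi-square on the interval marginal (i-weighted): P(i) = i p(i)/E[L]
        support = exp_protocol.dist.support
        exp_counts = np.array([probs[pairs[:, 0] == i].sum() for i in support]) * n
        obs_counts = np.array([(obs_interval == i).sum() for i in support])
        keep = exp_counts > 5
        chi2 = ((obs_counts[keep] - exp_counts[keep]) ** 2 / exp_counts[keep]).sum()
        crit = stats.chi2.ppf(0.999, keep.sum() - 1)
        assert chi2 < crit

    def test_pulse_frequency_is_pulse_rate(self, exp_sequence, exp_protocol):
        ds = pi.build_dataset([flat_track(n=exp_sequence.total_length)], exp_sequence)
        _, x, _ = pi.sample_minibatch(ds, exp_protocol, 100_000, rng=1)
        rate = 1.0 / exp_protocol.dist.mean_interval
        assert x.mean() == pytest.approx(rate, abs=3 * np.sqrt(rate / 100_000) + 2e-3)

    def test_empty_group_borrows_with_warning(self):
        seq = pi.PulseSequence(np.array([5, 15, 25]), total_length=60)  # only L=10
        ds = pi.build_dataset([flat_track(n=60)], seq)
        d = IntervalDistribution(np.array([10, 12]), np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="groups empty"):
            rows, _, _ = pi.sample_minibatch(ds, pi.StimulationProtocol(d), 200, rng=0)
        assert rows.size == 200

    def test_empty_dataset_raises(self, exp_protocol):
        seq = pi.PulseSequence(np.array([5, 20]), total_length=40)
        ds = pi.build_dataset([], seq)
        with pytest.raises(ValueError):
            pi.sample_minibatch(ds, exp_protocol, 10, rng=0)


class TestImputation:
    def test_short_last_kept(self):
        assert pi.impute_long_interval(60, 5) == (35, 5.0)

    def test_short_time_to_next_pulse_kept(self):
        i, l = pi.impute_long_interval(60, 55)
        assert (i, l) == (35, 30.0)  # 35 - (60 - 55)

    def test_mid_interval_compression(self):
        i, l = pi.impute_long_interval(60, 30)
        assert i == 35
        assert l == pytest.approx(10 + 20 * (35 - 20) / (60 - 20))  # 17.5

    def test_continuity_across_branches(self):
        # adjacent formulas agree at last = 10 and at interval - last = 10
        for interval in range(36, 91):
            _, at10 = pi.impute_long_interval(interval, 10)
            assert at10 == pytest.approx(10.0, abs=1e-9)
            last_edge = interval - 10
            _, a = pi.impute_long_interval(interval, last_edge)
            assert a == pytest.approx(25.0, abs=1e-9)

    @given(st.integers(36, 90), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_branch_preservation(self, interval, data):
        last = data.draw(st.integers(1, interval))
        _, lstar = pi.impute_long_interval(interval, last)
        assert 1 <= lstar <= 35
        assert (lstar < 10) == (last < 10)

    def test_requires_long_interval(self):
        with pytest.raises(ValueError):
            pi.impute_long_interval(35, 10)


class TestStandardization:
    def test_zero_mean_unit_sd(self, exp_sequence):
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(3):
            t = flat_track(n=exp_sequence.total_length, cid=i)
            t.y = rng.normal(0, 1, exp_sequence.total_length)
            t.s = pi.responsiveness(t.y)
            tracks.append(t)
        ds = pi.standardize_features(pi.build_dataset(tracks, exp_sequence))
        z = ds.standardized()
        varying = ds.features.std(axis=0) > 1e-12
        np.testing.assert_allclose(z.mean(axis=0)[varying], 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0)[varying], 1.0, atol=1e-9)

    def test_constant_column_centered_not_scaled(self, exp_sequence):
        with pytest.warns(UserWarning, match="zero-variance"):
            ds = pi.standardize_features(
                pi.build_dataset([flat_track(n=exp_sequence.total_length)],
                                 exp_sequence))
        j = ds.names.index("cell_line")
        z = ds.standardized()
        np.testing.assert_allclose(z[:, j], 0.0, atol=1e-12)

    def test_reapplication_idempotent(self, exp_sequence):
        ds = pi.standardize_features(
            pi.build_dataset([flat_track(n=exp_sequence.total_length)], exp_sequence))
        np.testing.assert_array_equal(ds.standardized(), ds.standardized())
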