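"""Diagnostics: update tables, refractory time, neighbours, condition tables."""

import numpy as np
import pandas as pd
import pytest

import pulseinfo as pi
from pulseinfo.report import diagonal_update_curve


class TestMeanLogitUpdate:
    def test_counts_match_group_sizes(self, mixture_run, exp_protocol):
        ds = mixture_run["dataset"]
        tbl = pi.mean_logit_update(mixture_run["model"], ds)
        for _, row in tbl.iterrows():
            assert row["count"] == len(ds.groups[(row["interval"], row["last"])])

    def test_diagonal_positive_off_diagonal_negative_at_long_last(
            self, mixture_run, exp_protocol):
        tbl = pi.mean_logit_update(mixture_run["model"], mixture_run["dataset"])
        diag = diagonal_update_curve(tbl)
        # detectable pulses after long recovery: strongly positive updates
        assert diag[diag["interval"] >= 20]["mean_update"].mean() > 1.0
        off = tbl[(tbl["interval"] != tbl["last"]) & (tbl["last"] >= 20)]
        assert off["mean_update"].mean() < 0.0

    def test_update_table_reproduces_population_bitrate(self, mixture_run,
                                                        exp_protocol):
        """Count-weighted mean of per-group pointwise information equals the
        population bitrate (diagnostic/estimator consistency)."""
        tbl = pi.mean_logit_update(mixture_run["model"], mixture_run["dataset"],
                                   exp_protocol)
        pooled = 60.0 * np.average(tbl["mean_info"], weights=tbl["count"])
        assert pooled == pytest.approx(mixture_run["report"].population_bitrate,
                                       abs=1e-9)

    def test_no_information_data_gives_near_zero_updates(self, exp_sequence,
                                                         exp_protocol):
        from tests.test_classifier import _toy_model
        from tests.test_dataset import flat_track
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(4):
            t = flat_track(n=exp_sequence.total_length, cid=i)
            t.y = rng.normal(0, 0.1, exp_sequence.total_length)
            t.s = pi.responsiveness(t.y)
            tracks.append(t)
        ds = pi.standardize_features(pi.build_dataset(tracks, exp_sequence))
        model = _toy_model(d=12)  # zero head: u identically 0
        model.stats = ds.stats
        tbl = pi.mean_logit_update(model, ds)
        np.testing.assert_allclose(tbl["mean_update"], 0.0, atol=1e-12)


class TestEffectiveRefractoryTime:
    def _curve(self, intervals, updates):
        return pd.DataFrame({"interval": intervals, "mean_update": updates})

    def test_step_curve(self):
        c = self._curve([5, 9, 10, 15, 20, 25, 30, 35],
                        [0.0, 0.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        assert pi.effective_refractory_time(c) == pytest.approx(10.0, abs=0.5)

    def test_flat_positive_curve_below_support(self):
        c = self._curve([5, 10, 15, 20, 25], [1.5, 1.5, 1.5, 1.5, 1.5])
        assert pi.effective_refractory_time(c) == "below support"

    def test_interpolated_crossing(self):
        c = self._curve([5, 10, 15, 20, 25, 30, 35],
                        [0.0, 1.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        assert pi.effective_refractory_time(c) == pytest.approx(10.0)

    def test_non_positive_asymptote_flagged(self):
        c = self._curve([5, 10, 15, 20], [0.0, -0.1, -0.2, -0.1])
        assert np.isnan(pi.effective_refractory_time(c))

    def test_trained_decoder_refractory_near_recovery_half_time(self, mixture_run,
                                                                exp_protocol):
        # the generator's peak recovery half-time is 8.5 min; the decoder's
        # half-credibility interval should land in that neighbourhood
        tbl = pi.mean_logit_update(mixture_run["model"], mixture_run["dataset"])
        t = pi.effective_refractory_time(diagonal_update_curve(tbl))
        assert isinstance(t, float)
        assert 5.0 <= t <= 15.0


class TestNeighborProbability:
    def test_all_transmitting(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, (20, 2))
        tbl = pi.neighbor_transmission_probability(pos, np.ones(20, bool), k_max=3)
        assert (tbl["p_transmitting"] == 1.0).all()

    def test_collinear_toy_by_hand(self):
        """Cells at x = 0, 1, 2.2, 3.5 with flags T, T, N, N.
        k=1 neighbours: 0->1(T), 1->0(T), 2.2->1(T), 3.5->2.2(N);
        k=2 neighbours: 0->2.2(N), 1->2.2(N), 2.2->3.5(N), 3.5->1(T)."""
        pos = np.array([[0.0, 0], [1.0, 0], [2.2, 0], [3.5, 0]])
        flags = np.array([True, True, False, False])
        tbl = pi.neighbor_transmission_probability(pos, flags, k_max=2)
        get = lambda a, k: tbl[(tbl["anchor"] == a) & (tbl["k"] == k)][
            "p_transmitting"].iloc[0]
        assert get("transmitting", 1) == pytest.approx(1.0)
        assert get("non-transmitting", 1) == pytest.approx(0.5)
        assert get("transmitting", 2) == pytest.approx(0.0)
        assert get("non-transmitting", 2) == pytest.approx(0.5)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            pi.neighbor_transmission_probability(np.zeros((3, 2)),
                                                 np.ones(3, bool), k_max=3)

    def test_shuffled_labels_flat_in_k(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 1000, (500, 2))
        flags = rng.random(500) < 0.6
        tbl = pi.neighbor_transmission_probability(pos, flags, k_max=8)
        frac = flags.mean()
        for _, row in tbl.iterrows():
            n = row["n_anchors"]
            assert abs(row["p_transmitting"] - frac) < 3.5 * np.sqrt(
                frac * (1 - frac) / n) + 0.02


class TestConditionSummary:
    def _fake_report(self, b, frac=0.5):
        import pandas as pd
        from pulseinfo.bitrate import BitrateReport
        tbl = pd.DataFrame({"cell_id": [0], "replicate_id": ["r"], "b_j": [b],
                            "w_j": [10], "transmitting": [True]})
        return BitrateReport(cell_table=tbl, population_bitrate=b,
                             total_points=10, threshold=0.0,
                             fraction_transmitting=frac, se_bitrate=0.1)

    def test_single_replicate_sem_missing(self):
        out = pi.condition_summary({"c": [self._fake_report(5.0)]})
        assert np.isnan(out["population_bitrate_sem"].iloc[0])
        assert out["population_bitrate"].iloc[0] == pytest.approx(5.0)

    def test_identical_replicates_zero_sem(self):
        out = pi.condition_summary({"c": [self._fake_report(5.0)] * 3})
        assert out["population_bitrate_sem"].iloc[0] == pytest.approx(0.0)

    def test_transmitting_bitrate_ratio_identity(self):
        """On a toy report the transmitting-subpopulation bitrate equals the
        population bitrate divided by the weighted transmitting share."""
        import pandas as pd
        from pulseinfo.bitrate import BitrateReport
        tbl = pd.DataFrame({
            "cell_id": [0, 1, 2, 3], "replicate_id": ["r"] * 4,
            "b_j": [0.0, 0.0, 6.0, 10.0], "w_j": [1, 1, 1, 1],
            "transmitting": [False, False, True, True]})
        rep = BitrateReport(cell_table=tbl, population_bitrate=4.0,
                            total_points=4, threshold=6.0,
                            fraction_transmitting=0.5, se_bitrate=0.0)
        # non-transmitting cells average exactly 0 here, so b = frac * b_tx
        assert rep.transmitting_bitrate == pytest.approx(
            rep.population_bitrate / rep.fraction_transmitting)
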