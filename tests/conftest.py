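"""Shared fixtures: the study protocol and a mid-size simulated experiment.

The expensive fixtures (simulation + decoder training) are session-scoped
and shared across test modules; tests treat them as read-only.
"""

import warnings

import pytest

import pulseinfo as pi

warnings.filterwarnings("ignore", message="zero-variance features")
warnings.filterwarnings("ignore", message=r"\d+ \(interval, last\) groups empty")


@pytest.fixture(scope="session")
def gamma_dist():
    return pi.build_gamma_interval_distribution(4, 5, 5, 35)


@pytest.fixture(scope="session")
def exp_sequence(gamma_dist):
    """Reconstruction of the ~17-h experimental pulse sequence."""
    return pi.realize_pulse_sequence(gamma_dist, 1020)


@pytest.fixture(scope="session")
def exp_protocol(exp_sequence):
    """Protocol matching the realized sequence's empirical interval counts."""
    return pi.StimulationProtocol(exp_sequence.empirical_distribution())


@pytest.fixture(scope="session")
def mixture_run(exp_sequence, exp_protocol):
    """High-SNR two-population experiment: simulate, preprocess, train, score.

    200 cells, 65% transmitting, full-length sequence; used by the
    parameter-recovery, diagnostics and estimator-identity tests.
    """
    cfg = pi.SimulationConfig(
        n_cells=200, fraction_transmitting=0.65, seed=7,
        noise_sd=0.03, measurement_noise_sd=0.01, peak_gain=0.5,
    )
    sim = pi.simulate_population(cfg, exp_sequence)
    tracks = pi.filter_short_tracks(
        pi.build_tracks(sim.table, cfg.background, sim.seq))
    ds = pi.standardize_features(pi.build_dataset(tracks, sim.seq))
    model = pi.train(ds, exp_protocol, pi.TrainConfig(steps=1000, batch_size=8000, seed=0))
    report = pi.evaluate_bitrate(model, ds, exp_protocol)
    return {"sim": sim, "tracks": tracks, "dataset": ds, "model": model,
            "report": report, "config": cfg}
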