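"""Synthetic single-cell reporter trajectories under pulsatile stimulation.

Emulates the statistical structure of optogenetic receptor -> kinase
translocation reporter (KTR) experiments: each light pulse evokes, in
responsive cells, a fast nuclear-import "dip" (phosphatase channel, ~2 min
after the pulse) followed by a larger nuclear-export "peak" (kinase channel,
~7 min after the pulse).  The peak amplitude recovers with the time since
the previous pulse (refractory behaviour with a configurable half-time,
default 8.5 min); the dip channel recovers much faster and is effectively
interval-independent.  Populations are mixtures of transmitting and
non-transmitting cells, optionally spatially clustered, with autocorrelated
noise and slow baseline drift.

The generator emits *raw* track tables (nuclear intensity, frame mean,
receptor summary, positions, condition covariates) by inverting the track
standardization map, so the full preprocessing path is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import PulseSequence

__all__ = [
    "CellPhenotype",
    "SimulationConfig",
    "SimulationResult",
    "response_kernel",
    "recovery_fraction",
    "simulate_population",
    "assign_positions",
]

RAW_COLUMNS = [
    "replicate_id", "cell_id", "minute", "nuclear_mean", "frame_mean",
    "receptor_mean", "pos_x", "pos_y", "cell_line",
    "alki_um", "meki_um", "calci_um",
]


@dataclass(frozen=True)
class CellPhenotype:
    """Per-cell response parameters (trajectory units are the standardized y)."""

    transmitting: bool
    peak_gain: float = 0.35
    dip_gain: float = 0.12
    refractory_tau: float = 8.5       # peak-amplitude recovery half-time, min
    dip_refractory_tau: float = 1.5   # dip channel recovers almost instantly
    noise_sd: float = 0.05            # AR(1) process noise
    baseline_drift_sd: float = 0.004  # per-minute random-walk drift
    receptor_level: float = 1000.0

    def __post_init__(self):
        for name in ("peak_gain", "dip_gain", "refractory_tau", "dip_refractory_tau",
                     "noise_sd", "baseline_drift_sd", "receptor_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.transmitting and (self.peak_gain != 0 or self.dip_gain != 0):
            raise ValueError("non-transmitting phenotype must have zero gains")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated replicate."""

    n_cells: int = 200
    fraction_transmitting: float = 0.65
    cell_line: str = "BEAS2B"          # "BEAS2B" or "STE1"
    alki_um: float = 0.0
    meki_um: float = 0.0
    calci_um: float = 0.0
    # response kernel timing/shape (gamma-shaped lobes; minutes)
    dip_time: float = 2.0
    peak_time: float = 7.0
    dip_shape: float = 3.0
    peak_shape: float = 4.0
    recovery_half_time: float = 8.5
    dip_recovery_half_time: float = 1.5
    # population-level gain/noise scales
    peak_gain: float = 0.35
    dip_gain: float = 0.12
    gain_cv: float = 0.25              # log-normal cell-to-cell gain spread
    ste1_peak_scale: float = 0.2       # ~5x weaker response in STE1-like cells
    noise_sd: float = 0.05
    noise_rho: float = 0.5             # AR(1) autocorrelation of process noise
    measurement_noise_sd: float = 0.02
    baseline_drift_sd: float = 0.004
    clustering: float = 0.0
    warmup_min: int = 90               # unstimulated imaging before the first pulse
    tail_min: int = 15                 # imaging continued past the last pulse
    background: float = 100.0
    frame_mean: float = 1000.0
    replicate_id: str = "sim0"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.fraction_transmitting <= 1.0:
            raise ValueError("fraction_transmitting must be in [0, 1]")


@dataclass
class SimulationResult:
    table: pd.DataFrame          # raw track table, one row per cell-minute
    phenotypes: pd.DataFrame     # ground truth per cell
    seq: PulseSequence           # pulse minutes in the table's minute coordinates
    config: SimulationConfig


def recovery_fraction(interval: float, half_time: float) -> float:
    """Saturating amplitude recovery, 0.5 at ``interval == half_time``."""
    if half_time <= 0:
        return 1.0
    return 1.0 - 0.5 ** (interval / half_time)


def _gamma_bump(t: np.ndarray, mode: float, shape: float) -> np.ndarray:
    """Gamma-density-shaped lobe normalized to max 1 at ``t == mode``."""
    theta = mode / (shape - 1.0)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / mode) ** (shape - 1.0) * np.exp((mode - t[pos]) / theta)
    return out


def response_kernel(
    phenotype: CellPhenotype,
    t_since_pulse,
    preceding_interval: float,
    *,
    dip_time: float = 2.0,
    peak_time: float = 7.0,
    dip_shape: float = 3.0,
    peak_shape: float = 4.0,
) -> np.ndarray:
    """Trajectory increment evoked by one pulse.

    Negative dip lobe centered at ``dip_time`` plus positive peak lobe
    centered at ``peak_time``; the peak is scaled by the refractory recovery
    at the preceding interval while the dip recovers with its own (much
    shorter) half-time and is effectively interval-independent.
    """
    t = np.atleast_1d(np.asarray(t_since_pulse, dtype=float))
    if np.any(t < 0):
        raise ValueError("t_since_pulse must be >= 0")
    dip = -phenotype.dip_gain * recovery_fraction(
        preceding_interval, phenotype.dip_refractory_tau
    ) * _gamma_bump(t, dip_time, dip_shape)
    peak = phenotype.peak_gain * recovery_fraction(
        preceding_interval, phenotype.refractory_tau
    ) * _gamma_bump(t, peak_time, peak_shape)
    out = dip + peak
    return out if np.ndim(t_since_pulse) else float(out[0])


def assign_positions(n_cells, labels, clustering, seed):
    """Place cells in a 1 mm^2 field; optionally spatially cluster the labels.

    With ``clustering == 0`` positions are uniform and labels are returned
    unchanged.  With ``clustering > 0`` the labels are reassigned by
    thresholding a smoothed Gaussian random field (plus iid noise scaled by
    1/clustering) at the quantile matching the original label count, so the
    transmitting fraction is preserved while labels become spatially
    autocorrelated.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != n_cells:
        raise ValueError("need one label per cell")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1000.0, size=(n_cells, 2))
    if clustering <= 0 or n_cells < 2:
        return positions, labels.copy()
    n_anchors = max(8, n_cells // 20)
    anchors = rng.uniform(0.0, 1000.0, size=(n_anchors, 2))
    weights = rng.standard_normal(n_anchors)
    length = 150.0  # field correlation length, um
    d2 = ((positions[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    fld = (np.exp(-d2 / (2 * length**2)) * weights).sum(axis=1)
    fld = (fld - fld.mean()) / (fld.std() + 1e-12)
    score = fld + rng.standard_normal(n_cells) / clustering
    n_true = int(labels.sum())
    new = np.zeros(n_cells, dtype=bool)
    if n_true > 0:
        new[np.argsort(score)[-n_true:]] = True
    return positions, new


def _condition_gains(config: SimulationConfig) -> tuple[float, float]:
    """Population-level (peak_gain, dip_gain) under the condition covariates."""
    peak, dip = config.peak_gain, config.dip_gain
    if config.cell_line == "STE1":
        # fusion-oncoprotein suppression: no response unless the ALK inhibitor
        # is applied, and no fast dip channel at all; the restored peak is
        # several-fold weaker than in the non-cancerous line
        dip = 0.0
        peak = peak * config.ste1_peak_scale if config.alki_um > 0 else 0.0
    if config.meki_um > 0:
        peak = 0.0
    if config.calci_um > 0:
        dip = 0.0
    return peak, dip


def simulate_population(config: SimulationConfig, seq: PulseSequence) -> SimulationResult:
    """Simulate one replicate of raw tracks stimulated with ``seq``.

    ``seq`` is given in stimulation coordinates (first pulse at its stated
    minute); the emitted table prepends ``warmup_min`` unstimulated minutes
    and appends ``tail_min`` minutes after the end of the sequence.  The
    returned :class:`SimulationResult.seq` is expressed in table coordinates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    pulses_abs = np.asarray(seq.pulse_minutes) + config.warmup_min
    n_minutes = config.warmup_min + seq.total_length + config.tail_min
    seq_abs = PulseSequence(pulses_abs, total_length=n_minutes)

    transmitting = rng.random(n) < config.fraction_transmitting
    positions, transmitting = assign_positions(
        n, transmitting, config.clustering, rng.integers(2**31)
    )
    base_peak, base_dip = _condition_gains(config)
    gain_mult = np.exp(rng.normal(0.0, config.gain_cv, size=n))
    receptor = np.exp(rng.normal(np.log(1000.0), 0.4, size=n))

    # preceding interval of each pulse (first pulse treated as fully recovered)
    intervals = np.diff(pulses_abs)
    prec = np.concatenate([[1e9], intervals]).astype(float)

    minutes = np.arange(n_minutes)
    frame = np.full(n_minutes, config.frame_mean, dtype=float)

    cell_line01 = 1 if config.cell_line == "BEAS2B" else 0
    records_y = np.empty((n, n_minutes))
    pheno_rows = []
    for j in range(n):
        is_tx = bool(transmitting[j])
        pg = base_peak * gain_mult[j] if is_tx else 0.0
        dg = base_dip * gain_mult[j] if is_tx else 0.0
        phen = CellPhenotype(
            transmitting=is_tx, peak_gain=pg, dip_gain=dg,
            refractory_tau=config.recovery_half_time,
            dip_refractory_tau=config.dip_recovery_half_time,
            noise_sd=config.noise_sd,
            baseline_drift_sd=config.baseline_drift_sd,
            receptor_level=receptor[j],
        )
        y = np.full(n_minutes, 0.5 + 0.1 * rng.standard_normal())
        if config.baseline_drift_sd > 0:
            y += np.cumsum(rng.normal(0.0, config.baseline_drift_sd, n_minutes))
        if is_tx:
            for p, L in zip(pulses_abs, prec):
                hi = min(p + 40, n_minutes)  # lobes are negligible 40 min out
                t = minutes[p:hi] - p
                y[p:hi] += response_kernel(
                    phen, t, L,
                    dip_time=config.dip_time, peak_time=config.peak_time,
                    dip_shape=config.dip_shape, peak_shape=config.peak_shape,
                )
        if config.noise_sd > 0:
            eps = rng.normal(0.0, config.noise_sd, n_minutes)
            rho = config.noise_rho
            ar = signal.lfilter([1.0], [1.0, -rho], eps)
            y += ar * np.sqrt(1 - rho**2)  # unit-variance-normalized AR(1)
        if config.measurement_noise_sd > 0:
            y += rng.normal(0.0, config.measurement_noise_sd, n_minutes)
        records_y[j] = y
        pheno_rows.append({
            "cell_id": j, "transmitting": is_tx, "peak_gain": pg, "dip_gain": dg,
            "receptor_mean": receptor[j], "pos_x": positions[j, 0],
            "pos_y": positions[j, 1],
        })

    # invert the standardization map: y = -log((nuc - bg) / (frame - bg))
    nuclear = config.background + (frame[None, :] - config.background) * np.exp(-records_y)

    table = pd.DataFrame({
        "replicate_id": np.repeat(config.replicate_id, n * n_minutes),
        "cell_id": np.repeat(np.arange(n), n_minutes),
        "minute": np.tile(minutes, n),
        "nuclear_mean": nuclear.ravel(),
        "frame_mean": np.tile(frame, n),
        "receptor_mean": np.repeat(receptor, n_minutes),
        "pos_x": np.repeat(positions[:, 0], n_minutes),
        "pos_y": np.repeat(positions[:, 1], n_minutes),
        "cell_line": cell_line01,
        "alki_um": config.alki_um,
        "meki_um": config.meki_um,
        "calci_um": config.calci_um,
    })
    return SimulationResult(
        table=table, phenotypes=pd.DataFrame(pheno_rows), seq=seq_abs, config=config
    )
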