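"""Track standardization, filtering and per-cell summary statistics.

The normalized reporter trajectory of a cell is

    y_k = -log[(nuclear_k - background) / (frame_k - background)]

where ``nuclear_k`` is the mean nuclear reporter intensity, ``frame_k`` the
mean intensity of the whole frame (correcting illumination and global
fluorescence shifts) and ``background`` a per-replicate scalar.  Kinase
activity exports the reporter from the nucleus, so y rises on activation
(peak) and falls when the phosphatase channel imports it (dip).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import PulseSequence

__all__ = [
    "CellTrack",
    "standardize_track",
    "build_tracks",
    "filter_short_tracks",
    "preselect_by_receptor",
    "responsiveness",
    "baseline_table",
    "response_amplitude",
    "amplitude_by_interval",
    "write_qc_report",
]

# preselection windows in sigma units around the track-length-weighted mean
RECEPTOR_WINDOWS = {1: (0.0, 3.0), 0: (-0.5, 2.0)}  # cell_line 1 = BEAS-2B-like


@dataclass
class CellTrack:
    """One cell's standardized trajectory and covariates."""

    cell_id: int
    replicate_id: str
    y: np.ndarray                    # standardized trajectory, NaN = missing
    cell_line: int                   # 0 = STE-1-like, 1 = BEAS-2B-like
    inhibitors: tuple[float, float, float]   # (ALKi, MEKi, CALCi) in uM
    receptor_summary: float = np.nan  # mean receptor intensity at pulse minutes
    position: tuple[float, float] = (np.nan, np.nan)
    s: float = np.nan                # responsiveness, filled by `responsiveness`
    w: int = 0                       # usable data points, filled at dataset build

    def __len__(self) -> int:
        return len(self.y)


def standardize_track(nuclear_series, frame_series, background: float) -> np.ndarray:
    """Normalized trajectory; minutes with non-positive intensities become NaN."""
    nuc = np.asarray(nuclear_series, dtype=float) - background
    frm = np.asarray(frame_series, dtype=float) - background
    y = np.full(nuc.shape, np.nan)
    ok = (nuc > 0) & (frm > 0)
    y[ok] = -np.log(nuc[ok] / frm[ok])
    return y


def build_tracks(
    table: pd.DataFrame,
    background: float | dict[str, float],
    seq: PulseSequence | None = None,
) -> list[CellTrack]:
    """Standardize a raw track table into :class:`CellTrack` objects.

    ``background`` may be a scalar or a per-replicate mapping.  When ``seq``
    is given (table minute coordinates), the receptor summary is the mean
    receptor intensity at pulse minutes; otherwise over the whole track.
    """
    tracks = []
    pulse_minutes = None if seq is None else np.asarray(seq.pulse_minutes)
    for (rep, cid), g in table.groupby(["replicate_id", "cell_id"], sort=True):
        g = g.sort_values("minute")
        bg = background[rep] if isinstance(background, dict) else background
        y = standardize_track(g["nuclear_mean"].values, g["frame_mean"].values, bg)
        minutes = g["minute"].values
        rec = g["receptor_mean"].values
        if pulse_minutes is not None:
            at_pulse = np.isin(minutes, pulse_minutes)
            receptor = float(rec[at_pulse].mean()) if at_pulse.any() else float(rec.mean())
        else:
            receptor = float(rec.mean())
        tracks.append(CellTrack(
            cell_id=int(cid), replicate_id=str(rep), y=y,
            cell_line=int(g["cell_line"].iloc[0]),
            inhibitors=(float(g["alki_um"].iloc[0]), float(g["meki_um"].iloc[0]),
                        float(g["calci_um"].iloc[0])),
            receptor_summary=receptor,
            position=(float(g["pos_x"].iloc[0]), float(g["pos_y"].iloc[0])),
        ))
    for t in tracks:
        t.s = responsiveness(t.y)
    return tracks


def filter_short_tracks(tracks, min_length: int = 180):
    """Drop tracks shorter than ``min_length`` minutes (3 h default, inclusive)."""
    return [t for t in tracks if len(t) >= min_length]


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    # population (denominator n) convention, weights = track lengths
    w = weights / weights.sum()
    mu = float(np.dot(w, values))
    var = float(np.dot(w, (values - mu) ** 2))
    return mu, np.sqrt(var)


def preselect_by_receptor(tracks, windows: dict[int, tuple[float, float]] | None = None):
    """Keep tracks whose receptor summary lies in a per-replicate expression window.

    Per replicate, mu and sigma are the track-length-weighted mean and
    standard deviation of the receptor summaries; the retained window is
    [mu + a*sigma, mu + b*sigma] with (a, b) depending on the cell line
    ((0, 3) for BEAS-2B-like, (-0.5, 2) for STE-1-like).
    """
    windows = RECEPTOR_WINDOWS if windows is None else windows
    kept = []
    by_rep: dict[str, list[CellTrack]] = {}
    for t in tracks:
        by_rep.setdefault(t.replicate_id, []).append(t)
    for rep, ts in by_rep.items():
        if len(ts) == 1:
            warnings.warn(f"replicate {rep}: single track, preselection skipped")
            kept.extend(ts)
            continue
        vals = np.array([t.receptor_summary for t in ts])
        wts = np.array([float(len(t)) for t in ts])
        mu, sd = _weighted_mean_sd(vals, wts)
        for t in ts:
            a, b = windows[t.cell_line]
            if mu + a * sd <= t.receptor_summary <= mu + b * sd:
                kept.append(t)
    return kept


def responsiveness(y: np.ndarray, lag: int = 7) -> float:
    """s = Std over k of (y_k - y_{k+lag}), population (n) denominator.

    The standard deviation is taken across *all* timepoints, not only pulse
    minutes, so it is independent of pulse timing.  Returns NaN if fewer
    than ``lag + 1`` usable minutes; a single valid difference gives 0.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < lag + 1:
        return np.nan
    d = y[:-lag] - y[lag:]
    d = d[~np.isnan(d)]
    if d.size == 0:
        return np.nan
    return float(np.std(d))


def baseline_table(tracks, seq: PulseSequence, offset: int = 7) -> dict[int, float]:
    """Population drift correction for response amplitudes.

    For each interval length L, the mean over all tracks and all pulses p
    that are followed by an at-least-(L + offset)-minute interval of
    y[p + L + offset] - y[p + L]: the typical trajectory change over
    ``offset`` minutes at phase L after a pulse, absent a new pulse.
    """
    pm = np.asarray(seq.pulse_minutes)
    next_gap = np.diff(pm)
    lengths = np.unique(next_gap)
    sums: dict[int, float] = {int(l): 0.0 for l in lengths}
    counts: dict[int, int] = {int(l): 0 for l in lengths}
    for L in lengths:
        L = int(L)
        # eligible pulses: followed by >= L + offset minutes without a pulse
        elig = pm[:-1][next_gap >= L + offset]
        if pm.size:  # the last pulse is eligible if the track extends far enough
            elig = np.concatenate([elig, pm[-1:]])
        for t in tracks:
            idx = elig[elig + L + offset < len(t)]
            d = t.y[idx + L + offset] - t.y[idx + L]
            d = d[~np.isnan(d)]
            sums[L] += float(d.sum())
            counts[L] += d.size
    return {L: sums[L] / counts[L] for L in sums if counts[L] > 0}


def response_amplitude(
    track: CellTrack,
    seq: PulseSequence,
    pulse_minute: int,
    baseline: dict[int, float],
    offset: int = 7,
) -> float:
    """Drift-corrected response to the pulse at ``pulse_minute``.

    Raw amplitude y[t + offset] - y[t], minus the population baseline for
    the interval L preceding this pulse.  NaN if the window is missing or
    the pulse has no preceding interval.
    """
    pm = np.asarray(seq.pulse_minutes)
    i = np.searchsorted(pm, pulse_minute)
    if i >= len(pm) or pm[i] != pulse_minute:
        raise ValueError(f"{pulse_minute} is not a pulse minute")
    if i == 0:
        return np.nan
    L = int(pm[i] - pm[i - 1])
    if pulse_minute + offset >= len(track) or L not in baseline:
        return np.nan
    raw = track.y[pulse_minute + offset] - track.y[pulse_minute]
    return float(raw - baseline[L])


def amplitude_by_interval(tracks, seq: PulseSequence, offset: int = 7) -> pd.DataFrame:
    """Mean corrected response amplitude grouped by the preceding interval."""
    base = baseline_table(tracks, seq, offset=offset)
    pm = np.asarray(seq.pulse_minutes)
    rows = []
    for i in range(1, len(pm)):
        L = int(pm[i] - pm[i - 1])
        for t in tracks:
            a = response_amplitude(t, seq, int(pm[i]), base, offset=offset)
            if not np.isnan(a):
                rows.append({"interval": L, "amplitude": a})
    df = pd.DataFrame(rows)
    return (df.groupby("interval")["amplitude"].agg(["mean", "sem", "count"])
            .reset_index())


def write_qc_report(path, counts: dict) -> None:
    """Counts of tracks removed by each filter, as JSON."""
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2)
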