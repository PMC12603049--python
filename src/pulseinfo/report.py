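"""Interval-resolved diagnostics and population summaries.

Covers the decoder-side diagnostics (mean logit update by (interval, last),
effective refractory time from the diagonal update curve), the spatial
neighbour analysis of transmitting cells, and condition-level tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bitrate import BitrateReport, pointwise_information
from .classifier import PulseClassifier, posterior_probability
from .dataset import PulseDataset
from .protocol import StimulationProtocol

__all__ = [
    "mean_logit_update",
    "diagonal_update_curve",
    "effective_refractory_time",
    "neighbor_transmission_probability",
    "condition_summary",
]


def mean_logit_update(model: PulseClassifier, dataset: PulseDataset,
                      protocol: StimulationProtocol | None = None) -> pd.DataFrame:
    """Mean u_Bayes per (interval, last) group.

    Diagonal entries (last == interval) are the pulse minutes; positive
    means the decoder consistently raises the pulse probability above the
    prior there.  Off-diagonal entries at detectable lasts are negative:
    the absence of a response argues against a pulse.  With a ``protocol``
    the per-group mean prior-referenced pointwise information (bits) is
    added; its count-weighted mean over groups reproduces the population
    bitrate.
    """
    u = model.forward(dataset.standardized())
    info = None
    if protocol is not None:
        prior = protocol.prior(dataset.last)
        post = posterior_probability(u, prior)
        info = pointwise_information(dataset.x, prior, post)
    rows = []
    for (i, l), idx in sorted(dataset.groups.items()):
        row = {"interval": i, "last": l,
               "mean_update": float(u[idx].mean()), "count": len(idx)}
        if info is not None:
            row["mean_info"] = float(info[idx].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def diagonal_update_curve(table: pd.DataFrame) -> pd.DataFrame:
    """u(interval): mean update at last == interval (actual pulses)."""
    d = table[table["interval"] == table["last"]]
    return d.sort_values("interval")[["interval", "mean_update", "count"]]


def effective_refractory_time(curve: pd.DataFrame, plateau_quantile: float = 0.75):
    """Interval at which pulse detectability reaches half its asymptote.

    The asymptote is the mean update over the plateau (top quartile of
    tested intervals by default).  Returns the linearly interpolated
    interval of the first upward crossing of half the asymptote, the string
    ``"below support"`` if the curve already exceeds it at the shortest
    tested interval, or NaN (flagged) if the asymptote is not positive.
    """
    curve = curve.sort_values("interval")
    iv = curve["interval"].to_numpy(dtype=float)
    up = curve["mean_update"].to_numpy(dtype=float)
    if len(iv) < 3:
        raise ValueError("need a curve over at least 3 intervals")
    plateau = up[iv >= np.quantile(iv, plateau_quantile)]
    asym = float(plateau.mean())
    if asym <= 0:
        return np.nan
    half = asym / 2.0
    if up[0] >= half:
        return "below support"
    above = np.flatnonzero(up >= half)
    if above.size == 0:
        return np.nan
    i = above[0]
    x0, x1, y0, y1 = iv[i - 1], iv[i], up[i - 1], up[i]
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def neighbor_transmission_probability(positions, transmitting, k_max: int = 10
                                      ) -> pd.DataFrame:
    """P(kth nearest neighbour transmits | anchor group), k = 1..k_max.

    Euclidean distances, self excluded; exact ties are broken by cell index
    (the order of ``positions``).  Returns one row per (anchor group, k).
    """
    positions = np.asarray(positions, dtype=float)
    flags = np.asarray(transmitting, dtype=bool)
    n = len(positions)
    if n < k_max + 1:
        raise ValueError("need at least k_max + 1 cells")
    tree = cKDTree(positions)
    # k_max + 1 because the nearest hit of each anchor is itself
    _, idx = tree.query(positions, k=k_max + 1)
    rows = []
    for anchor_tx in (True, False):
        anchors = np.flatnonzero(flags == anchor_tx)
        if anchors.size == 0:
            continue
        neigh = idx[anchors, 1:]  # drop self
        for k in range(1, k_max + 1):
            rows.append({
                "anchor": "transmitting" if anchor_tx else "non-transmitting",
                "k": k,
                "p_transmitting": float(flags[neigh[:, k - 1]].mean()),
                "n_anchors": int(anchors.size),
            })
    return pd.DataFrame(rows)


def condition_summary(reports: dict[str, list[BitrateReport]],
                      amplitudes: dict[str, list[float]] | None = None
                      ) -> pd.DataFrame:
    """Across-replicate mean +/- SEM per condition.

    ``reports`` maps a condition label to its per-replicate bitrate reports;
    ``amplitudes`` optionally supplies per-replicate mean response
    amplitudes.  SEM is reported as NaN for single replicates.
    """
    rows = []
    for cond, reps in reports.items():
        pop = np.array([r.population_bitrate for r in reps], dtype=float)
        frac = np.array([r.fraction_transmitting for r in reps], dtype=float)
        tx = np.array([r.transmitting_bitrate for r in reps], dtype=float)
        amp = (np.array(amplitudes[cond], dtype=float)
               if amplitudes and cond in amplitudes else None)

        def mean_sem(a):
            if a is None or len(a) == 0:
                return np.nan, np.nan
            sem = np.nan if len(a) < 2 else float(np.std(a, ddof=1) / np.sqrt(len(a)))
            return float(np.mean(a)), sem

        row = {"condition": cond, "n_replicates": len(reps)}
        for name, arr in [("population_bitrate", pop),
                          ("fraction_transmitting", frac),
                          ("transmitting_bitrate", tx),
                          ("mean_amplitude", amp)]:
            m, s = mean_sem(arr)
            row[name] = m
            row[f"{name}_sem"] = s
        rows.append(row)
    return pd.DataFrame(rows)
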