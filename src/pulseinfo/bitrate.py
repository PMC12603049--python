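"""Mutual-information lower bound from decoder posteriors.

For each data point the information gained about the pulse indicator x_k is
the reduction in surprisal from prior to posterior,

    info_k = log2 p_theta(x_k | ...) - log2 p(x_k | last_k)   [bits],

evaluated at the realized x_k.  A cell's bitrate b_j is the mean over its
w_j usable minutes, times 60 (bit/h); the population bitrate is the
track-length-weighted mean of the b_j, identical to pooling all points.
Cells are split into non-transmitting / transmitting subpopulations by
sorting the b_j ascending and taking the longest prefix whose weighted mean
is strictly negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import PulseClassifier, TrainConfig, posterior_probability, train
from .dataset import PulseDataset, build_dataset, standardize_features
from .protocol import PulseSequence, StimulationProtocol

__all__ = [
    "BitrateReport",
    "pointwise_information",
    "single_cell_bitrate",
    "population_bitrate",
    "transmitting_split",
    "evaluate_bitrate",
    "channel_bitrate",
]


@dataclass
class BitrateReport:
    """Per-cell and population information-rate estimates for one condition."""

    cell_table: pd.DataFrame       # cell_id, replicate_id, b_j, w_j, transmitting
    population_bitrate: float      # bit/h, = sum w_j b_j / sum w_j
    total_points: int              # D = sum w_j
    threshold: float               # bit/h; smallest transmitting b_j
    fraction_transmitting: float   # weighted share of transmitting cells
    se_bitrate: float              # weighted between-cell standard error, bit/h

    @property
    def transmitting_bitrate(self) -> float:
        """Weighted mean bitrate within the transmitting subpopulation."""
        t = self.cell_table[self.cell_table["transmitting"]]
        if t.empty:
            return np.nan
        return float(np.average(t["b_j"], weights=t["w_j"]))

    def to_json(self, path) -> None:
        payload = {
            "population_bitrate_bit_per_h": self.population_bitrate,
            "total_points": self.total_points,
            "threshold_bit_per_h": self.threshold,
            "fraction_transmitting": self.fraction_transmitting,
            "transmitting_bitrate_bit_per_h": self.transmitting_bitrate,
            "se_bitrate_bit_per_h": self.se_bitrate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def pointwise_information(x, prior, posterior) -> np.ndarray:
    """log2 posterior(x) - log2 prior(x), evaluated at the realized x."""
    x = np.asarray(x)
    prior = np.asarray(prior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    p_real = np.where(x == 1, prior, 1.0 - prior)
    q_real = np.where(x == 1, posterior, 1.0 - posterior)
    return np.log2(q_real) - np.log2(p_real)


def single_cell_bitrate(info_bits: np.ndarray) -> float:
    """b_j in bit/h: mean per-minute information times 60; may be negative."""
    return float(np.mean(info_bits)) * 60.0


def population_bitrate(b_j, w_j) -> float:
    """Track-length-weighted mean of single-cell bitrates (pooled identity)."""
    b_j = np.asarray(b_j, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    return float(np.dot(w_j, b_j) / w_j.sum())


def transmitting_split(b_j, w_j):
    """Longest-negative-prefix split into non-transmitting and transmitting cells.

    Sorts cells ascending by b_j and finds the longest prefix whose weighted
    mean bitrate is strictly negative; those cells are non-transmitting.
    Returns (threshold, flags, fraction): the threshold is the smallest
    transmitting b_j (-inf if none transmit, +inf threshold never occurs
    since an empty prefix has no mean), flags align with the input order and
    the fraction is the weighted share of transmitting cells.
    """
    b_j = np.asarray(b_j, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    order = np.argsort(b_j, kind="stable")
    cw = np.cumsum(w_j[order])
    cs = np.cumsum((w_j * b_j)[order])
    prefix_mean = cs / cw
    neg = np.flatnonzero(prefix_mean < 0)
    n_non = int(neg[-1]) + 1 if neg.size else 0
    flags = np.ones(len(b_j), dtype=bool)
    flags[order[:n_non]] = False
    fraction = float(w_j[flags].sum() / w_j.sum()) if w_j.sum() > 0 else np.nan
    threshold = float(b_j[order[n_non]]) if n_non < len(b_j) else np.inf
    return threshold, flags, fraction


def evaluate_bitrate(
    model: PulseClassifier,
    dataset: PulseDataset,
    protocol: StimulationProtocol,
    per_replicate_split: bool = False,
) -> BitrateReport:
    """Estimate bitrates over every usable data point (each used exactly once).

    The prior is the protocol's clipped hazard at the point's last_k; the
    posterior adds the decoder's logit update.  ``per_replicate_split``
    applies the transmitting split within each replicate separately (the
    pooled split is the default, as used for histograms).
    """
    u = model.forward(dataset.standardized())
    prior = protocol.prior(dataset.last)
    post = posterior_probability(u, prior)
    info = pointwise_information(dataset.x, prior, post)

    cells = dataset.cells
    n_cells = len(cells)
    b = np.zeros(n_cells)
    w = np.zeros(n_cells, dtype=int)
    sums = np.bincount(dataset.cell_index, weights=info, minlength=n_cells)
    counts = np.bincount(dataset.cell_index, minlength=n_cells)
    present = counts > 0
    b[present] = 60.0 * sums[present] / counts[present]
    w[:] = counts

    table = pd.DataFrame({
        "cell_id": [c.cell_id for c in cells],
        "replicate_id": [c.replicate_id for c in cells],
        "b_j": b, "w_j": w,
    })
    table = table[table["w_j"] > 0].reset_index(drop=True)

    if per_replicate_split:
        flags = np.zeros(len(table), dtype=bool)
        thresholds = []
        for rep, g in table.groupby("replicate_id"):
            thr, fl, _ = transmitting_split(g["b_j"].values, g["w_j"].values)
            flags[g.index.values] = fl
            thresholds.append(thr)
        threshold = float(np.nanmean(thresholds))
    else:
        threshold, flags, _ = transmitting_split(table["b_j"].values, table["w_j"].values)
    table["transmitting"] = flags
    fraction = float(table.loc[flags, "w_j"].sum() / table["w_j"].sum())

    pop = population_bitrate(table["b_j"].values, table["w_j"].values)
    wn = table["w_j"].values / table["w_j"].values.sum()
    var_between = float(np.sum(wn**2 * (table["b_j"].values - pop) ** 2))
    return BitrateReport(
        cell_table=table,
        population_bitrate=pop,
        total_points=int(table["w_j"].sum()),
        threshold=threshold,
        fraction_transmitting=fraction,
        se_bitrate=np.sqrt(var_between),
    )


def channel_bitrate(
    tracks,
    seq: PulseSequence,
    protocol: StimulationProtocol,
    slice_mode: str,
    config: TrainConfig = TrainConfig(),
) -> tuple[BitrateReport, PulseClassifier]:
    """Full train-and-estimate pipeline for a restricted trajectory slice.

    ``slice_mode`` "dip_only" decodes from y[k..k+2] (the fast phosphatase
    channel), "peak_only" from y[k+6..k+12] (the kinase channel), "full"
    from y[k..k+6].
    """
    ds = standardize_features(build_dataset(tracks, seq, slice_mode=slice_mode))
    model = train(ds, protocol, config)
    return evaluate_bitrate(model, ds, protocol), model


def quadrant_table(report_a: BitrateReport, report_b: BitrateReport,
                   labels=("dip", "peak")) -> pd.DataFrame:
    """Per-cell two-channel transmitting table plus quadrant fractions."""
    a = report_a.cell_table.set_index(["replicate_id", "cell_id"])
    bt = report_b.cell_table.set_index(["replicate_id", "cell_id"])
    j = a[["b_j", "transmitting"]].join(
        bt[["b_j", "transmitting"]], lsuffix=f"_{labels[0]}", rsuffix=f"_{labels[1]}",
        how="inner")
    return j.reset_index()
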