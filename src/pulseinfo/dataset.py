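"""Classifier data points and protocol-driven minibatch sampling.

Every usable minute k of every track yields one data point carrying the
pulse indicator x_k, the renewal-state variables (interval_k, last_k), the
trajectory-slice differences, the cell's responsiveness and its condition
covariates.  Points are grouped by (interval_k, last_k) so that minibatches
can be drawn under an *assumed* protocol: pairs (interval, last) are sampled
from the protocol's stationary joint distribution

    P(interval = i, last = l) = p(i) / E[L]   for 1 <= l <= i,

and then data points are drawn uniformly (with replacement) from the
matching experimental groups.  Protocols with intervals longer than the
longest measured one are served by imputation onto the measured 35-min
interval, preserving the time since the previous pulse and the time to the
next pulse whenever either is below 10 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import PulseSequence, StimulationProtocol, annotate_sequence

__all__ = [
    "PulseDataset",
    "FeatureStats",
    "SLICE_MODES",
    "extract_datapoints",
    "build_dataset",
    "joint_interval_last",
    "sample_minibatch",
    "impute_long_interval",
    "standardize_features",
]

# slice_mode -> (first offset, last offset) of the y-slice relative to k
SLICE_MODES = {"full": (0, 6), "dip_only": (0, 2), "peak_only": (6, 12)}


@dataclass(frozen=True)
class FeatureStats:
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class PulseDataset:
    """Column-oriented collection of data points with a (interval, last) index.

    ``features`` holds raw (unstandardized) values in the column order
    ``names``; ``log_last_col`` marks the log(last_k) column so that samplers
    may override it (imputation keeps the trajectory slice of the imputed
    group but the decoder always receives the true last_k).
    """

    features: np.ndarray            # (n, d) raw feature matrix
    x: np.ndarray                   # (n,) pulse indicators
    last: np.ndarray                # (n,) minutes since previous pulse
    interval: np.ndarray            # (n,) enclosing interval length
    cell_index: np.ndarray          # (n,) row into `cells`
    cells: list                     # CellTrack objects (w filled)
    names: list
    log_last_col: int
    groups: dict                    # (interval, last) -> np.ndarray of rows
    stats: FeatureStats | None = None

    def __len__(self) -> int:
        return len(self.x)

    @property
    def replicates(self) -> list[str]:
        return sorted({c.replicate_id for c in self.cells})

    def standardized(self, rows=None, true_last=None) -> np.ndarray:
        """Standardized feature matrix; optionally with log(last) overridden."""
        if self.stats is None:
            raise ValueError("dataset not standardized yet")
        f = self.features if rows is None else self.features[rows]
        f = (f - self.stats.mean) / self.stats.sd
        if true_last is not None:
            j = self.log_last_col
            f = f.copy()
            f[:, j] = (np.log(true_last) - self.stats.mean[j]) / self.stats.sd[j]
        return f

    def subset(self, row_mask) -> "PulseDataset":
        rows = np.flatnonzero(row_mask)
        remap = -np.ones(len(self.x), dtype=int)
        remap[rows] = np.arange(rows.size)
        groups = {}
        for key, idx in self.groups.items():
            kept = remap[idx]
            kept = kept[kept >= 0]
            if kept.size:
                groups[key] = kept
        return PulseDataset(
            features=self.features[rows], x=self.x[rows], last=self.last[rows],
            interval=self.interval[rows], cell_index=self.cell_index[rows],
            cells=self.cells, names=self.names, log_last_col=self.log_last_col,
            groups=groups, stats=self.stats,
        )

    def subset_cells(self, keep_cell_rows) -> "PulseDataset":
        keep = np.zeros(len(self.cells), dtype=bool)
        keep[np.asarray(keep_cell_rows)] = True
        return self.subset(keep[self.cell_index])


def extract_datapoints(track, seq: PulseSequence, slice_mode: str = "full"):
    """Per-minute data points of one track.

    Returns (features, x, last, interval) arrays; one row per usable minute
    (strictly after the first pulse, at or before the last pulse, with the
    full trajectory slice present and finite).  Features: the slice's
    discrete differences, log(last_k), responsiveness s, cell line, and the
    three inhibitor concentrations.
    """
    lo, hi = SLICE_MODES[slice_mode]
    ann = annotate_sequence(seq)
    n = min(len(track.y), seq.total_length)
    ks = np.arange(n - hi)
    usable = ann["usable"][: len(ks)].astype(bool)
    sl = np.stack([track.y[ks + o] for o in range(lo, hi + 1)], axis=1)
    ok = usable & np.isfinite(sl).all(axis=1)
    ks = ks[ok]
    diffs = np.diff(sl[ok], axis=1)
    feats = np.column_stack([
        diffs,
        np.log(ann["last"][ks]),
        np.full(ks.size, track.s),
        np.full(ks.size, float(track.cell_line)),
        np.full(ks.size, track.inhibitors[0]),
        np.full(ks.size, track.inhibitors[1]),
        np.full(ks.size, track.inhibitors[2]),
    ])
    return feats, ann["x"][ks], ann["last"][ks], ann["interval"][ks]


def build_dataset(tracks, seq: PulseSequence, slice_mode: str = "full") -> PulseDataset:
    """Extract, pool and index data points from all tracks."""
    lo, hi = SLICE_MODES[slice_mode]
    r = hi - lo
    names = [f"dy{i+1}" for i in range(r)] + [
        "log_last", "s", "cell_line", "alki", "meki", "calci"]
    feats, xs, lasts, intervals, cidx = [], [], [], [], []
    for j, t in enumerate(tracks):
        f, x, l, i = extract_datapoints(t, seq, slice_mode)
        t.w = len(x)
        feats.append(f)
        xs.append(x)
        lasts.append(l)
        intervals.append(i)
        cidx.append(np.full(len(x), j))
    if feats:
        features = np.concatenate(feats)
        x = np.concatenate(xs).astype(int)
        last = np.concatenate(lasts).astype(int)
        interval = np.concatenate(intervals).astype(int)
        cell_index = np.concatenate(cidx).astype(int)
    else:
        features = np.empty((0, r + 6))
        x = last = interval = cell_index = np.empty(0, dtype=int)
    groups: dict = {}
    order = np.lexsort((last, interval))
    si, sl_ = interval[order], last[order]
    if len(order):
        change = np.flatnonzero(np.diff(si) | np.diff(sl_)) + 1
        for block in np.split(order, change):
            groups[(int(interval[block[0]]), int(last[block[0]]))] = block
    return PulseDataset(
        features=features, x=x, last=last, interval=interval,
        cell_index=cell_index, cells=list(tracks), names=names,
        log_last_col=r, groups=groups,
    )


def joint_interval_last(protocol: StimulationProtocol):
    """Stationary per-minute joint distribution of (interval, last).

    Each minute of the renewal process lies in some interval of length i at
    phase l in 1..i; long intervals cover proportionally more minutes, so
    P(i, l) = p(i)/E[L].  The diagonal mass sum_i P(i, i) is the pulse rate
    1/E[L].
    """
    dist = protocol.dist
    mean = dist.mean_interval
    pairs, probs = [], []
    for i, p in zip(dist.support, dist.probs):
        for l in range(1, int(i) + 1):
            pairs.append((int(i), l))
            probs.append(p / mean)
    return np.array(pairs), np.array(probs)


def impute_long_interval(interval: float, last: float) -> tuple[int, float]:
    """Map a long-interval request onto the longest measured interval (35 min).

    Keeps the time since the previous pulse if it is short (< 10 min), keeps
    the time *to the next* pulse if that is short, and otherwise linearly
    compresses the mid-interval phase onto 10..25 min.  The decoder still
    receives the true last_k; only the trajectory slice comes from the
    imputed group.
    """
    if interval <= 35:
        raise ValueError("imputation applies only to intervals > 35 min")
    if not 1 <= last <= interval:
        raise ValueError("need 1 <= last <= interval")
    if last < 10:
        return 35, float(last)
    if interval - last < 10:
        return 35, 35.0 - (interval - last)
    return 35, 10.0 + (last - 10.0) * (35.0 - 20.0) / (interval - 20.0)


def _nearest_group(groups: dict, key: tuple[int, int]):
    if key in groups:
        return groups[key]
    i0, l0 = key
    best = min(groups, key=lambda k: (abs(k[0] - i0) + abs(k[1] - l0), k))
    return groups[best]


def sample_minibatch(
    dataset: PulseDataset,
    protocol: StimulationProtocol,
    batch_size: int = 10_000,
    rng=None,
    impute_above: int | None = None,
):
    """Draw a protocol-weighted minibatch.

    Returns (rows, x, true_last): dataset row indices (with replacement),
    the pulse labels implied by the sampled pairs (x = 1 iff last ==
    interval), and the true last_k to be used for both the decoder's
    log(last) input and the prior.  With ``impute_above`` set (e.g. 35),
    pairs with longer intervals are served from the imputed groups.
    """
    if not dataset.groups:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(rng)
    pairs, probs = joint_interval_last(protocol)
    probs = probs / probs.sum()  # guard tiny renormalization drift
    pick = rng.choice(len(pairs), size=batch_size, p=probs)
    rows = np.empty(batch_size, dtype=int)
    true_last = pairs[pick, 1].astype(float)
    x = (pairs[pick, 0] == pairs[pick, 1]).astype(int)
    missing = set()
    for pair_id in np.unique(pick):
        sel = pick == pair_id
        i, l = int(pairs[pair_id, 0]), int(pairs[pair_id, 1])
        if impute_above is not None and i > impute_above:
            i_star, l_star = impute_long_interval(i, l)
            key = (i_star, int(round(l_star)))
        else:
            key = (i, l)
        if key not in dataset.groups:
            missing.add(key)
        grp = _nearest_group(dataset.groups, key)
        rows[sel] = grp[rng.integers(0, len(grp), size=int(sel.sum()))]
    if missing:
        warnings.warn(f"{len(missing)} (interval, last) groups empty; "
                      "borrowed from nearest groups")
    return rows, x, true_last


def write_dataset(dataset: PulseDataset, path, sidecar=None) -> None:
    """Parquet table of data points with a JSON sidecar for the metadata.

    The sidecar (default: ``path`` with a ``.json`` suffix appended) stores
    feature names, standardization statistics and the per-cell summary; the
    (interval, last) group index is rebuilt on load.
    """
    import json

    import pandas as pd

    df = pd.DataFrame(dataset.features, columns=dataset.names)
    df["x"] = dataset.x
    df["last"] = dataset.last
    df["interval"] = dataset.interval
    df["cell_index"] = dataset.cell_index
    df.to_parquet(path)
    meta = {
        "names": dataset.names,
        "log_last_col": dataset.log_last_col,
        "stats": None if dataset.stats is None else
            {"mean": dataset.stats.mean.tolist(), "sd": dataset.stats.sd.tolist()},
        "cells": [
            {"cell_id": c.cell_id, "replicate_id": c.replicate_id, "w": int(c.w),
             "s": None if np.isnan(c.s) else float(c.s),
             "cell_line": int(c.cell_line),
             "inhibitors": list(map(float, c.inhibitors))}
            for c in dataset.cells
        ],
    }
    sidecar = f"{path}.json" if sidecar is None else sidecar
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)


def read_dataset(path, sidecar=None) -> PulseDataset:
    import json

    import pandas as pd

    from .preprocess import CellTrack

    sidecar = f"{path}.json" if sidecar is None else sidecar
    with open(sidecar) as fh:
        meta = json.load(fh)
    df = pd.read_parquet(path)
    names = meta["names"]
    cells = []
    for c in meta["cells"]:
        t = CellTrack(cell_id=c["cell_id"], replicate_id=c["replicate_id"],
                      y=np.empty(0), cell_line=c["cell_line"],
                      inhibitors=tuple(c["inhibitors"]))
        t.w = c["w"]
        t.s = np.nan if c["s"] is None else c["s"]
        cells.append(t)
    interval = df["interval"].to_numpy()
    last = df["last"].to_numpy()
    groups: dict = {}
    order = np.lexsort((last, interval))
    if len(order):
        change = np.flatnonzero(np.diff(interval[order]) | np.diff(last[order])) + 1
        for block in np.split(order, change):
            groups[(int(interval[block[0]]), int(last[block[0]]))] = block
    stats = meta["stats"]
    return PulseDataset(
        features=df[names].to_numpy(), x=df["x"].to_numpy(), last=last,
        interval=interval, cell_index=df["cell_index"].to_numpy(), cells=cells,
        names=names, log_last_col=meta["log_last_col"], groups=groups,
        stats=None if stats is None else FeatureStats(
            np.asarray(stats["mean"]), np.asarray(stats["sd"])),
    )


def standardize_features(dataset: PulseDataset) -> PulseDataset:
    """Fit dataset-wide per-feature mean/sd (sd 0 -> scale 1, with a warning)."""
    mean = dataset.features.mean(axis=0)
    sd = dataset.features.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        warnings.warn(
            f"zero-variance features scaled by 1: {[dataset.names[i] for i in np.flatnonzero(zero)]}")
        sd = np.where(zero, 1.0, sd)
    dataset.stats = FeatureStats(mean=mean, sd=sd)
    return dataset
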