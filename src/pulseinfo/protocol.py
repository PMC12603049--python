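"""Interval-encoded stimulation protocols.

A protocol is a renewal process on a 1-minute grid: pulses are separated by
i.i.d. intervals ``L`` (whole minutes) drawn from an :class:`IntervalDistribution`.
The per-minute representation of a pulse train is the binary sequence
``x_k`` with ``x_k = 1`` at pulse minutes.  Because the process is renewal,
the conditional pulse probability at minute ``k`` depends only on the time
``last_k`` elapsed since the previous pulse; that conditional probability is
the *hazard* of the interval distribution,

    h(l) = p(L = l) / P(L >= l),

which serves as the decoder's prior.  The input information rate of a
protocol is the entropy rate of the induced binary process,

    rate = H(L) / E[L]   (bits per minute),

reported here in bits per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "IntervalDistribution",
    "StimulationProtocol",
    "PulseSequence",
    "build_gamma_interval_distribution",
    "geometric_interval_distribution",
    "entropy_rate",
    "hazard_from_distribution",
    "realize_pulse_sequence",
    "annotate_sequence",
    "read_pulse_sequence",
    "write_pulse_sequence",
    "read_interval_distribution",
    "write_interval_distribution",
]

_PROB_ATOL = 1e-9


@dataclass(frozen=True)
class IntervalDistribution:
    """Probability distribution over inter-pulse intervals in whole minutes."""

    support: np.ndarray  # strictly increasing positive integers
    probs: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-d arrays of equal length")
        if support.size == 0:
            raise ValueError("empty support")
        if np.any(support <= 0) or np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing positive integers")
        if np.any(probs < 0):
            raise ValueError("negative probabilities")
        if abs(probs.sum() - 1.0) > _PROB_ATOL:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")

    @property
    def mean_interval(self) -> float:
        """E[L] in minutes."""
        return float(np.dot(self.support, self.probs))

    @property
    def entropy(self) -> float:
        """H(L) in bits per pulse."""
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum())

    def quantile(self, q: float) -> int:
        """Smallest supported interval with CDF >= q."""
        c = np.cumsum(self.probs)
        return int(self.support[np.searchsorted(c, q * (1 - 1e-12))])


@dataclass(frozen=True)
class StimulationProtocol:
    """Interval distribution plus its per-minute prior (hazard) map.

    ``hazard(l)`` is clipped into ``[prior_clip, 1 - prior_clip]`` before any
    logit transform so the prior-logit term of the decoder stays finite
    (the hazard at the maximal supported interval is exactly 1).
    """

    dist: IntervalDistribution
    prior_clip: float = 1e-6
    _hazard: dict = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_hazard", hazard_from_distribution(self.dist))

    def hazard(self, last: int) -> float:
        """Unclipped p(pulse | last minutes since previous pulse)."""
        if last < self.dist.support[0]:
            return 0.0
        if last > self.dist.support[-1]:
            raise ValueError(f"last={last} beyond maximal supported interval")
        return self._hazard.get(int(last), 0.0)

    def prior(self, last) -> np.ndarray:
        """Clipped hazard, vectorized over ``last``."""
        last = np.atleast_1d(np.asarray(last, dtype=int))
        out = np.array([self._hazard.get(int(l), 0.0) if l <= self.dist.support[-1]
                        else np.nan for l in last])
        if np.any(np.isnan(out)):
            raise ValueError("last beyond maximal supported interval")
        return np.clip(out, self.prior_clip, 1.0 - self.prior_clip)

    def prior_logit(self, last) -> np.ndarray:
        p = self.prior(last)
        return np.log(p) - np.log1p(-p)


@dataclass(frozen=True)
class PulseSequence:
    """A realized pulse train: sorted pulse minutes on ``[0, total_length)``."""

    pulse_minutes: np.ndarray
    total_length: int

    def __post_init__(self):
        pm = np.asarray(self.pulse_minutes, dtype=int)
        object.__setattr__(self, "pulse_minutes", pm)
        if pm.size and (np.any(np.diff(pm) <= 0) or pm[0] < 0 or pm[-1] >= self.total_length):
            raise ValueError("pulse minutes must be sorted, unique and within [0, total_length)")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.pulse_minutes)

    def empirical_distribution(self) -> IntervalDistribution:
        lengths, counts = np.unique(self.intervals, return_counts=True)
        return IntervalDistribution(lengths, counts / counts.sum())

    def x(self) -> np.ndarray:
        out = np.zeros(self.total_length, dtype=int)
        out[self.pulse_minutes] = 1
        return out


def build_gamma_interval_distribution(
    shape: float, scale: float, support_min: int, support_max: int
) -> IntervalDistribution:
    """Gamma density discretized to integer minutes and renormalized.

    The default study protocol uses shape 4, scale 5 min on 5..35 min; its
    mode sits at (shape-1)*scale = 15 min.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if support_min < 1 or support_max < support_min:
        raise ValueError("need 1 <= support_min <= support_max")
    support = np.arange(support_min, support_max + 1)
    dens = stats.gamma.pdf(support, a=shape, scale=scale)
    if dens.sum() <= 0:
        raise ValueError("Gamma density vanishes on the requested support")
    return IntervalDistribution(support, dens / dens.sum())


def geometric_interval_distribution(q: float, support_max: int = 64) -> IntervalDistribution:
    """Interval distribution of per-minute Bernoulli(q) pulses.

    p(l) = q (1-q)^(l-1), truncated at ``support_max`` with the tail mass
    absorbed into the last atom (negligible for support_max >> 1/q).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    support = np.arange(1, support_max + 1)
    p = q * (1 - q) ** (support - 1)
    p[-1] = (1 - q) ** (support_max - 1)  # tail mass: P(L >= support_max)
    return IntervalDistribution(support, p)


def entropy_rate(dist: IntervalDistribution) -> float:
    """Input entropy rate H(L)/E[L], in bits per hour.

    Equals the per-minute conditional entropy of the induced binary renewal
    process (chain rule), times 60.
    """
    return 60.0 * dist.entropy / dist.mean_interval


def hazard_from_distribution(dist: IntervalDistribution) -> dict[int, float]:
    """h(l) = p(L=l)/P(L>=l) for every l in [min support, max support]."""
    lmin, lmax = int(dist.support[0]), int(dist.support[-1])
    pmf = dict(zip(dist.support.tolist(), dist.probs.tolist()))
    out: dict[int, float] = {}
    tail = 1.0
    for l in range(lmin, lmax + 1):
        p = pmf.get(l, 0.0)
        out[l] = p / tail if tail > 0 else 1.0
        tail -= p
    out[lmax] = 1.0  # exact by construction; avoid round-off shortfall
    return out


def distribution_from_hazard(hazard: dict[int, float]) -> IntervalDistribution:
    """Inverse of :func:`hazard_from_distribution`: p(l) = h(l) prod_{m<l} (1-h(m))."""
    ls = sorted(hazard)
    surv = 1.0
    support, probs = [], []
    for l in ls:
        p = hazard[l] * surv
        if p > 0:
            support.append(l)
            probs.append(p)
        surv *= 1.0 - hazard[l]
    probs = np.asarray(probs)
    return IntervalDistribution(np.asarray(support), probs / probs.sum())


def _interval_counts(
    dist: IntervalDistribution, time_budget: int, short_cutoff: int
) -> np.ndarray:
    """Integer interval counts best matching ``dist`` within the budget.

    Counts start at round(m * p(L)) with m = budget / E[L]; every length at
    or below ``short_cutoff`` is raised to at least two occurrences; the
    total duration is then trimmed back under the budget by decrementing the
    lengths most overrepresented relative to their target (never below the
    two-occurrence floor).
    """
    target = (time_budget / dist.mean_interval) * dist.probs
    counts = np.round(target).astype(int)
    short = dist.support <= short_cutoff
    counts[short] = np.maximum(counts[short], 2)
    floor = np.where(short, 2, 0)
    while np.dot(counts, dist.support) > time_budget:
        excess = counts - target
        excess[counts <= floor] = -np.inf
        if not np.any(np.isfinite(excess)):
            raise ValueError("time budget too small for the required interval counts")
        counts[np.argmax(excess)] -= 1
    if counts.sum() < 2:
        raise ValueError("time budget too small to place two intervals")
    return counts


def realize_pulse_sequence(
    dist: IntervalDistribution,
    time_budget: int,
    seed: int | None = None,
    short_cutoff: int = 12,
) -> PulseSequence:
    """Deterministically realize a pulse sequence representative of ``dist``.

    Interval counts follow :func:`_interval_counts`.  Ordering rule: the
    occurrences of a repeated length should be preceded by intervals spread
    over the distribution — the m-th occurrence (of c) targets the
    m/(c+1)-quantile of the realized empirical distribution.  The sequence is
    built greedily: after placing an interval of length v, the next interval
    is the remaining length whose next occurrence's target predecessor is
    closest to v (ties to the shorter length).  ``seed`` only breaks the
    choice of the initial interval; the construction is otherwise
    deterministic.
    """
    if time_budget < 2 * int(dist.support[-1]):
        raise ValueError("time budget must cover at least twice the maximal interval")
    counts = _interval_counts(dist, time_budget, short_cutoff)
    realized = IntervalDistribution(dist.support, counts / counts.sum())

    # target predecessor value for the m-th (1-based) occurrence of each length
    remaining = dict(zip(dist.support.tolist(), counts.tolist()))
    remaining = {l: c for l, c in remaining.items() if c > 0}
    placed = {l: 0 for l in remaining}
    targets = {
        l: [realized.quantile((m + 1) / (c + 1)) for m in range(c)]
        for l, c in remaining.items()
    }

    # start near the median so early predecessors are representative; the
    # construction is fully deterministic (seed kept for API symmetry)
    del seed
    median = realized.quantile(0.5)
    first = min(remaining, key=lambda l: (abs(l - median), l))
    order = [first]
    remaining[first] -= 1
    placed[first] += 1
    if remaining[first] == 0:
        del remaining[first]
    while remaining:
        prev = order[-1]
        best = min(
            remaining,
            key=lambda l: (abs(prev - targets[l][placed[l]]), l),
        )
        order.append(best)
        placed[best] += 1
        remaining[best] -= 1
        if remaining[best] == 0:
            del remaining[best]

    pulses = np.concatenate([[0], np.cumsum(order)])
    return PulseSequence(pulses, total_length=int(pulses[-1]) + 1)


def annotate_sequence(seq: PulseSequence) -> np.ndarray:
    """Per-minute annotations of a pulse train.

    Returns a structured array over minutes ``0..total_length-1`` with fields
    ``x`` (pulse indicator), ``last`` (minutes since the previous pulse;
    at a pulse minute this equals the preceding interval), ``interval``
    (length of the inter-pulse interval the minute falls in) and ``usable``
    (False before/at the first pulse and after the last pulse, where either
    ``last`` or ``interval`` is undefined).
    """
    if seq.pulse_minutes.size < 2:
        raise ValueError("need at least two pulses to annotate")
    n = seq.total_length
    out = np.zeros(n, dtype=[("x", int), ("last", int), ("interval", int), ("usable", bool)])
    out["x"][seq.pulse_minutes] = 1
    pm = seq.pulse_minutes
    for a, b in zip(pm[:-1], pm[1:]):
        ks = np.arange(a + 1, b + 1)
        out["last"][ks] = ks - a
        out["interval"][ks] = b - a
        out["usable"][ks] = True
    return out


# ---------------------------------------------------------------------------
# plain-text IO

def write_pulse_sequence(seq: PulseSequence, path: str | Path) -> None:
    """One pulse minute per line; header comment carries the total length."""
    with open(path, "w") as fh:
        fh.write(f"# total_length={seq.total_length}\n")
        for m in seq.pulse_minutes:
            fh.write(f"{int(m)}\n")


def read_pulse_sequence(path: str | Path) -> PulseSequence:
    """Auto-detects the one-column pulse-minute list or (minute, pulse) CSV."""
    total = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "total_length=" in line:
                    total = int(line.split("total_length=")[1])
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if parts[0].lower() in {"minute", "pulse_minute"}:
                continue
            rows.append([int(float(p)) for p in parts])
    if not rows:
        raise ValueError(f"no pulse data in {path}")
    if len(rows[0]) == 1:
        pulses = np.array([r[0] for r in rows])
        if total is None:
            total = int(pulses[-1]) + 1
    else:  # (minute, 0/1) table
        minutes = np.array([r[0] for r in rows])
        flags = np.array([r[1] for r in rows])
        pulses = minutes[flags == 1]
        if total is None:
            total = int(minutes.max()) + 1
    return PulseSequence(pulses, total_length=total)


def write_interval_distribution(dist: IntervalDistribution, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("interval_min,probability\n")
        for l, p in zip(dist.support, dist.probs):
            fh.write(f"{int(l)},{p:.12g}\n")


def read_interval_distribution(path: str | Path) -> IntervalDistribution:
    support, probs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("interval"):
                continue
            l, p = line.split(",")
            support.append(int(float(l)))
            probs.append(float(p))
    probs = np.asarray(probs)
    return IntervalDistribution(np.asarray(support), probs / probs.sum())
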