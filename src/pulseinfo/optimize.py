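"""In-silico stimulation-protocol optimization (channel-capacity estimation).

The interval distribution is parameterized by logits phi over a contiguous
integer support (default 5..90 min), p = softmax(phi).  The objective is the
decoder-based bitrate estimate under the candidate protocol: data points are
requested by (interval, last) pair from the *measured* dataset (pairs with
intervals beyond the measured range are imputed onto the longest measured
interval), the prior is recomputed from the candidate protocol's hazard, and
the trained decoder is reused unchanged — its posterior shifts with the
protocol only through the additive prior-logit term.

Because minibatches are drawn from the candidate protocol itself, the
gradient with respect to phi is computed with the frozen-distribution
importance-weight identity: sampling from a frozen copy phi' with weights
p_phi(z)/p_phi'(z) (all equal to 1 at phi = phi'), whose derivatives supply
the score-function term.  A smoothness penalty — alpha times the mean
squared second difference of the interval log-probabilities — discourages
jagged protocols; the reported capacity is the unregularized bitrate of the
final protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .classifier import LN2, PulseClassifier
from .dataset import PulseDataset, _nearest_group, impute_long_interval
from .protocol import IntervalDistribution, StimulationProtocol

__all__ = [
    "OptimizableProtocol",
    "regularization_penalty",
    "penalty_gradient",
    "estimate_objective_and_gradient",
    "exact_objective",
    "exact_gradient",
    "optimize_protocol",
    "OptimizationResult",
]

DEFAULT_ALPHA = 0.003


@dataclass
class OptimizableProtocol:
    """Logit-parameterized interval distribution on a contiguous support."""

    support: np.ndarray
    phi: np.ndarray
    prior_clip: float = 1e-6

    @classmethod
    def from_distribution(cls, dist: IntervalDistribution,
                          support_min: int = 5, support_max: int = 90,
                          floor: float = 1e-4) -> "OptimizableProtocol":
        """Initialize from a distribution, extending the support with a small
        probability floor where the distribution assigns none."""
        support = np.arange(support_min, support_max + 1)
        pmf = dict(zip(dist.support.tolist(), dist.probs.tolist()))
        p = np.array([max(pmf.get(int(l), 0.0), floor) for l in support])
        p = p / p.sum()
        return cls(support=support, phi=np.log(p))

    @property
    def probs(self) -> np.ndarray:
        return softmax(self.phi)

    def distribution(self) -> IntervalDistribution:
        return IntervalDistribution(self.support, self.probs)

    def protocol(self) -> StimulationProtocol:
        return StimulationProtocol(self.distribution(), prior_clip=self.prior_clip)


# ---------------------------------------------------------------------------
# hazard (prior) of the softmax distribution, with gradients of its logit

def _hazard_state(support: np.ndarray, p: np.ndarray, clip: float):
    """Per-support-index hazard h, its clipped value and survival tails.

    T[i] = P(L > support[i]);  h = p / (p + T);  logit h = ln p - ln T.
    The hazard at the last support point is 1 and is clipped; clipped
    entries carry zero gradient.
    """
    tail = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])  # strictly-after mass
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p + tail > 0, p / np.maximum(p + tail, 1e-300), 1.0)
    h_clip = np.clip(h, clip, 1.0 - clip)
    unclipped = (h > clip) & (h < 1.0 - clip) & (tail > 0)
    return h_clip, tail, unclipped


def _prior_for_last(opt: OptimizableProtocol, last: np.ndarray, state=None):
    """Clipped prior probability for each true last_k (0 below the support)."""
    h_clip, tail, unclipped = state or _hazard_state(
        opt.support, opt.probs, opt.prior_clip)
    smin = int(opt.support[0])
    last = np.asarray(last, dtype=int)
    idx = last - smin
    below = idx < 0
    idx_safe = np.clip(idx, 0, len(opt.support) - 1)
    prior = np.where(below, opt.prior_clip, h_clip[idx_safe])
    grad_ok = ~below & unclipped[idx_safe]
    return prior, idx_safe, grad_ok, tail


# ---------------------------------------------------------------------------
# smoothness regularization (on interval log-probabilities)

def regularization_penalty(phi: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """alpha times the mean squared second difference of log softmax(phi)."""
    if len(phi) < 3:
        raise ValueError("need at least 3 support points")
    lp = log_softmax(np.asarray(phi, dtype=float))
    d2 = np.diff(lp, n=2)
    return float(alpha * np.mean(d2**2))


def penalty_gradient(phi: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    lp = log_softmax(phi)
    d2 = np.diff(lp, n=2)
    g_lp = np.zeros_like(lp)
    c = 2.0 * alpha / len(d2)
    # adjoint of the second-difference stencil
    g_lp[:-2] += c * d2
    g_lp[1:-1] -= 2 * c * d2
    g_lp[2:] += c * d2
    p = softmax(phi)
    return g_lp - p * g_lp.sum()


# ---------------------------------------------------------------------------
# per-point information terms under a candidate protocol

def _point_info(model: PulseClassifier, dataset: PulseDataset, rows, x, true_last,
                prior):
    """f (bits/point) and df/d(prior logit) for given rows and priors."""
    feats = dataset.standardized(rows, true_last=np.asarray(true_last, dtype=float))
    u = model.forward(feats)
    eta = np.log(prior) - np.log1p(-prior)
    post = 1.0 / (1.0 + np.exp(-(u + eta)))
    x = np.asarray(x)
    q = np.where(x == 1, post, 1.0 - post)
    pr = np.where(x == 1, prior, 1.0 - prior)
    f = (np.log(np.clip(q, 1e-300, None)) - np.log(pr)) / LN2
    dfdeta = (prior - post) / LN2
    return f, dfdeta


def _rows_for_pair(dataset: PulseDataset, i: int, l: int, max_measured: int):
    """Dataset group serving pair (interval i, last l), imputing long intervals."""
    if i > max_measured:
        i_star, l_star = impute_long_interval(i, l)
        key = (int(i_star), int(round(l_star)))
    else:
        key = (i, l)
    return _nearest_group(dataset.groups, key)


def estimate_objective_and_gradient(
    opt: OptimizableProtocol,
    model: PulseClassifier,
    dataset: PulseDataset,
    batch_size: int = 10_000,
    rng=None,
    alpha: float = DEFAULT_ALPHA,
    max_measured: int | None = None,
):
    """Monte-Carlo estimate of the regularized objective and its phi-gradient.

    Samples (interval, last) pairs from the *current* protocol (the frozen
    copy; importance weights are identically 1 at the evaluation point) and
    assembles the unbiased score-function gradient: the pathwise term from
    the prior logit plus f(z) times the gradient of the log joint
    probability of the sampled pair.
    """
    rng = np.random.default_rng(rng)
    support = opt.support
    p = opt.probs
    mean_L = float(np.dot(support, p))
    if max_measured is None:
        max_measured = int(dataset.interval.max())
    state = _hazard_state(support, p, opt.prior_clip)

    # sample pairs (i, l): i ~ p(i) * i / E[L] (minutes-in-interval weighting),
    # l | i ~ uniform on 1..i  — exactly the stationary joint P(i,l) = p(i)/E[L]
    pi = p * support / mean_L
    pi = pi / pi.sum()
    ii = rng.choice(len(support), size=batch_size, p=pi)
    i_val = support[ii]
    l_val = rng.integers(1, i_val + 1)
    x = (l_val == i_val).astype(int)

    rows = np.empty(batch_size, dtype=int)
    for i_u in np.unique(ii):
        for l_u in np.unique(l_val[ii == i_u]):
            sel = (ii == i_u) & (l_val == l_u)
            grp = _rows_for_pair(dataset, int(support[i_u]), int(l_u), max_measured)
            rows[sel] = grp[rng.integers(0, len(grp), size=int(sel.sum()))]

    prior, idx_last, grad_ok, tail = _prior_for_last(opt, l_val, state)
    f, dfdeta = _point_info(model, dataset, rows, x, l_val, prior)

    n = len(support)
    grad = np.zeros(n)
    B = batch_size
    # pathwise term: dfdeta * d(logit h(l))/d(phi_m) = dfdeta * (delta_{l m}
    #   - p_m 1[m > l] / T_l), zero where the hazard is clipped
    c = np.where(grad_ok, dfdeta, 0.0)
    np.add.at(grad, idx_last, c / B)
    with np.errstate(divide="ignore"):
        ct = np.where(grad_ok, dfdeta / np.maximum(tail[idx_last], 1e-300), 0.0)
    s_by_l = np.bincount(idx_last, weights=ct, minlength=n)
    prefix = np.concatenate([[0.0], np.cumsum(s_by_l)[:-1]])  # sum over l < m
    grad -= p * prefix / B
    # score term: f * d(log P(i, l))/d(phi_m) = f * (delta_{i m} - p_m
    #   - p_m (L_m - E[L]) / E[L])
    np.add.at(grad, ii, f / B)
    fbar = f.mean()
    grad -= fbar * (p + p * (support - mean_L) / mean_L)

    objective = 60.0 * fbar - regularization_penalty(opt.phi, alpha)
    gradient = 60.0 * grad - penalty_gradient(opt.phi, alpha)
    return objective, gradient


def _pair_iter(opt: OptimizableProtocol):
    p = opt.probs
    mean_L = float(np.dot(opt.support, p))
    for idx, (i, pi) in enumerate(zip(opt.support, p)):
        for l in range(1, int(i) + 1):
            yield idx, int(i), l, pi / mean_L


def exact_objective(
    opt: OptimizableProtocol, model: PulseClassifier, dataset: PulseDataset,
    alpha: float = DEFAULT_ALPHA, max_measured: int | None = None,
) -> float:
    """Batch-exact objective: full enumeration of (interval, last) pairs.

    Intended for small supports/datasets (tests, final-protocol evaluation);
    cost is sum of group sizes over all pairs.
    """
    if max_measured is None:
        max_measured = int(dataset.interval.max())
    state = _hazard_state(opt.support, opt.probs, opt.prior_clip)
    total = 0.0
    for idx, i, l, P in _pair_iter(opt):
        rows = _rows_for_pair(dataset, i, l, max_measured)
        prior, _, _, _ = _prior_for_last(opt, np.array([l]), state)
        x = np.full(len(rows), int(l == i))
        f, _ = _point_info(model, dataset, rows, x,
                           np.full(len(rows), l), np.full(len(rows), prior[0]))
        total += P * f.mean()
    return 60.0 * total - regularization_penalty(opt.phi, alpha)


def exact_gradient(
    opt: OptimizableProtocol, model: PulseClassifier, dataset: PulseDataset,
    alpha: float = DEFAULT_ALPHA, max_measured: int | None = None,
) -> np.ndarray:
    """Exact expectation of the importance (score-function) gradient."""
    if max_measured is None:
        max_measured = int(dataset.interval.max())
    support, p = opt.support, opt.probs
    mean_L = float(np.dot(support, p))
    state = _hazard_state(support, p, opt.prior_clip)
    n = len(support)
    grad = np.zeros(n)
    for idx, i, l, P in _pair_iter(opt):
        rows = _rows_for_pair(dataset, i, l, max_measured)
        prior, idx_last, grad_ok, tail = _prior_for_last(opt, np.array([l]), state)
        x = np.full(len(rows), int(l == i))
        f, dfdeta = _point_info(model, dataset, rows, x,
                                np.full(len(rows), l), np.full(len(rows), prior[0]))
        fbar, dbar = f.mean(), dfdeta.mean()
        if grad_ok[0]:
            li = idx_last[0]
            grad[li] += P * dbar
            mask = support > support[li]
            grad[mask] -= P * dbar * p[mask] / max(tail[li], 1e-300)
        glogP = -p - p * (support - mean_L) / mean_L
        glogP[idx] += 1.0
        grad += P * fbar * glogP
    return 60.0 * grad - penalty_gradient(opt.phi, alpha)


@dataclass
class OptimizationResult:
    protocol: OptimizableProtocol
    capacity: float                # unregularized bitrate of the final protocol
    trace: np.ndarray              # per-step regularized objective estimates
    initial_objective: float

    def save(self, out_dir) -> None:
        """Optimized protocol CSV, objective-trace CSV and capacity JSON."""
        import json
        from pathlib import Path

        from .protocol import write_interval_distribution

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_interval_distribution(self.protocol.distribution(),
                                    out / "optimized_protocol.csv")
        with open(out / "objective_trace.csv", "w") as fh:
            fh.write("step,objective_bit_per_h\n")
            for i, v in enumerate(self.trace):
                fh.write(f"{i},{v:.6g}\n")
        with open(out / "capacity.json", "w") as fh:
            json.dump({"capacity_bit_per_h": self.capacity,
                       "initial_objective_bit_per_h": self.initial_objective},
                      fh, indent=2)


def optimize_protocol(
    model: PulseClassifier,
    dataset: PulseDataset,
    init: OptimizableProtocol | IntervalDistribution,
    steps: int = 500,
    learning_rate: float = 0.05,
    batch_size: int = 10_000,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    support_min: int = 5,
    support_max: int = 90,
    eval_batch: int = 100_000,
) -> OptimizationResult:
    """Gradient-ascent search for the capacity-achieving interval distribution.

    Starts from ``init`` (typically the experimental distribution), takes
    plain gradient steps on the logits with a freshly frozen sampling copy
    each step, and reports the final protocol's *unregularized* bitrate
    estimated with a large batch.  Run this on the transmitting
    subpopulation determined under the experimental protocol
    (``dataset.subset_cells``).
    """
    if isinstance(init, IntervalDistribution):
        opt = OptimizableProtocol.from_distribution(init, support_min, support_max)
    else:
        opt = OptimizableProtocol(init.support.copy(), init.phi.copy(),
                                  init.prior_clip)
    rng = np.random.default_rng(seed)
    max_measured = int(dataset.interval.max())
    trace = np.empty(steps)
    initial = None
    for step in range(steps):
        obj, grad = estimate_objective_and_gradient(
            opt, model, dataset, batch_size=batch_size, rng=rng, alpha=alpha,
            max_measured=max_measured)
        if not np.isfinite(obj) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"objective diverged at step {step}: obj={obj!r}")
        if initial is None:
            initial = obj
        trace[step] = obj
        opt.phi = opt.phi + learning_rate * grad
        opt.phi -= opt.phi.max()  # keep logits bounded; softmax-invariant
    cap, _ = estimate_objective_and_gradient(
        opt, model, dataset, batch_size=eval_batch, rng=rng, alpha=0.0,
        max_measured=max_measured)
    return OptimizationResult(protocol=opt, capacity=cap, trace=trace,
                              initial_objective=float(initial))
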