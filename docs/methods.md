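# Methods

## Model and estimator

Stimulation is an interval-encoded renewal process on a 1-minute grid: a
pulse occupies one minute bin, and gaps between pulses are i.i.d. draws
from an interval distribution `p(L)` over whole minutes. Because the
process is renewal, the conditional pulse probability at minute `k` given
the full history equals the hazard at the age `last_k` (minutes since the
previous pulse), `h(l) = p(L = l)/P(L ≥ l)`. The input entropy rate is
`H(L)/E[L]` bits per minute; the chain rule makes this identical to the
per-minute conditional entropy of the binary pulse process (verified
against brute-force sequence enumeration in the tests). All rates are
reported in bit/h (×60).

The transmitted-information estimator is a decoder-based lower bound on the
mutual information between the pulse train and a cell's trajectory. For
every usable minute, a multilayer perceptron maps

    [Δy_{k+1..k+r}, log last_k, s, cellLine, ALKi, MEKi, CALCi]   (r = 6)

to a scalar logit update `u_Bayes`; the posterior pulse probability is
`sigmoid(u_Bayes + logit h(last_k))`. The per-point information is the
surprisal reduction `log2 posterior(x_k) − log2 prior(x_k)` at the realized
`x_k`; a cell's bitrate is its mean × 60, the population bitrate the
track-length-weighted mean of cell bitrates (exactly the pooled average —
an algebraic identity asserted to 1e−12). Because the bound only requires
*some* posterior model, any decoder shortfall makes the estimate
conservative, never inflated; individual cells can still come out negative
when a decoder trained on the population is misled by their aberrant
responses.

Transmitting/non-transmitting split: cells sorted by bitrate; the longest
prefix whose length-weighted mean is strictly negative is non-transmitting.
The split can be applied pooled (for histograms) or per replicate (for
condition summaries); both modes are exposed.

## Decoder and training

Architecture: input width r + 6 = 12 (6 trajectory-slice differences,
log last, responsiveness, cell line, three inhibitor concentrations),
hidden layers (40, 20), leaky-ReLU slope 0.01, scalar output. Features are
standardized to zero mean and unit SD with dataset-wide statistics that are
stored with the model and reapplied verbatim at inference; zero-variance
columns are centered but not scaled. Dip-only decoding uses the slice
y[k..k+2] (2 differences, input width 8), peak-only y[k+6..k+12].

Training minimizes the Bernoulli cross-entropy of the posterior with Adam
(learning rate 1e−3, minibatch 10^4 by default; internally in nats,
traced in bits/point). Minibatches are protocol-weighted: `(interval,
last)` pairs are sampled from the stationary joint `P(i, l) = p(i)/E[L]`
(l = 1..i) of the assumed protocol, then data points are drawn uniformly
with replacement from the matching experimental groups; empty groups borrow
from the nearest group in Manhattan distance with a warning. The output
layer is zero-initialized, so the untrained decoder reproduces the prior
exactly and the bitrate starts at 0.

Weight selection: 10% of cells are held out of the sampler and the returned
weights are those with the best validation cross-entropy (checked every 25
steps). Since step 0 *is* the prior, a decoder that finds no validated
signal returns "no update" and the estimate stays at zero rather than going
negative through overfitting — this keeps the lower-bound property clean on
null data. Hazards are clipped to [1e−6, 1 − 1e−6] before logits so the
prior term stays finite (the hazard at the maximal supported interval is
exactly 1).

Evaluation uses every usable point exactly once (uniform average);
protocol-driven sampling weights apply to training only. Leave-one-
replicate-out cross-validation (train on the rest, evaluate on all, report
deltas against the all-data model) checks that a single decoder can serve
all replicates.

## Protocol optimization

Candidate protocols are parameterized as logits over intervals 5..90 min
(softmax-normalized); intervals below 5 min are excluded from the search
space because the measured data contain no detectable responses there to
extrapolate from. The objective is the bitrate estimate under the candidate
protocol with the *same trained decoder*: priors are recomputed from the
candidate hazard (the posterior shifts only through the additive prior-
logit term), and requests for intervals beyond the measured maximum
(35 min) are imputed onto the 35-min groups — time since the previous pulse
is preserved when < 10 min, time to the next pulse when < 10 min, and the
mid-interval phase is compressed linearly otherwise; the decoder and the
prior always receive the *true* last_k. The imputation map is continuous
across its branches (verified by enumeration over intervals 36–90).

Gradients use the frozen-distribution importance-weight identity: batches
are sampled from a frozen copy of the protocol, where the weights are
identically 1 but their ϕ-derivatives supply the score term
`f(z) ∇ log P_ϕ(z)`; the pathwise term propagates through the prior logit,
`∂ logit h(l) / ∂ϕ_m = δ_{lm} − p_m·1[m>l]/P(L>l)`, with zero gradient
where the hazard is clipped. The estimator is exactly unbiased (tested
against full pair enumeration and central finite differences). Plain
gradient ascent, step 0.05 on the logits, 500 steps and batch 10^4 by
default, refreezing the sampling copy each step; optimization runs on the
transmitting subpopulation determined under the experimental protocol. A
smoothness penalty — α times the mean squared second difference of the
interval log-probabilities, α = 0.003 — discourages jagged protocols; the
reported capacity is the *unregularized* bitrate of the final protocol
(measured α=0 vs α=0.003 capacities agree within 5%).

## Preprocessing

Trajectories: `y_k = −log[(nuclear_k − background)/(frame_k − background)]`
with a per-replicate scalar background (image-level background estimation
is upstream of this package); non-positive intensities flag the minute as
missing, and the map is exactly invertible given frame and background.
Tracks shorter than 180 min (inclusive boundary) are dropped. Receptor
preselection keeps tracks inside [µ, µ+3σ] (BEAS-2B-like) or [µ−0.5σ,
µ+2σ] (STE-1-like), where µ and σ are the track-length-weighted mean and
SD of the per-track mean receptor intensity at pulse minutes, per
replicate; both moments use the weighted population (denominator-n)
convention, and σ = 0 keeps everything. Responsiveness is
`s = Std_k(y_k − y_{k+7})` over all minutes (population SD; a single valid
difference gives 0; fewer than 8 usable minutes, undefined). Response
amplitudes `y_{t+7} − y_t` are drift-corrected by the population mean of
`y_{p+L+7} − y_{p+L}` over pulses `p` followed by at least L+7 pulse-free
minutes, where L is the preceding interval.

## Stimulation-sequence realization

The study-style sequence discretizes a Gamma(shape 4, scale 5 min) density
to integer minutes on 5..35, realizes integer interval counts matching the
distribution under a ~17-h budget (counts = round of the expected number,
every length ≤ 12 min raised to ≥ 2 occurrences, then trimmed back under
the budget by decrementing the most overrepresented lengths), and orders
the intervals so the m-th occurrence of a repeated length is preceded by an
interval near the m/(c+1) quantile of the realized distribution (greedy
nearest-target choice, ties to the shorter interval; fully deterministic).
This reconstruction yields 58 pulses over ~17 h with an empirical input
entropy rate of 16.44 bit/h. The deposited experimental sequence is not
bundled; its undocumented "minor adjustments" to interval counts can move
the empirical rate by a few tenths of a bit/h around the printed 16.4.

## Synthetic data: what it emulates and what it does not

Each simulated pulse adds to responsive cells a gamma-shaped negative lobe
peaking 2 min after the pulse (dip; recovery half-time 1.5 min, effectively
interval-independent) and a positive lobe peaking at 7 min (peak), scaled
by the saturating recovery `1 − 0.5^(L/τ)` with τ = 8.5 min by default.
The paper-level facts emulated are the lobe timings, the refractory
behaviour of the peak versus the near-flat dip, condition switches (a MEK
inhibitor removes the peak, a calcineurin inhibitor the dip; STE-1-like
cells respond only under an ALK inhibitor, several-fold weaker and without
a dip), mixtures of transmitting/non-transmitting cells, log-normal
receptor expression, and optional spatial clustering of the transmitting
phenotype (smoothed-random-field thresholding at the matching quantile).
Functional forms of the lobes, the AR(1)+white noise model (ρ = 0.5,
process SD 0.05, measurement SD 0.02), the baseline random-walk drift
(0.004/min) and all gain magnitudes (peak 0.35, dip 0.12, cell-to-cell
log-normal CV 0.25) are choices of this package — the source data report no
single-cell noise decomposition — picked once to give realistic-looking
trajectories with population bitrates in the observed several-bit/h range.
A 90-min unstimulated warm-up and a 15-min tail are emitted around the
pulse sequence. The generator does not model mechanistic pathway dynamics,
reporter saturation, cell division/movement, or segmentation artifacts, so
passing tests certify the *estimator and optimizer*, not biological claims
about any particular pathway.

## Numerical choices and problem sizes

Time is 0-based whole minutes. Logs are natural internally, base-2 at
reporting. Hazard clip 1e−6. The transmitting threshold is the smallest
transmitting cell's bitrate. Tests and acceptance checks run reduced
problem sizes chosen for a single CPU: the null-data check uses 700 cells
at a 450-min stimulation budget with an 800-step decoder; the mixture-
recovery check 200 cells at the full ~17-h sequence with 1000 steps; the
noiseless-consistency check 60 cells with 1500 steps; optimizer checks
80 cells with 200 ascent steps at batch 6000. The sequence-level and
identity checks are exact and instant.

## Known limitations

- Per-cell bitrates are evaluated with a decoder trained on (most of) the
  same cells; as in the source method, cells are not excluded from training
  one at a time, which can be slightly optimistic for individual cells
  (population-level optimism is controlled by the validation-selected
  weights and checked by the null test).
- The capacity estimate inherits the imputation assumption that responses
  to intervals > 35 min match the 35-min response; for channels whose
  detectability is still rising at 35 min this underestimates nothing, but
  protocols concentrating mass far beyond the measured range rest on
  extrapolation.
- The sequence realization reproduces the documented construction rules,
  not the deposited pulse table; empirical entropy rates agree to ~0.1
  bit/h but interval-by-interval counts may differ.
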