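# pulseinfo

Information transmission rates of pulsatile receptor–reporter signaling,
estimated from single-cell trajectories with a neural decoder, plus
in-silico stimulation-protocol optimization (channel-capacity estimation).

## The problem

Optogenetic experiments stimulate cells with trains of light pulses whose
inter-pulse intervals `L` (whole minutes) are drawn from a distribution
`p(L)`; a kinase translocation reporter (KTR) records each cell's response
as a per-minute trajectory. How many bits per hour does the pathway carry
from receptor to reporter? The input entropy rate of such an interval
encoding is `H(L)/E[L]` bits per minute, and the transmitted rate is

```
b(X;Y) = H(X) − H(X|Y)   per time point,
```

the input rate minus the uncertainty that remains after seeing the
response. `pulseinfo` estimates a *lower bound* on `b` by training a small
MLP to predict, for every minute `k`, the pulse indicator `x_k` from the
standardized trajectory slice, the time since the previous pulse `last_k`,
a responsiveness score `s`, and condition covariates. The decoder outputs a
*logit Bayesian update* added to the protocol prior (the renewal hazard
`p(L = l)/P(L ≥ l)`):

```
logit p_θ(x_k = 1 | …) = u_Bayes + logit p(x_k = 1 | last_k)
b ≈ (1/D) Σ_{j,k} [ log2 p_θ(x_k | …) − log2 p(x_k | last_k) ]
```

Per-cell bitrates `b_j` (the same average per track, ×60 for bit/h) split
the population into transmitting and non-transmitting cells by the
longest-prefix-averaging-negative rule. A protocol optimizer then reweights
the measured `(interval, last)` data groups under candidate interval
distributions (logits over 5–90 min, score-function gradients with frozen
importance sampling, smoothness penalty `α‖ΔΔ log p‖²`) to estimate the
channel capacity from a single experiment.

A synthetic-data module generates raw track tables with the statistical
structure such experiments produce — a fast negative "dip" ~2 min after a
pulse, a slower positive "peak" ~7 min after it with refractory recovery
(half-time 8.5 min), transmitting/non-transmitting mixtures, inhibitor
conditions, autocorrelated noise, spatially clustered phenotypes — so the
whole pipeline is testable without any downloads.

## Worked example

```
python examples/02_bitrate_from_tracks.py
```

```
Simulated 200 cells x 1116 min (223200 table rows)
200 tracks -> 202000 (cell, minute) data points

Input entropy rate:      16.44 bit/h
Population bitrate:      10.51 bit/h (lower bound on transmitted information)
Fraction transmitting:    0.67 (simulated: 0.67)
Transmitting-cell rate:  15.69 bit/h
Single-cell bitrates:    -0.3 .. 16.4 bit/h (negative values = decoder misled by aberrant cells)
```

The simulated population mixes 65% responding cells with 35% silent ones;
the decoder recovers the mixture fraction exactly and bounds the
transmitted information at 10.5 of the 16.4 bit/h sent. The other examples
cover protocol construction and entropy rates (`01`), dip-only/peak-only
channel decoding (`03`), capacity estimation by protocol optimization
(`04`, capacity 22.4 bit/h for a fast-recovering channel, with probability
mass shifted onto short intervals), and interval-resolved diagnostics plus
spatial neighbour analysis (`05`).

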