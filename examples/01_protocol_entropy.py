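"""Build interval-encoded stimulation protocols and compute their entropy rates.

The input information rate of a renewal pulse train is H(L)/E[L] bits per
minute: the entropy of the interval distribution divided by the mean
interval.  Two reference points: per-minute Bernoulli(1/2) pulses are the
1-minute-resolution ceiling (60 bit/h), and the study-style protocol —
Gamma(shape 4, scale 5 min) intervals discretized to 5..35 min, realized
over a ~17-h budget with every short interval occurring at least twice —
lands at ~16.4 bit/h.
"""

import numpy as np

import pulseinfo as pi

bernoulli = pi.geometric_interval_distribution(q=0.5)
print(f"Bernoulli(1/2) per-minute protocol: {pi.entropy_rate(bernoulli):.1f} bit/h")

gamma = pi.build_gamma_interval_distribution(shape=4, scale=5,
                                             support_min=5, support_max=35)
print(f"Discretized Gamma(4, 5 min) on 5..35 min: {pi.entropy_rate(gamma):.2f} bit/h")

seq = pi.realize_pulse_sequence(gamma, time_budget=1020)
emp = seq.empirical_distribution()
print(f"Realized sequence: {len(seq.pulse_minutes)} pulses over "
      f"{seq.total_length} min; empirical rate {pi.entropy_rate(emp):.2f} bit/h")

iv = seq.intervals
occurrences_13 = [int(iv[i - 1]) for i in range(1, len(iv)) if iv[i] == 13]
print(f"Intervals preceding the three 13-min intervals: {occurrences_13} "
      "(spread over the distribution's quantiles for fair per-interval stats)")

hazard = pi.hazard_from_distribution(emp)
print(f"Hazard (per-minute pulse prior): h(5) = {hazard[5]:.3f}, "
      f"h(20) = {hazard[20]:.3f}, h(max) = {hazard[int(emp.support[-1])]:.0f}")
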