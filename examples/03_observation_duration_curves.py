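"""Build probability-of-observation curves from order-i inter-FP intervals.

For each order i, the interval I_i(n) = t(n+i) - t(n) is the time needed for
i further FPs after the n-th. The pooled empirical CDF of I_i answers: with
what probability will i FPs have occurred within T seconds of observation?
"""
import numpy as np

import fpwatch as fw

# a small cohort of 6 muscles at varied rates
trains = []
for k, rate in enumerate([4.0, 8.0, 15.0, 30.0, 60.0, 120.0]):
    spec = fw.RenewalSpec("gamma", rate, shape=3.5, seed=100 + k)
    trains.append(fw.generate_event_train(spec, 600.0)
                  .to_event_train(f"muscle{k}"))

summaries, curves, table = fw.analyze_event_trains(trains,
                                                   orders=(1, 2, 3, 4, 5))
print("muscle rates (/min):",
      [round(s.rate_per_min, 1) for s in summaries])
print("interval skewness  :",
      [round(s.skewness, 2) for s in summaries])

c1 = curves[1]
print(f"\nP(>=1 FP within 20 s) = {c1.probability_at(20.0):.3f}")
print(f"P(>=1 FP within 40 s) = {c1.probability_at(40.0):.3f}")
for i in (1, 5):
    d = fw.duration_for_probability(curves[i], 0.95)
    print(f"observe {i} FP(s) with p=0.95: record {d:.0f} s")
d1 = fw.duration_for_probability(c1, 1.0)
print(f"longest wait for a single FP in this cohort: {d1:.0f} s")
# The last number is the pooled maximum order-1 interval: the recording
# duration after which a silent muscle would very likely have no FPs at all.
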