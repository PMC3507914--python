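# Methods

## The interval model

FP occurrence in a relaxed muscle is modelled as a renewal process: the
inter-event intervals are independent and identically distributed. This is
the weakest model that determines everything the analysis uses — the order-i
interval I_i(n) = t(n+i) − t(n) is then a sum of i i.i.d. intervals, and the
probability of observing i FPs within an observation window T is the CDF of
that sum. Three interval families are implemented:

- **exponential** (Poisson process): interval skewness 2; the order-i
  interval is Gamma(i, λ), used as the closed-form oracle throughout the
  test suite;
- **gamma(shape s)**: skewness 2/√s. The default study shape is **3.5**,
  giving skewness ≈ 1.07 — the scale reported for patient inter-FP-interval
  distributions (≈ 1, strongly right-skewed: many short intervals, few long
  ones). A gamma with s > 1 is also more regular than Poisson at short lags,
  which matches the existence of a motor-unit refractory period;
- **lognormal(σ)** for heavier tails.

Trains start at time 0 with a full first interval; events at or beyond the
recording end are dropped, and the censored interval from the last FP to the
end of the recording is **excluded** (the interval formula spans n ≤ N−i
only). This biases the extreme tail of the pooled distribution slightly
downward; it is the same censoring any finite recording imposes.

Events from different simulated motor units closer than 1 ms are merged and
counted once: FPs are pooled regardless of waveform or source, since any FP
carries the same diagnostic weight. No spike sorting is attempted anywhere.

## The synthetic study

The default cohort emulates the study design the package targets: **29
muscles**, FP rates **log-uniform over 3.5–139 events/min** (log-uniform
because the reported range spans 1.6 decades and muscles at the low end are
clinically the interesting ones), recording durations **uniform over
215–764 s**, gamma(3.5) intervals. Two of every three muscles use the 8×8
grid (4 mm inter-electrode distance, intrinsic hand muscles), every third
the 20-channel 5 mm linear bar (biceps), with 2–5 randomly chosen dead
channels per recording. A master seed fixes every child seed through
`numpy.random.SeedSequence`, so the whole study is bit-reproducible.

## Signal synthesis

Each FP contributes a temporal kernel — by default the first derivative of a
Gaussian (biphasic, 10 ms support, σ = duration/6), peak-normalised and
aligned so its largest-magnitude sample sits at the event time — scaled per
channel by a spatial attenuation profile and added to band-limited noise:

- **amplitude**: 100 µV at the best-placed channel. No amplitude statistics
  exist for these muscles in surface recordings, so this is a free modeling
  choice, exposed in `FPWaveformModel`; what matters downstream is only the
  ratio to the noise floor (the benchmark SNR, peak/noise RMS, is 10).
- **spatial profile**: Gaussian decay exp(−d²/2λ²) with length constant
  λ = 10 mm, normalised so the channel nearest the source receives the
  nominal amplitude. Gaussian rather than exponential decay models the
  smooth blurring of a subcutaneous source by the volume conductor, and
  keeps channels within one length constant above ~0.6× the peak — enough
  that they clear a 5σ threshold at SNR 10. Exponential decay is available
  as an option.
- **latency jitter**: per-channel Gaussian jitter, SD 0.5 ms, mimicking
  propagation delays across the array.
- **noise**: white Gaussian shaped to the 20–500 Hz system band (4th-order
  Butterworth, causal — noise phase is irrelevant) and rescaled to the
  target RMS per channel. Dead channels carry a flat zero trace and are
  flagged in the live mask.

What this generator does **not** emulate: motor-unit waveform diversity
(every source uses the same kernel shape), amplitude variability between
discharges, non-stationary rates, movement or mains artifacts, and real
volume-conductor physics. Passing the detector benchmark therefore shows
that the detection-and-analysis chain is correct and well-calibrated under
the stated model, not that the detector is validated against clinical
recordings.

## Detection

Per channel: zero-phase (forward–backward) 20–500 Hz band-pass, so detection
times are not phase-shifted; noise sigma estimated as MAD/0.6745, which is
insensitive to the sparse large spikes the channel is supposed to contain;
every contiguous supra-threshold excursion of |x| (threshold 5σ, both
polarities) is reduced to the time of its largest peak; peaks closer than
the 20 ms refractory period keep only the larger.

Across channels: working from the largest peak downward, all detections
within the 10 ms coincidence window join one event, timed at that largest
peak (robust to low-amplitude channels). Events supported by fewer than 3
distinct channels (2 on the linear array, which is 1-D and shorter) are
discarded as single-channel artifacts. Channels flagged dead, flat channels,
and channels whose noise sigma exceeds 10× the median channel noise are
excluded before detection.

Degenerate input: on a noise-free channel the MAD underflows to numerical
residue. When the MAD is negligible relative to the channel peak (< 10⁻⁶×),
the threshold falls back to the mean absolute deviation, floored at a
quarter of the channel peak so that the band-pass filter's own ringing
(half-cycles of the 20 Hz edge) cannot cross it. Detection thus degrades
gracefully as noise → 0 and remains invariant to overall amplitude scaling
in all regimes.

All thresholds are noise-relative and every parameter (band, threshold_k,
merge window, consensus count, refractory, polarity) is exposed in
`DetectionConfig`; the defaults follow standard extracellular spike-
detection practice.

## Interval analysis

The pooled cumulative curve is right-continuous (intervals ≤ T are counted),
on a duration grid from 0 to the maximum pooled interval with a default step
of 1 s; consequently `duration_for_probability(curve, 1.0)` equals the
maximum pooled interval up to one grid step, exactly. Two pooling modes are
implemented because the choice is genuinely open: **all_intervals** (every
interval from every muscle, equal weight — the default, matching a
whole-dataset cumulative frequency distribution) and **per_muscle_max**
(one value, the muscle's longest order-i interval — a conservative
worst-case variant). Note the two can differ a lot: equal-weight pooling is
dominated by high-rate muscles, which contribute the most intervals.

Skewness is the Fisher–Pearson adjusted sample skewness of order-1
intervals, defined for N ≥ 4 (NaN below; exactly 0 for equally spaced
events, whose interval spread is zero). Trains with N ≤ i contribute nothing
at order i rather than excluding the muscle outright.

Order-i intervals from one train overlap (the index n slides by one), so
pooled samples are m-dependent with ~i-fold variance inflation relative to
i.i.d. draws; the Kolmogorov–Smirnov checks in the test suite account for
this by pooling ≥ 20 000 intervals.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations so the whole
chain stays cheap while estimator noise stays well inside the asserted
tolerances: the renewal oracle uses 200 Poisson trains × 600 s at 12/min
(≈ 23 000 pooled intervals per order; expected KS ≈ 0.01); skewness recovery
pools 20 gamma trains of ≥ 500 events; the detector benchmark runs the full
29-muscle cohort with durations scaled down tenfold (21.5–76.4 s), which
still pools ≈ 750 events. Event-time matching uses greedy one-to-one
two-pointer matching at ±5 ms. Quantile checks on 1 s grids use a finer
0.25 s grid where the quantity itself is of order 15 s, since grid
quantization alone would otherwise dominate the comparison.

All times are float seconds from the first sample; event CSVs store times at
1 µs precision (sub-µs digits are meaningless at 2 kHz sampling). Signals
are float32 end to end — acquisition-realistic and lossless through the
native `.dat` + JSON-sidecar layout, so write→read→detect is bit-identical
to detecting in memory.

## Known limitations

- The probability-of-observation numbers produced by the synthetic study
  depend on the assumed rate distribution and interval family; they
  characterise the method, not any patient population.
- Equal-weight pooling over-represents high-rate muscles (see above); use
  `per_muscle_max` for a sensitivity analysis.
- The detector's consensus rule assumes a spatially coherent source; highly
  localised FPs visible on fewer channels than `min_channels` would be
  rejected as artifacts.
- No confidence bands on the curves, no hazard/renewal-density estimation,
  and no test of rate stationarity.
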