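"""Detect FPs in a synthetic recording and score them against ground truth.

The detector band-passes each channel (20-500 Hz, zero phase), thresholds at
5x the robust (MAD-based) noise sigma, and merges coincident peaks across
channels into consensus events. Here it runs on a 2-minute SNR-10 recording.
"""
import fpwatch as fw

spec = fw.RenewalSpec("gamma", mean_rate_per_min=24.0, shape=3.5, seed=7)
truth = fw.generate_event_train(spec, duration_s=120.0)
rec = fw.synthesize_recording(truth, fw.ArrayGeometry.grid(),
                              noise_rms_uv=10.0, dead_channels=[5, 42],
                              seed=8, name="demo")

train = fw.detect(rec)                       # default config: k=5, 3-channel consensus
scores = fw.detection_scores(train.times, truth.event_times, tolerance_s=0.005)
print(f"detected {train.n} FPs ({train.rate_per_min:.1f}/min), "
      f"truth had {truth.n_events}")
print(f"precision {scores.precision:.3f}, recall {scores.recall:.3f}, "
      f"F1 {scores.f1:.3f} at +/-5 ms")

events = fw.detect_events(rec)
widths = [len(e.channels_hit) for e in events]
print(f"median channels supporting an event: {sorted(widths)[len(widths)//2]}")
# F1 near 1.0 means the consensus detector recovers essentially every
# simulated FP at this signal-to-noise ratio without false positives.
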