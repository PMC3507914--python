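"""Event-time matching and detection scores against ground truth."""
from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["DetectionScores", "match_event_times", "detection_scores"]


class DetectionScores(NamedTuple):
    n_matched: int
    n_detected: int
    n_reference: int
    precision: float
    recall: float
    f1: float


def match_event_times(detected_s: np.ndarray, reference_s: np.ndarray,
                      tolerance_s: float = 0.005) -> int:
    """Number of one-to-one matches between two sorted time lists.

    Two-pointer greedy matching: a detected and a reference event match when
    they differ by at most the tolerance; each event is used at most once.
    """
    d = np.asarray(detected_s, dtype=float)
    r = np.asarray(reference_s, dtype=float)
    i = j = matched = 0
    while i < d.size and j < r.size:
        if abs(d[i] - r[j]) <= tolerance_s:
            matched += 1
            i += 1
            j += 1
        elif d[i] < r[j]:
            i += 1
        else:
            j += 1
    return matched


def detection_scores(detected_s: np.ndarray, reference_s: np.ndarray,
                     tolerance_s: float = 0.005) -> DetectionScores:
    """Precision, recall and F1 of detected event times at a matching tolerance."""
    d = np.asarray(detected_s, dtype=float)
    r = np.asarray(reference_s, dtype=float)
    m = match_event_times(d, r, tolerance_s)
    prec = m / d.size if d.size else (1.0 if r.size == 0 else 0.0)
    rec = m / r.size if r.size else 1.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return DetectionScores(m, int(d.size), int(r.size), prec, rec, f1)
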