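import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_events(truth_times, detected_times, tolerance=0.0025):
    """Greedy one-to-one matching of detected events to ground truth.

    Returns (n_true_positive, precision, recall).
    """
    truth_times = np.asarray(truth_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    used = np.zeros(detected_times.size, dtype=bool)
    tp = 0
    for t in truth_times:
        d = np.abs(detected_times - t)
        d[used] = np.inf
        if d.size and d.min() <= tolerance:
            used[np.argmin(d)] = True
            tp += 1
    precision = tp / detected_times.size if detected_times.size else 0.0
    recall = tp / truth_times.size if truth_times.size else 1.0
    return tp, precision, recall
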