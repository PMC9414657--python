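"""Shared oracles for tolerance-matching tests."""

from functools import lru_cache

import numpy as np


def optimal_tp(detected, truth, tol):
    """Exhaustive maximum one-to-one matching (oracle for small lists).

    Recurses over detected peaks, trying every free true peak within the
    tolerance (tracked in a bitmask), so every one-to-one assignment is
    explored.
    """
    detected, truth = list(detected), list(truth)

    @lru_cache(maxsize=None)
    def best(i, used_mask):
        if i == len(detected):
            return 0
        score = best(i + 1, used_mask)  # leave detected[i] unmatched
        for j, t in enumerate(truth):
            if not used_mask & (1 << j) and abs(detected[i] - t) <= tol:
                score = max(score, 1 + best(i + 1, used_mask | (1 << j)))
        return score

    return best(0, 0)


def random_instance(rng, refractory=30):
    """Physiologically spaced truth + jittered/dropped/spurious detections."""
    n_true = int(rng.integers(0, 8))
    gaps = rng.integers(refractory, 120, size=n_true)
    truth = np.cumsum(gaps) + int(rng.integers(0, 50)) if n_true else np.empty(0, dtype=np.int64)
    detected = []
    for t in truth:
        r = rng.random()
        if r < 0.7:  # close hit
            detected.append(int(t) + int(rng.integers(-4, 5)))
        elif r < 0.85:  # miss beyond tolerance
            detected.append(int(t) + int(rng.integers(7, 15)) * int(rng.choice([-1, 1])))
        # else dropped
    n_spur = int(rng.integers(0, 3))
    if n_spur:
        upper = int(truth[-1]) + 100 if n_true else 500
        detected.extend(int(v) for v in rng.integers(0, upper, size=n_spur))
    detected = np.unique(np.asarray(detected, dtype=np.int64))
    return detected, np.asarray(truth, dtype=np.int64)
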