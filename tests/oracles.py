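"""Independent brute-force oracles used by multiple test modules."""

import numpy as np


def brute_force_es(scores, member_positions, weight_p):
    """Independent running-sum oracle: evaluate the sum at every rank.

    ``scores`` descending; ``member_positions`` 0-based.  Returns the signed
    maximum deviation (earliest extremum on ties).
    """
    N = len(scores)
    members = set(member_positions)
    h = len(members)
    if weight_p == 0:
        w = {i: 1.0 for i in members}
    else:
        w = {i: abs(scores[i]) ** weight_p for i in members}
    total = sum(w.values())
    if total == 0:
        w = {i: 1.0 for i in members}
        total = float(h)
    running = 0.0
    best = 0.0
    for i in range(N):
        if i in members:
            running += w[i] / total
        else:
            running -= 1.0 / (N - h)
        if abs(running) > abs(best):
            best = running
    return best


def brute_force_path_score(scores, member_positions):
    """Max of the unweighted running sum, evaluated at every rank."""
    N = len(scores)
    members = set(member_positions)
    h = len(members)
    running, best = 0.0, -np.inf
    for i in range(N):
        running += 1.0 / h if i in members else -1.0 / (N - h)
        best = max(best, running)
    return best
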