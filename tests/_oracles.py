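"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own code paths: mutual information
is summed from Counter tables and the mRMR criterion is evaluated
exhaustively at every step.
"""

import math
from collections import Counter

import numpy as np


def mi_oracle(x, y):
    """Plug-in mutual information in bits, Counter-based."""
    n = len(x)
    cxy, cx, cy = Counter(zip(x, y)), Counter(x), Counter(y)
    return sum(
        v / n * math.log2((v / n) / ((cx[a] / n) * (cy[b] / n)))
        for (a, b), v in cxy.items()
    )


def greedy_mid_oracle(disc, y, top_m):
    """Exhaustive per-step maximization of the MID criterion
    I(f;c) - mean_{s in S} I(f;s), lowest index on ties."""
    n_feat = disc.shape[1]
    rel = [mi_oracle(disc[:, j].tolist(), list(y)) for j in range(n_feat)]
    selected = []
    for _ in range(min(top_m, n_feat)):
        best, best_score = None, -np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            if selected:
                red = np.mean(
                    [mi_oracle(disc[:, j].tolist(), disc[:, s].tolist()) for s in selected]
                )
            else:
                red = 0.0
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


def brute_force_tail(N, K, n, k):
    """Explicit binomial-coefficient hypergeometric tail sum."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
    ) / math.comb(N, n)
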