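"""Independent test oracles, deliberately naive.

The local-alignment oracle enumerates every order-preserving matching of
query positions to subject positions (a local alignment is exactly such a
matching); gaps between consecutive matched pairs are charged open + k*extend
per side.  Exhaustive and exponential-free only because test sequences are
tiny (sum over k of C(n,k) * C(m,k) terms).
"""

from itertools import combinations

import numpy as np

from sgsearch.engine import encode


def brute_force_local_score(query: str, subject: str, matrix, gap_open: int,
                            gap_extend: int) -> int:
    q = encode(query)
    s = encode(subject)
    nq, ns = len(q), len(s)
    best = 0  # the empty alignment scores 0
    for k in range(1, min(nq, ns) + 1):
        qsubs = np.array(list(combinations(range(nq), k)))
        ssubs = np.array(list(combinations(range(ns), k)))
        # substitution total for every (query subset, subject subset) pair
        sub = matrix[q[qsubs][:, None, :], s[ssubs][None, :, :]].sum(axis=-1)
        gq = _internal_gap_cost(qsubs, gap_open, gap_extend)
        gs = _internal_gap_cost(ssubs, gap_open, gap_extend)
        total = sub - gq[:, None] - gs[None, :]
        best = max(best, int(total.max()))
    return best


def _internal_gap_cost(subsets: np.ndarray, gap_open: int, gap_extend: int) -> np.ndarray:
    if subsets.shape[1] < 2:
        return np.zeros(subsets.shape[0], dtype=int)
    runs = np.diff(subsets, axis=1) - 1  # unmatched residues between matches
    return ((runs > 0) * gap_open + runs * gap_extend * (runs > 0)).sum(axis=1)
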