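"""Score-only Smith-Waterman kernel (affine gaps), numba-compiled.

The dynamic program keeps one row of H (best score ending at cell) and E
(best score ending in a query gap); F (subject gap) is carried in a scalar.
A gap of length k costs open + k*extend, i.e. the first gapped residue
costs open+extend.  Scores are floored at zero (local alignment).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_best_scores(query, db_concat, offsets, matrix, gap_open, gap_extend):
    """Best local alignment score of ``query`` against each subject.

    query : int8 residue codes
    db_concat : int8 codes of all subjects, concatenated
    offsets : int64 array of length n_subjects+1 delimiting each subject
    matrix : int32 (24, 24) substitution scores
    """
    n = query.shape[0]
    nsub = offsets.shape[0] - 1
    out = np.zeros(nsub, dtype=np.int64)
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.zeros(n + 1, dtype=np.int64)
    neg = np.int64(-(1 << 60))
    oe = np.int64(gap_open + gap_extend)
    ge = np.int64(gap_extend)
    for s in range(nsub):
        for i in range(n + 1):
            H[i] = 0
            E[i] = neg
        best = np.int64(0)
        for j in range(offsets[s], offsets[s + 1]):
            c = db_concat[j]
            diag = np.int64(0)
            F = neg
            for i in range(1, n + 1):
                e = E[i] - ge
                t = H[i] - oe
                if t > e:
                    e = t
                E[i] = e
                f = F - ge
                t = H[i - 1] - oe
                if t > f:
                    f = t
                F = f
                h = diag + matrix[query[i - 1], c]
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                diag = H[i]
                H[i] = h
                if h > best:
                    best = h
        out[s] = best
    return out
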