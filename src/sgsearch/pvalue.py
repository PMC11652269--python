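"""Shuffle-based Studentized-Gumbel P-values and FWER control.

The procedure: shuffle the query m times, search each shuffle against the
database exactly as the original query was searched, and record the m
database-wide optimal scores Y_1..Y_m.  An observed score S is studentized,
T = (S - Ybar) / sigma_Y, and its P-value is the tabulated SG_m right tail
at T.  Reporting every alignment with P <= alpha controls the family-wise
error rate at alpha: among the k alignments of one query, some null
alignment is reported only if the *maximal* score's P-value is <= alpha,
an event of probability <= alpha when the P-values are valid.

One null sample is shared by all alignments of a (query, database,
engine-settings) run; studentization makes the P-value invariant under
affine transformations of the score scale, so raw scores and bit scores
give identical answers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .engine import AlignmentHit, SequenceRecord
from .table import SGTable

__all__ = [
    "NullSample",
    "shuffle_query",
    "collect_null_sample",
    "studentize",
    "sg_p",
    "fwer_select",
    "by_adjust",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullSample:
    """The m database-wide optimal scores of the shuffled queries.

    ``seed`` is the master seed; per-shuffle seeds are spawned from it with
    ``numpy.random.SeedSequence(seed, spawn_key=(j,))`` for shuffle j, so a
    published run is replayable from the master seed alone.
    """

    scores: np.ndarray
    seed: int | None = None
    engine_id: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size < 2:
            raise ValueError("a null sample needs at least 2 scores")
        object.__setattr__(self, "scores", scores)

    @property
    def m(self) -> int:
        return self.scores.size

    @property
    def ybar(self) -> float:
        return float(self.scores.mean())

    @property
    def sy(self) -> float:
        # (m-1)-denominator, matching the two-sample-t analogy
        return float(self.scores.std(ddof=1))


def shuffle_query(sequence: str, seed) -> str:
    """Uniformly random permutation of the residues (Fisher-Yates).

    Preserves length and residue multiset; reproducible for a fixed seed.
    """
    if isinstance(sequence, SequenceRecord):
        sequence = sequence.residues
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def shuffle_seeds(master_seed, m: int) -> list[np.random.SeedSequence]:
    """The fixed master-seed -> per-shuffle-seed splitting rule.

    Shuffle j gets ``SeedSequence(master_seed, spawn_key=(j,))``; an
    existing SeedSequence master is split with its own ``spawn``, which
    applies the same rule one level down.
    """
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed.spawn(m)
    return [np.random.SeedSequence(master_seed, spawn_key=(j,)) for j in range(m)]


def collect_null_sample(query, engine, m: int, seed) -> NullSample:
    """Search m shuffles of ``query`` and record each database-wide best score.

    ``engine`` must expose ``best_score(residues) -> float`` configured
    identically (matrix, penalties, database) to the original search.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    residues = query.residues if isinstance(query, SequenceRecord) else query
    scores = np.empty(m)
    for j, ss in enumerate(shuffle_seeds(seed, m)):
        shuffled = shuffle_query(residues, ss)
        try:
            scores[j] = engine.best_score(shuffled)
        except Exception as exc:
            raise RuntimeError(f"engine failed on shuffle {j}: {exc}") from exc
    return NullSample(scores=scores, seed=seed,
                      engine_id=getattr(engine, "engine_id", ""))


def studentize(S, ns: NullSample):
    """T = (S - Ybar) / sigma_Y.  Undefined (nan) when sigma_Y = 0."""
    sy = ns.sy
    S = np.asarray(S, dtype=float)
    if sy == 0:
        out = np.full(S.shape, np.nan)
        return out if out.ndim else float("nan")
    out = (S - ns.ybar) / sy
    return out if out.ndim else float(out)


def sg_p(S: float, ns: NullSample, table: SGTable) -> float:
    """SG_m P-value of an observed database-wide score S.

    T <= 0 maps to 1; T past the table's precision cutoff maps to the tail
    at the cutoff.  A degenerate null sample (sigma_Y = 0, e.g. a
    homopolymeric query whose shuffles are all identical) yields 1 when
    S <= Ybar and the cutoff tail — the limit of T -> +inf — when S > Ybar.
    """
    if table.m != ns.m:
        raise ValueError(f"table was built for m={table.m}, null sample has m={ns.m}")
    if ns.sy == 0:
        if S > ns.ybar:
            logger.warning("degenerate null sample (sigma_Y = 0) with S > Ybar; "
                           "returning the precision-cutoff tail")
            return table.tail_at_cutoff
        return 1.0
    t = (S - ns.ybar) / ns.sy
    return table.tail(t)


def fwer_select(hits, ns: NullSample, table: SGTable, alpha: float = 0.05):
    """Fill SG P-values for every hit and flag those with p <= alpha.

    All hits must come from the same query/database/engine run as the null
    sample.  Returns new AlignmentHit objects; input is left untouched.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    out = []
    for h in hits:
        t = studentize(h.score, ns)
        p = sg_p(h.score, ns, table)
        out.append(replace(h, studentized=None if np.isnan(t) else float(t),
                           pvalue=p, significant=bool(p <= alpha)))
    return out


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under dependence).

    Inflates by the harmonic sum H(k) = 1 + 1/2 + ... + 1/k, which makes the
    procedure control the FDR for arbitrarily dependent hypotheses — the
    right companion to P-values of overlapping alignments.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]
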