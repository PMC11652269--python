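"""Validity and power harness for alignment significance measures.

The central experiment: draw from the *null* distribution of database
searches by repeatedly shuffling a query and recording, per shuffle, the
maximal alignment score (and the minimal engine E-value when the engine
reports one).  A valid P-value should then be stochastically no smaller
than uniform: the fraction of replicates with P <= alpha must not
significantly exceed alpha.  Probability plots and one-sided binomial
exceedance tests quantify this; a resampling scheme turns the simulated
score sample into SG P-values without any extra engine work.

Also included is the "MLE P-value" diagnostic — fitting a Gumbel to the
small null sample and reading the tail at S — which is anti-conservative
and serves as a cautionary contrast to the studentized approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gumbel import fit_gumbel_mle, fit_gumbel_mle_batch, gumbel_tail
from .pvalue import shuffle_query, shuffle_seeds
from .table import SGTable

__all__ = [
    "CalibrationResult",
    "DEFAULT_ALPHAS",
    "simulate_null_scores",
    "sg_pvalues_by_resampling",
    "calibrate",
    "probability_plot_data",
    "exceedance_binomial_test",
    "mle_pvalue",
    "mle_pvalues_batch",
    "count_discoveries",
]

logger = logging.getLogger(__name__)

#: Canonical significance cutoffs examined in the calibration experiments.
DEFAULT_ALPHAS = (0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class CalibrationResult:
    """Per-replicate null records plus exceedance summaries at each alpha."""

    records: pd.DataFrame  # columns: score, min_evalue, sg_pvalue (subset may be NaN)
    n_replicates: int
    summary: pd.DataFrame  # columns: alpha, count, frequency, binomial_pvalue
    meta: dict = field(default_factory=dict)

    def exceedance(self, alpha: float, column: str = "sg_pvalue") -> float:
        vals = self.records[column].to_numpy()
        return float((vals <= alpha).sum() / self.n_replicates)


def simulate_null_scores(query, engine, n_replicates: int, seed) -> pd.DataFrame:
    """Null draws: per replicate, search one independent shuffle of ``query``.

    Returns a DataFrame with the maximal alignment score ``score`` and, for
    engines that report E-values, the minimal E-value ``min_evalue`` of each
    shuffled-query search (NaN for the built-in engine).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .engine import SequenceRecord

    residues = getattr(query, "residues", query)
    scores = np.empty(n_replicates)
    min_e = np.full(n_replicates, np.nan)
    reports_evalue = bool(getattr(engine, "reports_evalue", False))
    for j, ss in enumerate(shuffle_seeds(seed, n_replicates)):
        shuffled = shuffle_query(residues, ss)
        try:
            if reports_evalue:
                hits, best = engine.search(
                    SequenceRecord(id=f"shuffle_{j}", residues=shuffled))
                scores[j] = best
                evs = [h.evalue for h in hits if h.evalue is not None]
                if evs:
                    min_e[j] = min(evs)
            else:
                scores[j] = engine.best_score(shuffled)
        except Exception as exc:
            raise RuntimeError(f"engine failed on replicate {j}: {exc}") from exc
    return pd.DataFrame({"score": scores, "min_evalue": min_e})


def sg_pvalues_by_resampling(scores, table: SGTable, seed) -> np.ndarray:
    """SG P-value per score, with null samples resampled from the score pool.

    For each observed score S_j, the auxiliary null sample of size m is
    drawn with replacement from the full set of simulated optimal scores —
    the calibration shortcut that avoids m extra searches per replicate.
    Degenerate resamples (zero SD) get P = 1 when S <= Ybar, else the
    cutoff tail.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n == 0:
        raise ValueError("empty score sample")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    chunk = max(1, min(n, 200_000 // max(table.m, 1)))
    for start in range(0, n, chunk):
        block = s[start:start + chunk]
        y = s[rng.integers(0, n, size=(block.size, table.m))]
        ybar = y.mean(axis=1)
        sy = y.std(axis=1, ddof=1)
        t = np.full(block.size, -np.inf)
        np.divide(block - ybar, sy, out=t, where=sy > 0)
        deg_hi = (sy == 0) & (block > ybar)
        for i in range(block.size):
            out[start + i] = table.tail(float(t[i])) if np.isfinite(t[i]) else 1.0
        out[start:start + chunk][deg_hi] = table.tail_at_cutoff
    return out


def calibrate(scores, table: SGTable, seed, alphas=DEFAULT_ALPHAS,
              min_evalues=None, meta=None) -> CalibrationResult:
    """Assemble a :class:`CalibrationResult` from simulated null scores.

    Computes SG P-values via resampled null samples, then for each alpha the
    exceedance count/frequency and — only when the frequency exceeds alpha,
    a liberal tendency — the one-sided binomial P-value for it.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    pvals = sg_pvalues_by_resampling(s, table, seed)
    rows = []
    for a in alphas:
        k = int((pvals <= a).sum())
        freq = k / n
        binom_p = exceedance_binomial_test(k, n, a) if freq > a else np.nan
        rows.append((a, k, freq, binom_p))
    records = pd.DataFrame({
        "score": s,
        "min_evalue": (np.asarray(min_evalues, dtype=float)
                       if min_evalues is not None else np.full(n, np.nan)),
        "sg_pvalue": pvals,
    })
    summary = pd.DataFrame(rows, columns=["alpha", "count", "frequency",
                                          "binomial_pvalue"])
    return CalibrationResult(records=records, n_replicates=n, summary=summary,
                             meta=dict(meta or {}, seed=seed, m=table.m))


def probability_plot_data(values) -> tuple[np.ndarray, np.ndarray]:
    """Probability-plot coordinates for a sample of P-values (or E-values).

    For each value v: x = log10(fraction of the sample <= v), y = log10(v),
    sorted by v.  Ties use the <= convention (fraction counts every value
    less than or equal to v).  A valid uniform P-value sample tracks the
    diagonal y = x; dips below it signal liberality.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value sample")
    if np.any((v <= 0) | (v > 1)):
        raise ValueError("values must lie in (0, 1]")
    v = np.sort(v)
    frac = np.searchsorted(v, v, side="right") / v.size
    return np.log10(frac), np.log10(v)


def exceedance_binomial_test(k: int, n: int, alpha: float) -> float:
    """One-sided P(X >= k) for X ~ Binomial(n, alpha)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, alpha))


def mle_pvalue(S: float, null_scores) -> float:
    """Gumbel-MLE P-value of S given a null sample — a *diagnostic*.

    Fits Gumbel(mu, lam) to the null scores by maximum likelihood and
    returns the fitted right tail at S.  With small null samples these
    P-values are anti-conservative (too small too often); they are provided
    to reproduce that warning, not for production use.
    """
    params = fit_gumbel_mle(null_scores)
    return float(gumbel_tail(S, params))


def mle_pvalues_batch(S, null_samples: np.ndarray) -> np.ndarray:
    """Row-wise :func:`mle_pvalue`: S[i] against null_samples[i, :]."""
    S = np.asarray(S, dtype=float)
    mu, lam = fit_gumbel_mle_batch(null_samples)
    return -np.expm1(-np.exp(-lam * (S - mu)))


def count_discoveries(values, cutoff: float, labels=None):
    """Number of values <= cutoff; split by label when labels are given.

    Returns an int without labels, otherwise a dict label -> count (the
    power-comparison counting at cutoffs like 0.01 and 0.05).
    """
    v = np.asarray(values, dtype=float)
    hit = v <= cutoff
    if labels is None:
        return int(hit.sum())
    labels = np.asarray(labels)
    if labels.shape != v.shape:
        raise ValueError("labels must align with values")
    return {lab: int(hit[labels == lab].sum()) for lab in np.unique(labels)}
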