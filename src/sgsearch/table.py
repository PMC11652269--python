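"""Tabulating the Studentized-Gumbel(m) right tail by importance sampling.

The SG_m distribution is the law of T = (S - Ybar) / sigma_Y when S and the
null sample Y_1..Y_m are iid Gumbel.  T is pivotal: its distribution depends
on m only, not on the Gumbel location or rate, so it can be tabulated once
per m and reused for every query/database/matrix combination.

The far right tail (T of 20, 30, ...) is unreachable by plain Monte-Carlo,
so S is drawn from a shifted, widened Gumbel proposal and each draw is
weighted by the density ratio (Radon-Nikodym derivative) of the target to
the proposal.  Weighted draws are binned on a fixed grid of studentized
values; the estimated tail G(t) at a bin is the weight mass at that bin and
above, divided by the number of draws.  A coefficient-of-variation rule
marks the largest t at which the estimate is still trusted.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .gumbel import GumbelParams, log_gumbel_density

__all__ = [
    "SGTableConfig",
    "SGTable",
    "importance_weight",
    "build_sg_table",
    "precision_cutoff",
    "save_table",
    "load_table",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
_CHUNK = 250_000  # draws per chunk; bounds memory at ~ m * _CHUNK doubles


@dataclass(frozen=True)
class SGTableConfig:
    """Geometry and sampling plan for one SG_m table.

    Defaults follow the reference tabulation: null samples of size m = 50
    from Gumbel(mu=0, scale=3), proposal Gumbel(mu=33, scale=15), bins of
    width 0.001 spanning [0, 45), and a CV precision threshold of 0.01.
    """

    m: int = 50
    n_draws: int = 10**8
    bin_width: float = 0.001
    t_min: float = 0.0
    t_max: float = 45.0
    y_params: GumbelParams = field(default_factory=lambda: GumbelParams(0.0, 1.0 / 3.0))
    proposal_params: GumbelParams = field(default_factory=lambda: GumbelParams(33.0, 1.0 / 15.0))
    cv_threshold: float = 0.01
    cv_mode: str = "standard_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")
        if self.cv_mode not in ("standard_error", "tail_weights"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        nb = (self.t_max - self.t_min) / self.bin_width
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError("(t_max - t_min) / bin_width must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.t_max - self.t_min) / self.bin_width))

    def bin_centers(self) -> np.ndarray:
        return self.t_min + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class SGTable:
    """Binned right-tail probabilities G(t) of the SG_m distribution."""

    m: int
    t_min: float
    bin_width: float
    log10_tail: np.ndarray  # per-bin log10 G(t); -inf where no mass
    tail_se: np.ndarray  # per-bin standard error of the G(t) estimate
    precision_cutoff: float  # largest trustworthy bin center
    tail_at_cutoff: float  # G(precision_cutoff)
    n_draws: int
    seed: int
    y_params: GumbelParams
    proposal_params: GumbelParams
    cv_threshold: float
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return self.log10_tail.size

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t_min + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def t_max(self) -> float:
        return self.t_min + self.n_bins * self.bin_width

    def tail(self, t: float) -> float:
        """G(t): the tabulated SG_m right tail at studentized value t.

        Values <= 0 map to 1 (not an interesting score); values past the
        precision cutoff map to G(cutoff), the smallest trusted tail.
        Lookup is a step function at bin resolution, no interpolation.
        """
        if not math.isfinite(t):
            raise ValueError("t must be finite")
        if t <= 0:
            return 1.0
        if t < self.t_min:
            return 1.0
        if t > self.precision_cutoff:
            return self.tail_at_cutoff
        idx = int((t - self.t_min) / self.bin_width)
        idx = min(idx, self.n_bins - 1)
        return float(10.0 ** self.log10_tail[idx])

    def raw_tail(self, t: float) -> float:
        """Tabulated G at the bin containing t, ignoring the precision cutoff.

        Useful for inspecting the Monte-Carlo estimate beyond the trusted
        range; production P-values should use :meth:`tail`.
        """
        if not self.t_min <= t < self.t_max:
            raise ValueError(f"t={t} outside the tabulated range")
        idx = int((t - self.t_min) / self.bin_width)
        return float(10.0 ** self.log10_tail[min(idx, self.n_bins - 1)])


def importance_weight(s, target: GumbelParams, proposal: GumbelParams):
    """Density ratio f_target(s) / f_proposal(s), computed on the log scale."""
    logw = log_gumbel_density(s, target) - log_gumbel_density(s, proposal)
    return np.exp(logw)


def _cutoff_scan(tail_count: np.ndarray, tail_sum: np.ndarray, tail_sum2: np.ndarray,
                 G: np.ndarray, centers: np.ndarray, cv_threshold: float,
                 t_min: float, mode: str, n_total: int | None) -> tuple[float, bool]:
    """Scan bins from the top down; return the first (largest-t) bin center
    whose tail coefficient of variation is <= cv_threshold.

    mode "standard_error" (default): CV = SE[G_hat(t)] / G(t), where the
    standard error treats all n_total draws (zeros for draws outside the
    tail) as the sample — this shrinks like 1/sqrt(n_total), so larger runs
    push the cutoff further into the tail.  mode "tail_weights": CV =
    sample SD of the weights in the tail / G(t) (the literal rule; it does
    not shrink with n_total and is kept for sensitivity analysis).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "standard_error":
            if n_total is None:
                raise ValueError("standard_error mode requires n_total")
            var = (tail_sum2 - tail_sum**2 / n_total) / max(n_total - 1, 1)
            sd = np.sqrt(np.maximum(var, 0.0) / n_total)
            usable = (tail_count >= 2) & (G > 0)
        elif mode == "tail_weights":
            var = ((tail_sum2 - tail_sum**2 / np.maximum(tail_count, 1))
                   / np.maximum(tail_count - 1, 1))
            sd = np.sqrt(np.maximum(var, 0.0))
            usable = (tail_count >= 2) & (G > 0)
        else:
            raise ValueError(f"unknown cv mode {mode!r}")
        cv = np.where(usable, sd / np.where(G > 0, G, 1.0), np.inf)
    ok = np.nonzero(cv <= cv_threshold)[0]
    if ok.size == 0:
        return float(t_min), False
    return float(centers[ok[-1]]), True


def precision_cutoff(bin_weights, tail, bin_centers, cv_threshold: float = 0.01,
                     mode: str = "tail_weights", n_total: int | None = None) -> float:
    """Largest bin center whose tail coefficient of variation is <= threshold.

    Parameters
    ----------
    bin_weights : sequence of per-bin weight collections (ordered by t).
    tail : per-bin tail estimates G(t) on the same grid.
    bin_centers : studentized values labelling the bins.
    cv_threshold : precision limit on the CV at a bin.
    mode : ``"tail_weights"`` divides the sample SD of the weights in the
        bin and above by G(t); ``"standard_error"`` (the table builder's
        default) divides the standard error of the importance-sampling
        estimator of G(t) by G(t) and requires ``n_total``, the total
        number of Monte-Carlo draws.
    n_total : total draw count behind ``tail`` (standard_error mode only).

    Returns t_min (the first bin's lower edge) when no bin qualifies.
    """
    weights = [np.asarray(w, dtype=float) for w in bin_weights]
    tail = np.asarray(tail, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    if not (len(weights) == tail.size == centers.size):
        raise ValueError("bin_weights, tail and bin_centers must align")
    nb = len(weights)
    tail_count = np.zeros(nb)
    tail_sum = np.zeros(nb)
    tail_sum2 = np.zeros(nb)
    c = s = s2 = 0.0
    for i in range(nb - 1, -1, -1):
        w = weights[i]
        c += w.size
        s += float(w.sum())
        s2 += float((w**2).sum())
        tail_count[i], tail_sum[i], tail_sum2[i] = c, s, s2
    t_min = float(centers[0] - 0.5 * (centers[1] - centers[0])) if nb > 1 else float(centers[0])
    if tail_count.max() < 2:
        logger.warning("fewer than 2 tail weights everywhere; cutoff = t_min")
        return t_min
    cutoff, found = _cutoff_scan(tail_count, tail_sum, tail_sum2, tail, centers,
                                 cv_threshold, t_min, mode, n_total)
    if not found:
        logger.warning("no bin met the CV threshold %.3g; cutoff = t_min", cv_threshold)
    return cutoff


def build_sg_table(config: SGTableConfig) -> SGTable:
    """Monte-Carlo tabulation of the SG_m right tail with importance sampling.

    Per draw: a null sample Y_1..Y_m from ``y_params`` gives (Ybar, sigma_Y);
    one S from ``proposal_params`` is studentized to t = (S - Ybar)/sigma_Y
    and, if t lands in [t_min, t_max), contributes the weight
    f_y(S)/f_proposal(S) to its bin.  G(t) at a bin is the weight mass in
    that bin and above divided by n_draws.  Draws are generated in fixed
    chunks with per-chunk child seeds spawned from ``config.seed``, so the
    result is reproducible and memory stays bounded at any n_draws.
    """
    cfg = config
    if cfg.n_draws < 10**3:
        raise ValueError("n_draws < 1000 would produce a meaningless table")
    nb = cfg.n_bins
    sum_w = np.zeros(nb)
    sum_w2 = np.zeros(nb)
    count = np.zeros(nb, dtype=np.int64)
    n_dropped = 0

    root = np.random.SeedSequence(cfg.seed)
    n_chunks = (cfg.n_draws + _CHUNK - 1) // _CHUNK
    done = 0
    for k in range(n_chunks):
        c = min(_CHUNK, cfg.n_draws - done)
        done += c
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(k,)))
        uy = rng.random((c, cfg.m))
        y = cfg.y_params.mu - np.log(-np.log(uy)) / cfg.y_params.lam
        s = cfg.proposal_params.mu - np.log(-np.log(rng.random(c))) / cfg.proposal_params.lam
        ybar = y.mean(axis=1)
        sy = y.std(axis=1, ddof=1)
        ok = sy > 0
        if not ok.all():
            n_dropped += int((~ok).sum())
            logger.warning("dropped %d replicate(s) with zero sample SD", int((~ok).sum()))
        t = np.full(c, np.nan)
        np.divide(s - ybar, sy, out=t, where=ok)
        inb = ok & (t >= cfg.t_min) & (t < cfg.t_max)
        if inb.any():
            idx = ((t[inb] - cfg.t_min) / cfg.bin_width).astype(np.int64)
            np.clip(idx, 0, nb - 1, out=idx)
            logw = (log_gumbel_density(s[inb], cfg.y_params)
                    - log_gumbel_density(s[inb], cfg.proposal_params))
            w = np.exp(logw)
            sum_w += np.bincount(idx, weights=w, minlength=nb)
            sum_w2 += np.bincount(idx, weights=w * w, minlength=nb)
            count += np.bincount(idx, minlength=nb)
    del root

    tail_sum = np.cumsum(sum_w[::-1])[::-1]
    tail_sum2 = np.cumsum(sum_w2[::-1])[::-1]
    tail_count = np.cumsum(count[::-1])[::-1]
    G = tail_sum / cfg.n_draws
    centers = cfg.bin_centers()
    cutoff, found = _cutoff_scan(tail_count.astype(float), tail_sum, tail_sum2, G,
                                 centers, cfg.cv_threshold, cfg.t_min,
                                 cfg.cv_mode, cfg.n_draws)
    if not found:
        logger.warning("no bin met the CV threshold; precision cutoff set to t_min")
        tail_at_cutoff = float(G[0]) if G[0] > 0 else 1.0
    else:
        idx = int((cutoff - cfg.t_min) / cfg.bin_width)
        idx = min(idx, nb - 1)
        tail_at_cutoff = float(G[idx])
    with np.errstate(divide="ignore"):
        log10_tail = np.log10(G)
    tail_se = np.sqrt(np.maximum(tail_sum2 - tail_sum**2 / cfg.n_draws, 0.0)
                      / max(cfg.n_draws - 1, 1) / cfg.n_draws)
    return SGTable(
        m=cfg.m, t_min=cfg.t_min, bin_width=cfg.bin_width, log10_tail=log10_tail,
        tail_se=tail_se,
        precision_cutoff=cutoff, tail_at_cutoff=tail_at_cutoff,
        n_draws=cfg.n_draws, seed=cfg.seed, y_params=cfg.y_params,
        proposal_params=cfg.proposal_params, cv_threshold=cfg.cv_threshold,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# serialization: plain-text TSV with a commented header


def save_table(table: SGTable, destination) -> None:
    """Write a table as TSV: commented metadata header, then bin_center / log10_tail."""
    own = isinstance(destination, (str, os.PathLike))
    fh = open(destination, "w") if own else destination
    try:
        h = fh.write
        h(f"# sg-table-format: {FORMAT_VERSION}\n")
        h(f"# m: {table.m}\n")
        h(f"# n_draws: {table.n_draws}\n")
        h(f"# seed: {table.seed}\n")
        h(f"# y_mu: {table.y_params.mu!r}\n")
        h(f"# y_lam: {table.y_params.lam!r}\n")
        h(f"# proposal_mu: {table.proposal_params.mu!r}\n")
        h(f"# proposal_lam: {table.proposal_params.lam!r}\n")
        h(f"# t_min: {table.t_min!r}\n")
        h(f"# bin_width: {table.bin_width!r}\n")
        h(f"# n_bins: {table.n_bins}\n")
        h(f"# cv_threshold: {table.cv_threshold!r}\n")
        h(f"# precision_cutoff: {table.precision_cutoff!r}\n")
        h(f"# tail_at_cutoff: {table.tail_at_cutoff!r}\n")
        h(f"# n_dropped: {table.n_dropped}\n")
        h("bin_center\tlog10_tail\ttail_se\n")
        centers = table.bin_centers
        for c, v, se in zip(centers, table.log10_tail, table.tail_se):
            h(f"{float(c)!r}\t{float(v)!r}\t{float(se)!r}\n")
    finally:
        if own:
            fh.close()


class TableFormatError(ValueError):
    """Raised when an SG table file cannot be parsed."""


class TableMismatchError(ValueError):
    """Raised when a loaded table does not match the requested m."""


def load_table(source, *, m: int | None = None) -> SGTable:
    """Read a table written by :func:`save_table`; optionally enforce m."""
    own = isinstance(source, (str, os.PathLike))
    fh = open(source) if own else source
    try:
        meta: dict[str, str] = {}
        lineno = 0
        line = ""
        for line in fh:
            lineno += 1
            if not line.startswith("#"):
                break
            try:
                key, val = line[1:].split(":", 1)
            except ValueError:
                raise TableFormatError(f"malformed header line {lineno}: {line.rstrip()!r}")
            meta[key.strip()] = val.strip()
        if meta.get("sg-table-format") != str(FORMAT_VERSION):
            raise TableFormatError(
                f"unsupported table format version {meta.get('sg-table-format')!r}")
        if line.rstrip("\n").split("\t") != ["bin_center", "log10_tail", "tail_se"]:
            raise TableFormatError(f"expected column header at line {lineno}, got {line!r}")
        required = ["m", "n_draws", "seed", "y_mu", "y_lam", "proposal_mu",
                    "proposal_lam", "t_min", "bin_width", "n_bins",
                    "cv_threshold", "precision_cutoff", "tail_at_cutoff"]
        missing = [k for k in required if k not in meta]
        if missing:
            raise TableFormatError(f"missing header field(s): {', '.join(missing)}")
        n_bins = int(meta["n_bins"])
        log10_tail = np.empty(n_bins)
        tail_se = np.empty(n_bins)
        i = 0
        for lineno, line in enumerate(fh, start=lineno + 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableFormatError(f"malformed data line {lineno}: {line.rstrip()!r}")
            try:
                log10_tail[i] = float(parts[1])
                tail_se[i] = float(parts[2])
            except (ValueError, IndexError):
                raise TableFormatError(f"malformed data line {lineno}: {line.rstrip()!r}")
            i += 1
        if i != n_bins:
            raise TableFormatError(f"expected {n_bins} bins, found {i}")
        table = SGTable(
            m=int(meta["m"]), t_min=float(meta["t_min"]),
            bin_width=float(meta["bin_width"]), log10_tail=log10_tail,
            tail_se=tail_se,
            precision_cutoff=float(meta["precision_cutoff"]),
            tail_at_cutoff=float(meta["tail_at_cutoff"]),
            n_draws=int(meta["n_draws"]), seed=int(meta["seed"]),
            y_params=GumbelParams(float(meta["y_mu"]), float(meta["y_lam"])),
            proposal_params=GumbelParams(float(meta["proposal_mu"]),
                                         float(meta["proposal_lam"])),
            cv_threshold=float(meta["cv_threshold"]),
            n_dropped=int(meta.get("n_dropped", 0)),
        )
        if m is not None and table.m != m:
            raise TableMismatchError(f"table was built for m={table.m}, requested m={m}")
        return table
    finally:
        if own:
            fh.close()
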