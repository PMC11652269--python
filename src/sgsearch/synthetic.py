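"""Synthetic protein sequences, databases, and score-level null simulators.

Everything here is a pure function of (spec, seed): replays are
bit-identical.  The sequence generators emulate the iid null model that
underlies extreme-value alignment statistics — residues drawn
independently from a marginal amino-acid frequency table — which is also
the model under which shuffling a query is an exact null operation.  They
do not emulate compositional bias, low-complexity regions, or domain
structure of real proteins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .engine import SequenceRecord
from .gumbel import GumbelParams, sample_gumbel

__all__ = [
    "FrequencyTable",
    "ROBINSON_ROBINSON",
    "load_frequency_table",
    "save_frequency_table",
    "generate_iid_sequence",
    "generate_database",
    "simulate_score_null",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson & Robinson (1991) marginal amino-acid frequencies, the standard
#: background composition used by protein search tools.  Any 20-entry table
#: can be supplied instead (e.g. frequencies extracted from a tool's source).
ROBINSON_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


@dataclass(frozen=True)
class FrequencyTable:
    """Amino acid -> probability; 20 non-negative entries, renormalized to 1."""

    probs: dict

    def __post_init__(self) -> None:
        probs = dict(self.probs)
        if sorted(probs) != sorted(AMINO_ACIDS):
            raise ValueError("frequency table must cover exactly the 20 amino acids")
        vals = np.array([probs[a] for a in AMINO_ACIDS], dtype=float)
        if np.any(vals < 0):
            raise ValueError("frequencies must be non-negative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("frequencies must not all be zero")
        vals = vals / total  # renormalize; loaders may carry rounding error
        object.__setattr__(self, "probs", {a: float(v) for a, v in zip(AMINO_ACIDS, vals)})

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        return letters, np.array([self.probs[a] for a in AMINO_ACIDS])

    @classmethod
    def uniform(cls) -> "FrequencyTable":
        return cls({a: 0.05 for a in AMINO_ACIDS})

    @classmethod
    def default(cls) -> "FrequencyTable":
        return cls(ROBINSON_ROBINSON)


def load_frequency_table(source) -> FrequencyTable:
    """Read a two-column TSV (residue, probability)."""
    own = isinstance(source, (str, os.PathLike))
    fh = open(source) if own else source
    try:
        probs = {}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            res, val = line.split()
            probs[res.upper()] = float(val)
    finally:
        if own:
            fh.close()
    return FrequencyTable(probs)


def save_frequency_table(table: FrequencyTable, destination) -> None:
    own = isinstance(destination, (str, os.PathLike))
    fh = open(destination, "w") if own else destination
    try:
        for a in AMINO_ACIDS:
            fh.write(f"{a}\t{table.probs[a]!r}\n")
    finally:
        if own:
            fh.close()


def generate_iid_sequence(length: int, freq: FrequencyTable | None = None,
                          seed=None, id: str = "synthetic") -> SequenceRecord:
    """A protein sequence with residues iid from ``freq``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    freq = freq or FrequencyTable.default()
    rng = np.random.default_rng(seed)
    letters, p = freq.as_arrays()
    draws = rng.choice(letters, size=int(length), p=p)
    return SequenceRecord(id=id, residues=draws.tobytes().decode("ascii"))


def _resolve_lengths(n_sequences: int, lengths, rng) -> list[int]:
    if isinstance(lengths, int):
        out = [lengths] * n_sequences
    elif isinstance(lengths, tuple) and len(lengths) == 2:
        lo, hi = lengths
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length range {lengths}")
        out = [int(v) for v in rng.integers(lo, hi + 1, size=n_sequences)]
    else:
        out = [int(v) for v in lengths]
        if len(out) != n_sequences:
            raise ValueError("explicit length list must have n_sequences entries")
    if any(v < 1 for v in out):
        raise ValueError("all lengths must be >= 1")
    return out


def generate_database(n_sequences: int, lengths, freq: FrequencyTable | None = None,
                      seed=None) -> list[SequenceRecord]:
    """Independent iid records named db_0001, db_0002, ...

    ``lengths`` may be a fixed int, an inclusive (low, high) range drawn
    uniformly, or an explicit list of per-sequence lengths.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    freq = freq or FrequencyTable.default()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    lens = _resolve_lengths(n_sequences, lengths, rng)
    records = []
    for i, ln in enumerate(lens):
        child = np.random.SeedSequence(seed, spawn_key=(i + 1,))
        records.append(generate_iid_sequence(ln, freq, seed=child,
                                             id=f"db_{i + 1:04d}"))
    del root
    return records


def simulate_score_null(spec, n: int, seed) -> np.ndarray:
    """iid score draws bypassing the alignment engine.

    ``spec`` is either a :class:`GumbelParams` (or ``("gumbel", mu, lam)``)
    or ``("normal", mu, sigma)``.  The Gumbel path delegates to
    :func:`sgsearch.gumbel.sample_gumbel`, so the draws are bit-identical
    to that generator under a shared seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    if isinstance(spec, GumbelParams):
        return sample_gumbel(n, spec, seed)
    kind = spec[0].lower()
    if kind == "gumbel":
        return sample_gumbel(n, GumbelParams(float(spec[1]), float(spec[2])), seed)
    if kind == "normal":
        rng = np.random.default_rng(seed)
        return rng.normal(float(spec[1]), float(spec[2]), size=n)
    raise ValueError(f"unknown score distribution spec {spec!r}")
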