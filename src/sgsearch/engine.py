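"""Sequence I/O, substitution matrices, and local-alignment score engines.

Two score engines share one interface: a self-contained Smith-Waterman
implementation (affine gaps, score only) and an adapter around an external
``blastp`` executable.  The significance layer only ever needs the best raw
score of a query against each subject and against the whole database, so
neither engine produces tracebacks.

Gap convention: a gap of length k costs ``open + k * extend`` (the NCBI
convention, so penalties (11, 1) match ``blastp -gapopen 11 -gapextend 1``).
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._sw import sw_best_scores

__all__ = [
    "SequenceRecord",
    "ScoringScheme",
    "AlignmentHit",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "load_matrix",
    "smith_waterman",
    "search_database",
    "BuiltinEngine",
    "BlastpEngine",
    "run_blastp",
]

logger = logging.getLogger(__name__)

#: NCBI matrix residue order; the last four symbols are the ambiguity codes.
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CODES = np.full(128, ALPHABET.index("X"), dtype=np.int8)
for _i, _a in enumerate(ALPHABET):
    _CODES[ord(_a)] = _i
    if _a.isalpha():
        _CODES[ord(_a.lower())] = _i


def encode(residues: str) -> np.ndarray:
    """Map a residue string to int8 codes; unknown characters map to X."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODES[np.minimum(raw, 127)]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: an id and uppercase residues (unknowns -> X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        cleaned = "".join(
            c if c in ALPHABET else "X" for c in self.residues.upper()
        )
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (NCBI residue layout) plus affine gap penalties."""

    matrix: np.ndarray  # (24, 24) int32, symmetric
    gap_open: int
    gap_extend: int
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int32)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)}")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_name(cls, name: str = "BLOSUM62", gap_open: int = 11,
                  gap_extend: int = 1) -> "ScoringScheme":
        return cls(load_matrix(name), gap_open, gap_extend, name=name)

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_CODES[ord(a)], _CODES[ord(b)]])


@dataclass
class AlignmentHit:
    """One reported alignment: ids, raw score, and the statistics layered on top."""

    query_id: str
    subject_id: str
    score: float
    evalue: float | None = None
    studentized: float | None = None
    pvalue: float | None = None
    significant: bool | None = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> list[SequenceRecord]:
    """Read protein FASTA; ids are headers up to the first whitespace."""
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError("FASTA parse error: sequence data before any header")
    return [SequenceRecord(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(io.StringIO(text), "fasta")]


def write_fasta(records, destination, width: int = 60) -> None:
    own = isinstance(destination, (str, Path))
    fh = open(destination, "w") if own else destination
    try:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# substitution matrices


def _to_scheme_matrix(arr) -> np.ndarray:
    """Re-index a biopython substitution Array onto the fixed NCBI layout."""
    alpha = "".join(arr.alphabet)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    lookup = {a: i for i, a in enumerate(alpha)}
    x = lookup.get("X")
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            ia = lookup.get(a, x)
            jb = lookup.get(b, x)
            if ia is None or jb is None:
                raise ValueError(f"matrix lacks residues {a!r}/{b!r} and has no X row")
            out[i, j] = int(round(arr[ia, jb]))
    return out


def read_matrix(source) -> np.ndarray:
    """Parse an NCBI-format substitution matrix text file into the 24x24 layout.

    Comment lines start with '#'; the first data row lists the column
    residues, each following row is labelled by its residue.  The parsed
    table must be symmetric.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        arr = substitution_matrices.read(fh)
    except Exception as exc:
        raise ValueError(f"substitution matrix parse error: {exc}") from exc
    finally:
        if own:
            fh.close()
    mat = _to_scheme_matrix(arr)
    if not np.array_equal(mat, mat.T):
        raise ValueError("substitution matrix is not symmetric")
    return mat


def load_matrix(name: str) -> np.ndarray:
    """Load a matrix by standard name (BLOSUM/PAM) or from a file path."""
    path = Path(name)
    if path.exists():
        return read_matrix(path)
    try:
        arr = substitution_matrices.load(name.upper())
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {name!r} and no such file")
    return _to_scheme_matrix(arr)


def packaged_matrix_path(name: str = "BLOSUM62") -> Path:
    """Path of a matrix file shipped with the package (NCBI text format)."""
    return Path(resources.files("sgsearch").joinpath(f"data/{name}.txt"))


# ---------------------------------------------------------------------------
# built-in Smith-Waterman engine


def smith_waterman(query: SequenceRecord | str, subject: SequenceRecord | str,
                   scheme: ScoringScheme) -> int:
    """Best local alignment score under affine gaps (score floor 0)."""
    q = query.residues if isinstance(query, SequenceRecord) else query
    s = subject.residues if isinstance(subject, SequenceRecord) else subject
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    qe = encode(q)
    se = encode(s)
    offs = np.array([0, se.size], dtype=np.int64)
    return int(sw_best_scores(qe, se, offs, scheme.matrix,
                              scheme.gap_open, scheme.gap_extend)[0])


def search_database(query: SequenceRecord, database,
                    scheme: ScoringScheme) -> tuple[list[AlignmentHit], int]:
    """Best score per subject plus the database-wide maximum.

    Ties for the maximum are broken by the first subject in file order.
    """
    engine = BuiltinEngine(database, scheme)
    return engine.search(query)


class BuiltinEngine:
    """Self-contained database search: Smith-Waterman against every subject.

    Encodes the database once; per-query work is a single pass of the
    score-only dynamic program over the concatenated subjects.
    """

    def __init__(self, database, scheme: ScoringScheme):
        self.database = list(database)
        if not self.database:
            raise ValueError("database must be non-empty")
        self.scheme = scheme
        lens = np.array([len(r) for r in self.database], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(lens)])
        self._concat = np.concatenate([encode(r.residues) for r in self.database])
        self.floor_score = 0
        self.reports_evalue = False

    @property
    def engine_id(self) -> str:
        return (f"builtin-sw/{self.scheme.name}"
                f"({self.scheme.gap_open},{self.scheme.gap_extend})")

    def subject_scores(self, residues: str) -> np.ndarray:
        return np.asarray(sw_best_scores(encode(residues), self._concat,
                                         self._offsets, self.scheme.matrix,
                                         self.scheme.gap_open,
                                         self.scheme.gap_extend))

    def best_score(self, residues: str) -> int:
        """Database-wide optimal local alignment score of one query string."""
        return int(self.subject_scores(residues).max())

    def search(self, query: SequenceRecord) -> tuple[list[AlignmentHit], int]:
        scores = self.subject_scores(query.residues)
        hits = [
            AlignmentHit(query_id=query.id, subject_id=rec.id, score=int(sc))
            for rec, sc in zip(self.database, scores)
        ]
        return hits, int(scores.max())


# ---------------------------------------------------------------------------
# blastp adapter

#: The one tabular format this adapter understands.  It is pinned: parsing
#: breaks silently if the column list drifts, so overriding it is refused.
BLASTP_OUTFMT = "6 qseqid sseqid score evalue"


def parse_blast_tabular(text: str, query_id: str | None = None) -> list[AlignmentHit]:
    """Parse ``-outfmt '6 qseqid sseqid score evalue'`` output lines."""
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ValueError(f"unparsable blastp tabular line: {line!r}")
        qid, sid, score_s, evalue_s = parts
        try:
            score = float(score_s)
            evalue = float(evalue_s)
        except ValueError:
            raise ValueError(f"non-numeric field in blastp tabular line: {line!r}")
        hits.append(AlignmentHit(query_id=qid, subject_id=sid,
                                 score=score, evalue=evalue))
    return hits


class BlastpEngine:
    """Adapter around an external ``blastp``; same interface as BuiltinEngine.

    ``db`` must already be formatted with ``makeblastdb``.  Every search —
    the original query and each shuffled one — reuses the identical
    invocation, as the null-sample contract requires.
    """

    def __init__(self, db: str, matrix: str = "BLOSUM62", gap_open: int = 11,
                 gap_extend: int = 1, executable: str = "blastp",
                 extra_args: tuple[str, ...] = ()):
        exe = shutil.which(executable)
        if exe is None:
            raise FileNotFoundError(
                f"blastp executable {executable!r} not found on PATH")
        if any(a.startswith("-outfmt") or a == "-outfmt" for a in extra_args):
            raise ValueError(
                "the output format is pinned to "
                f"{BLASTP_OUTFMT!r} and cannot be overridden")
        self.executable = exe
        self.db = db
        self.matrix = matrix
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.extra_args = tuple(extra_args)
        self.floor_score = 0
        self.reports_evalue = True

    @property
    def engine_id(self) -> str:
        return f"blastp/{self.matrix}({self.gap_open},{self.gap_extend})"

    def _run(self, query: SequenceRecord) -> list[AlignmentHit]:
        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as tmp:
            write_fasta([query], tmp)
            qpath = tmp.name
        cmd = [
            self.executable, "-query", qpath, "-db", self.db,
            "-matrix", self.matrix,
            "-gapopen", str(self.gap_open), "-gapextend", str(self.gap_extend),
            "-outfmt", BLASTP_OUTFMT, *self.extra_args,
        ]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        finally:
            Path(qpath).unlink(missing_ok=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"blastp exited with {proc.returncode}: {proc.stderr.strip()}")
        return parse_blast_tabular(proc.stdout)

    def best_score(self, residues: str) -> float:
        hits = self._run(SequenceRecord(id="query", residues=residues))
        if not hits:
            logger.info("blastp reported no alignments; using floor score 0")
            return float(self.floor_score)
        return max(h.score for h in hits)

    def search(self, query: SequenceRecord) -> tuple[list[AlignmentHit], float]:
        hits = self._run(query)
        best = max((h.score for h in hits), default=float(self.floor_score))
        return hits, best


def run_blastp(query_path: str, db: str, matrix: str = "BLOSUM62",
               gap_open: int = 11, gap_extend: int = 1,
               executable: str = "blastp") -> list[AlignmentHit]:
    """One-shot blastp invocation over a query FASTA file; parsed hits."""
    engine = BlastpEngine(db, matrix=matrix, gap_open=gap_open,
                          gap_extend=gap_extend, executable=executable)
    records = read_fasta(query_path)
    hits: list[AlignmentHit] = []
    for rec in records:
        h, _ = engine.search(rec)
        hits.extend(h)
    return hits
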