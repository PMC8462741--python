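"""Reading and writing single-molecule bisulfite mutation matrices.

A mutation matrix records, for every sequenced molecule, which informative
sites were converted by bisulfite: reference C positions read as T on the
top strand, reference G positions read as A on the bottom strand (bottom
calls are made on top-strand-oriented reads so both strands share one
coordinate system).  All coordinates are 1-based, inclusive, relative to
the amplicon reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")

COORD_HEADER = "# coordinates: 1-based inclusive amplicon positions"


@dataclass
class ReferenceSeq:
    """An amplicon reference; position 1 is the first base."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if len(self.bases) == 0:
            raise ValueError("empty reference sequence")
        bad = set(self.bases) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MutationMatrix:
    """Binary conversion calls (S molecules x N informative sites).

    ``calls[s, t] == 1`` means molecule ``s`` carries the conversion
    (C>T top / G>A bottom) at amplicon position ``positions[t]``.
    ``weights`` are per-sequence duplicate counts (DUPCOUNT), default 1.
    """

    strand: str
    positions: np.ndarray
    calls: np.ndarray
    seq_ids: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        self.positions = np.asarray(self.positions, dtype=int)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape[1] != self.positions.size:
            raise ValueError("calls width does not match number of positions")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be binary")
        if self.weights is None:
            self.weights = np.ones(self.calls.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.calls.shape[0],):
            raise ValueError("weights length does not match number of sequences")
        if np.any(self.weights < 1):
            raise ValueError("weights must be >= 1")
        if len(self.seq_ids) != self.calls.shape[0]:
            raise ValueError("seq_ids length does not match number of sequences")

    @property
    def n_sequences(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size


@dataclass
class SiteCounts:
    """Weighted per-site converted counts x_t with common total n.

    Counts may be real-valued after :func:`barseg.bayes.scale_counts`.
    """

    positions: np.ndarray
    x: np.ndarray
    n: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != self.positions.shape:
            raise ValueError("x and positions must have equal length")
        if np.any(self.x < 0) or np.any(self.x > self.n + 1e-9):
            raise ValueError("counts must satisfy 0 <= x_t <= n")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def freq(self) -> np.ndarray:
        return self.x / self.n


def read_reference(path) -> ReferenceSeq:
    """Read the amplicon reference from the first FASTA record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    rec = records[0]
    return ReferenceSeq(id=rec.id, bases=str(rec.seq))


def informative_sites(ref: ReferenceSeq, strand: str) -> np.ndarray:
    """1-based positions of reference C (top) or G (bottom)."""
    base = {"top": "C", "bottom": "G"}[strand]
    return np.array([i + 1 for i, b in enumerate(ref.bases) if b == base], dtype=int)


def build_mutation_matrix(
    reads_path,
    ref: ReferenceSeq,
    strand: str,
    weights: dict[str, float] | None = None,
    with_report: bool = False,
):
    """Build a strand-specific mutation matrix from pre-aligned reads.

    Reads must be gap-free consensuses of the amplicon length; shorter or
    longer reads are rejected with a warning, reads containing characters
    outside {A,C,G,T,N} are dropped.  An N at an informative site scores 0
    and is tallied in the per-site missingness report.
    """
    if strand not in ("top", "bottom"):
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")
    positions = informative_sites(ref, strand)
    if positions.size == 0:
        raise ValueError(f"reference has zero informative sites on the {strand} strand")
    converted_base = {"top": "T", "bottom": "A"}[strand]
    idx0 = positions - 1

    rows, ids, w = [], [], []
    report = {
        "n_reads": 0,
        "n_kept": 0,
        "n_bad_length": 0,
        "n_bad_chars": 0,
        "missing_by_site": np.zeros(positions.size, dtype=int),
    }
    for rec in SeqIO.parse(str(reads_path), "fasta"):
        report["n_reads"] += 1
        seq = str(rec.seq).upper()
        if len(seq) != len(ref):
            logger.warning(
                "read %s has length %d != reference length %d; rejected",
                rec.id, len(seq), len(ref),
            )
            report["n_bad_length"] += 1
            continue
        if set(seq) - _DNA:
            report["n_bad_chars"] += 1
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")[idx0]
        rows.append((arr == converted_base.encode()).astype(np.uint8))
        report["missing_by_site"] += arr == b"N"
        ids.append(rec.id)
        w.append(1.0 if weights is None else float(weights.get(rec.id, 1.0)))
        report["n_kept"] += 1

    calls = np.vstack(rows) if rows else np.zeros((0, positions.size), dtype=np.uint8)
    matrix = MutationMatrix(
        strand=strand, positions=positions, calls=calls, seq_ids=ids,
        weights=np.asarray(w) if w else None,
    )
    return (matrix, report) if with_report else matrix


def mutation_rate(matrix: MutationMatrix) -> tuple[np.ndarray, float]:
    """Weighted per-site conversion frequencies and the overall frequency."""
    if matrix.n_sequences < 1:
        raise ValueError("no sequences")
    total_w = matrix.weights.sum()
    per_site = matrix.weights @ matrix.calls / total_w
    overall = float((matrix.weights @ matrix.calls).sum() / (total_w * matrix.n_sites))
    return per_site, overall


def to_site_counts(matrix: MutationMatrix) -> SiteCounts:
    """Collapse a matrix to weighted per-site binomial counts."""
    if matrix.n_sequences == 0:
        raise ValueError("no sequences")
    x = matrix.weights @ matrix.calls
    return SiteCounts(positions=matrix.positions, x=x, n=float(matrix.weights.sum()))


def write_matrix(matrix: MutationMatrix, path) -> None:
    """Write the TSV matrix format: seq_id column then one column per position."""
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        fh.write(f"# strand: {matrix.strand}\n")
        fh.write("seq_id\t" + "\t".join(str(p) for p in matrix.positions) + "\n")
        for sid, row in zip(matrix.seq_ids, matrix.calls):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_matrix(path, strand: str | None = None) -> MutationMatrix:
    """Read a TSV mutation matrix written by :func:`write_matrix`.

    ``strand`` overrides the ``# strand:`` comment; defaults to top when
    neither is present.
    """
    file_strand = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# strand:"):
                file_strand = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns.size == 0 or df.columns[0] != "seq_id":
        raise ValueError(f"{path}: missing header (first column must be 'seq_id')")
    seq_ids = df["seq_id"].tolist()
    try:
        positions = np.array([int(c) for c in df.columns[1:]], dtype=int)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric position column in header: {e}") from e
    calls = np.empty((len(seq_ids), positions.size), dtype=np.uint8)
    for j, col in enumerate(df.columns[1:]):
        vals = df[col]
        bad = ~vals.isin(["0", "1"])
        if bad.any():
            r = int(np.argmax(bad.values))
            raise ValueError(
                f"{path}: non-binary cell {vals.iloc[r]!r} at row "
                f"{seq_ids[r]!r}, column {col}"
            )
        calls[:, j] = vals.astype(np.uint8)
    return MutationMatrix(
        strand=strand or file_strand or "top",
        positions=positions, calls=calls, seq_ids=seq_ids,
    )


def read_weights(path) -> dict[str, float]:
    """Read an optional DUPCOUNT table: ``seq_id<TAB>count``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "count"], comment="#")
    return dict(zip(df["seq_id"].astype(str), df["count"].astype(float)))
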