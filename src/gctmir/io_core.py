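"""Readers, writers and validated in-memory containers for the pipeline.

Every downstream stage consumes only the types defined here (expression
matrices, CT tables, sequence records, motif matrices); no stage reads
files directly.  Coordinates are 0-based half-open throughout; strands are
reported as '+'/'-' with positions always on the input (forward) sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "ExpressionMatrix",
    "CtTable",
    "SequenceRecord",
    "MotifMatrix",
    "normalize_sequence",
    "reverse_complement",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "write_gene_list",
    "read_transfac",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A log2-scale feature x sample expression table with group labels.

    ``values`` is a pandas DataFrame (rows = features, columns = samples);
    ``groups`` maps every sample id to its group label.  Two-group
    comparisons require exactly two distinct labels.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if len(idx) == 0:
            raise ValueError("no features")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValueError(f"sample without group label: {missing[0]!r}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)].copy(), dict(self.groups))


@dataclass
class CtTable:
    """Raw qRT-PCR cycle-threshold values (genes x samples).

    Lower CT means more abundant template.  Missing reactions are NaN and
    propagate as missing.  Values outside ``ct_range`` are rejected.
    """

    ct: pd.DataFrame
    ct_range: tuple[float, float] = (0.0, 45.0)

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            dup = self.ct.index[self.ct.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.ct.columns.has_duplicates:
            dup = self.ct.columns[self.ct.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.ct = self.ct.astype(float)
        lo, hi = self.ct_range
        vals = self.ct.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"CT value outside plausible range [{lo}, {hi}]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)


@dataclass
class SequenceRecord:
    """A DNA sequence over {A,C,G,T,N}; masked bases are N."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid character {sorted(bad)[0]!r} "
                "after normalization (expected A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.sequence))


@dataclass
class MotifMatrix:
    """A position-frequency model of a TF binding site.

    ``frequencies`` has shape (length, 4) over columns (A, C, G, T); every
    entry is strictly positive (pseudocount applied at construction) and
    each row sums to 1.  ``max_raw_score`` is the log2-likelihood of the
    consensus word, so normalized word scores (see motif_scan) are <= 0.
    """

    name: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError("frequencies must have shape (length, 4)")
        if np.any(f <= 0):
            raise ValueError("motif frequencies must be strictly positive; apply a pseudocount")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each motif column must sum to 1")
        self.frequencies = f

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.01) -> "MotifMatrix":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("negative count in motif matrix")
        if np.any(c.sum(axis=1) == 0):
            raise ValueError(f"motif {name!r}: count row with all-zero entries")
        c = c + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, weight: float = 99.0,
                       pseudocount: float = 0.01) -> "MotifMatrix":
        """Near-deterministic motif whose consensus is the given word."""
        consensus = consensus.upper()
        counts = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = weight
        return cls.from_counts(name, counts, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return int(self.frequencies.shape[0])

    @property
    def log2_frequencies(self) -> np.ndarray:
        return np.log2(self.frequencies)

    @property
    def max_raw_score(self) -> float:
        return float(np.log2(self.frequencies.max(axis=1)).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.frequencies.argmax(axis=1))

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.name, self.frequencies[::-1, ::-1].copy())


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def normalize_sequence(raw: str, mask_lowercase: bool = False) -> str:
    """Normalize a raw sequence string to the {A,C,G,T,N} alphabet.

    Lowercase letters are uppercased, or mapped to N when
    ``mask_lowercase`` is set (soft-masked RepeatMasker convention);
    anything that is not A/C/G/T afterwards becomes N.
    """
    out = []
    for ch in raw:
        if ch.islower():
            ch = "N" if mask_lowercase else ch.upper()
        if ch not in "ACGT":
            ch = "N"
        out.append(ch)
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# TSV expression / CT tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError("no features")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) sidecar file, with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group file must have two tab-separated columns")
    if list(df.iloc[0]) [:2] == ["sample", "group"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_tsv(path: str | Path, groups: Mapping[str, str] | str | Path) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column = feature ids).

    ``groups`` is either a mapping sample -> group label or the path of a
    two-column sidecar file.
    """
    df = _read_table(path)
    if not isinstance(groups, Mapping):
        groups = read_groups_tsv(groups)
    return ExpressionMatrix(df, dict(groups))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         groups_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.groups[s]}\n")


def read_ct_tsv(path: str | Path, ct_range: tuple[float, float] = (0.0, 45.0)) -> CtTable:
    return CtTable(_read_table(path), ct_range=ct_range)


def write_ct_tsv(table: CtTable, path: str | Path) -> None:
    table.ct.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, mask_lowercase: bool = False) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file, normalizing the alphabet.

    Record order is preserved.  A non-header line appearing before the
    first '>' header is reported with its line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(f"malformed FASTA header at line {lineno}: expected '>'")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq), mask_lowercase)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one identifier per line; blanks skipped."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# TRANSFAC matrices
# ---------------------------------------------------------------------------

def read_transfac(path: str | Path, pseudocount: float = 0.01) -> list[MotifMatrix]:
    """Parse a TRANSFAC-format flat file into frequency matrices.

    Expected per-record structure: ``AC`` and/or ``ID`` lines, a ``P0``
    (or ``PO``) column header, numbered count rows with four numeric
    columns (A C G T), and a ``//`` terminator.  Counts are converted to
    per-column frequencies after adding ``pseudocount`` to every cell, so
    all log-scores downstream are finite.  The motif name is taken from
    the ID line, falling back to AC.
    """
    motifs: list[MotifMatrix] = []
    ac: str | None = None
    ident: str | None = None
    rows: list[list[float]] = []
    in_record = False
    terminated = True

    def flush() -> None:
        nonlocal ac, ident, rows, in_record
        if rows:
            name = ident or ac
            if name is None:
                raise ValueError("TRANSFAC record with counts but no ID/AC line")
            counts = np.array(rows, dtype=float)
            if np.any(counts.sum(axis=1) == 0):
                raise ValueError(f"motif {name!r}: count row with all-zero entries")
            motifs.append(MotifMatrix.from_counts(name, counts, pseudocount=pseudocount))
        ac = ident = None
        rows = []
        in_record = False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "//":
                flush()
                terminated = True
                continue
            terminated = False
            in_record = True
            if tag == "AC":
                ac = line[2:].strip()
            elif tag == "ID":
                ident = line[2:].strip()
            elif tag in ("P0", "PO"):
                continue
            elif tag.strip().isdigit() or (len(tag) == 2 and tag.isdigit()):
                parts = line.split()
                if len(parts) < 5:
                    raise ValueError(f"malformed TRANSFAC count row: {line!r}")
                rows.append([float(x) for x in parts[1:5]])
            # other annotation tags (XX, BF, NA, ...) are ignored
    if in_record and not terminated:
        raise ValueError("TRANSFAC record missing '//' terminator")
    if not motifs:
        raise ValueError("no motif matrices found")
    return motifs


def write_transfac(motifs: Iterable[MotifMatrix], path: str | Path, scale: float = 1000.0) -> None:
    """Write frequency matrices back out as TRANSFAC-style count records."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"ID {m.name}\nP0      A      C      G      T\n")
            for i, row in enumerate(m.frequencies, 1):
                cells = "  ".join(f"{v * scale:8.3f}" for v in row)
                fh.write(f"{i:02d}  {cells}\n")
            fh.write("//\n")
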