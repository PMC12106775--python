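"""Repertoire I/O and the numeric sequence representation.

A repertoire is a list of amino-acid strings (CDR3 loops, decoy proteins, or
model output). Models consume a fixed-length integer encoding: pad = 0 and
the 20 standard residues mapped to 1..20 in alphabetical order, affinely
rescaled to [-1, 1] to match a tanh output head.

Readers accept VDJdb-style TSV exports, FASTA, and plain one-sequence-per-line
text. Rows with characters outside the 20-letter alphabet are dropped and
counted rather than raised, since public exports routinely contain ``*``,
``_`` or ambiguity codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cdr3gen")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_SYMBOL = "-"
DEFAULT_MAX_LEN = 25


class SchemaError(ValueError):
    """A tabular input lacks the expected column."""


class FastaFormatError(ValueError):
    """A FASTA input is structurally malformed."""


class SequenceLengthError(ValueError):
    """A sequence exceeds the fixed model length."""


@dataclass(frozen=True)
class AminoAcidVocabulary:
    """Bijective letter <-> code map: pad = 0, then A..Y alphabetically."""

    alphabet: str = AMINO_ACIDS
    pad_symbol: str = PAD_SYMBOL

    def __post_init__(self):
        assert len(self.alphabet) == 20 and len(set(self.alphabet)) == 20

    @property
    def size(self) -> int:
        return len(self.alphabet) + 1  # 21 codes including pad

    def index_of(self, letter: str) -> int:
        if letter == self.pad_symbol:
            return 0
        return self.alphabet.index(letter) + 1

    def letter_of(self, code: int) -> str:
        if code == 0:
            return self.pad_symbol
        if not 1 <= code <= 20:
            raise ValueError(f"code {code} outside [0, 20]")
        return self.alphabet[code - 1]

    def is_valid(self, sequence: str) -> bool:
        return len(sequence) > 0 and all(c in self.alphabet for c in sequence)


VOCAB = AminoAcidVocabulary()
_CODE_LOOKUP = {c: i + 1 for i, c in enumerate(AMINO_ACIDS)}


@dataclass
class Repertoire:
    """A labeled collection of amino-acid sequences."""

    sequences: list[str]
    label: str = "real_tcr"
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        for s in self.sequences:
            if not VOCAB.is_valid(s):
                raise ValueError(f"invalid sequence {s!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class EncodedBatch:
    """Fixed-length numeric form of a repertoire.

    ``matrix`` holds integer codes right-padded with 0; ``scaled`` is the
    affine image 2*code/20 - 1 in [-1, 1] (pad <-> -1).
    """

    matrix: np.ndarray
    length: int

    @property
    def scaled(self) -> np.ndarray:
        return 2.0 * self.matrix / 20.0 - 1.0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def scaled_to_codes(scaled: np.ndarray) -> np.ndarray:
    """Invert the affine map by nearest-code rounding, clamping to [0, 20].

    Continuous generator outputs land between code centers; rounding is the
    deterministic inverse of the tanh head's scaling.
    """
    codes = np.rint((np.asarray(scaled, dtype=float) + 1.0) * 10.0).astype(int)
    n_clamped = int(np.sum((codes < 0) | (codes > 20)))
    if n_clamped:
        logger.warning("clamped %d out-of-range codes during decoding", n_clamped)
    return np.clip(codes, 0, 20)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vdjdb_table(path: str | Path, column: str = "cdr3", label: str = "real_tcr") -> Repertoire:
    """Read CDR3 strings from a VDJdb-style tab-separated export.

    Sequences are uppercased; rows with characters outside the 20-letter
    alphabet are dropped and counted. Duplicates are retained because
    downstream statistics are frequency-weighted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column not in df.columns:
        raise SchemaError(
            f"column {column!r} not found in {path.name}; available: {list(df.columns)}")
    raw = df[column].dropna().astype(str).str.upper().tolist()
    kept = [s for s in raw if VOCAB.is_valid(s)]
    n_dropped = len(raw) - len(kept)
    if n_dropped:
        logger.info("read_vdjdb_table: dropped %d invalid rows from %s", n_dropped, path.name)
    return Repertoire(kept, label=label, source=str(path), n_dropped=n_dropped)


def read_fasta(path: str | Path, label: str = "non_tcr") -> Repertoire:
    """Read a FASTA file; records with non-standard residues (B, J, O, U, X,
    Z, ...) are dropped with a logged count."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path.name} is empty")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path.name}: sequence data before first '>' header")
    kept, n_dropped = [], 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if VOCAB.is_valid(seq):
            kept.append(seq)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_fasta: dropped %d records with non-standard residues", n_dropped)
    return Repertoire(kept, label=label, source=str(path), n_dropped=n_dropped)


def read_plain(path: str | Path, label: str = "real_tcr") -> Repertoire:
    """Read one sequence per line; blank lines and '#' comments are ignored."""
    path = Path(path)
    kept, n_dropped = [], 0
    for line in path.read_text().splitlines():
        line = line.strip().upper()
        if not line or line.startswith("#"):
            continue
        if VOCAB.is_valid(line):
            kept.append(line)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_plain: dropped %d invalid lines", n_dropped)
    return Repertoire(kept, label=label, source=str(path), n_dropped=n_dropped)


def read_repertoire(path: str | Path, label: str = "real_tcr", column: str = "cdr3") -> Repertoire:
    """Dispatch on file extension: .tsv -> VDJdb table, .fa/.fasta -> FASTA,
    anything else -> plain text."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt.tsv"):
        return read_vdjdb_table(path, column=column, label=label)
    if suffix in (".fa", ".fasta", ".faa"):
        return read_fasta(path, label=label)
    return read_plain(path, label=label)


def write_fasta(rep: Repertoire, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=f"{rep.label}_{i}", description="")
               for i, s in enumerate(rep.sequences)]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(rep: Repertoire, path: str | Path, column: str = "cdr3") -> None:
    pd.DataFrame({column: rep.sequences}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Encoding / decoding
# ---------------------------------------------------------------------------


def encode_sequences(rep: Repertoire, length: int = DEFAULT_MAX_LEN,
                     vocab: AminoAcidVocabulary = VOCAB) -> EncodedBatch:
    """Encode each sequence to a row of integer codes, right-padded to
    ``length`` with the pad code 0."""
    matrix = np.zeros((len(rep), length), dtype=int)
    for i, s in enumerate(rep.sequences):
        if len(s) > length:
            raise SequenceLengthError(
                f"sequence {s!r} (length {len(s)}) exceeds model length {length}")
        matrix[i, : len(s)] = [_CODE_LOOKUP[c] for c in s]
    return EncodedBatch(matrix=matrix, length=length)


def decode_sequences(batch: EncodedBatch | np.ndarray, label: str = "generated",
                     vocab: AminoAcidVocabulary = VOCAB, scaled: bool = False) -> Repertoire:
    """Decode integer codes (or, with ``scaled=True``, continuous values in
    [-1, 1]) back to strings.

    The first pad code terminates a sequence, so a fixed-length head can emit
    variable-length sequences. All-pad rows decode to nothing and are
    excluded with a logged count.
    """
    matrix = batch.matrix if isinstance(batch, EncodedBatch) else np.asarray(batch)
    if scaled or (isinstance(matrix, np.ndarray) and matrix.dtype.kind == "f"):
        matrix = scaled_to_codes(matrix)
    sequences = []
    n_empty = 0
    for row in matrix:
        letters = []
        for code in row:
            if code == 0:
                break
            letters.append(vocab.letter_of(int(code)))
        if letters:
            sequences.append("".join(letters))
        else:
            n_empty += 1
    if n_empty:
        logger.info("decode_sequences: excluded %d all-pad rows", n_empty)
    return Repertoire(sequences, label=label, source="decoded", n_dropped=n_empty)
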