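"""Reading and writing of peptide/target tables, pseudo-sequence tables and FASTA input.

All file formats are plain whitespace-delimited text.  A training file holds
two columns (ligand sequence, numeric target) or three (plus a receptor
name); a pseudo-sequence table maps receptor names to fixed-length aligned
receptor sequences; evaluation proteins arrive as FASTA and are digested
into overlapping peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol set plus the wildcard used for insertions/unknowns.

    The wildcard is *not* a member of the alphabet: it encodes as an
    uninformative vector and is used to pad insertion positions in gapped
    cores and to replace unknown residues in digested proteins.
    """

    symbols: tuple[str, ...]
    wildcard: str

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValidationError("alphabet needs at least 2 symbols")
        if any(len(s) != 1 or s != s.upper() for s in self.symbols):
            raise ValidationError("alphabet symbols must be single upper-case characters")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be unique")
        if self.wildcard in self.symbols:
            raise ValidationError(f"wildcard {self.wildcard!r} must not be an alphabet symbol")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def is_standard_aa(self) -> bool:
        return set(self.symbols) == set(STANDARD_AA)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise ValidationError(f"symbol {symbol!r} not in alphabet") from None

    @classmethod
    def amino_acid(cls) -> "Alphabet":
        return cls(tuple(STANDARD_AA), "X")

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls(tuple("ACGT"), "N")

    @classmethod
    def from_string(cls, symbols: str, wildcard: Optional[str] = None) -> "Alphabet":
        """Build an alphabet from a string such as ``"ACGT"``.

        The wildcard defaults to the conventional ambiguity code: ``X`` for
        the standard amino acids, ``N`` for ``ACGT``, else the first ASCII
        letter not already used as a symbol.
        """
        syms = tuple(symbols.upper())
        if wildcard is None:
            sset = set(syms)
            if sset == set(STANDARD_AA):
                wildcard = "X"
            elif sset == set("ACGT"):
                wildcard = "N"
            else:
                for c in "XNZOUBJ" + "".join(chr(ord("A") + i) for i in range(26)):
                    if c not in sset:
                        wildcard = c
                        break
        return cls(syms, wildcard.upper())


@dataclass
class LigandRecord:
    """One ligand sequence with its (raw or rescaled) numeric target.

    ``source_id``/``start`` are populated for peptides produced by FASTA
    digestion (1-based, inclusive start within the source protein).
    """

    sequence: str
    target: float
    receptor_name: Optional[str] = None
    source_id: Optional[str] = None
    start: Optional[int] = None


@dataclass
class ReceptorTable:
    """Mapping of receptor name to a fixed-length aligned pseudo-sequence."""

    entries: dict[str, str] = field(default_factory=dict)

    @property
    def pseudo_length(self) -> int:
        if not self.entries:
            return 0
        return len(next(iter(self.entries.values())))

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> str:
        if name not in self.entries:
            known = ", ".join(sorted(self.entries))
            raise ValidationError(f"unknown receptor {name!r}; known receptors: {known}")
        return self.entries[name]


def _validate_sequence(seq: str, alphabet: Alphabet, lineno: int, allow_wildcard: bool = False) -> None:
    allowed = set(alphabet.symbols)
    if allow_wildcard:
        allowed.add(alphabet.wildcard)
    for ch in seq:
        if ch not in allowed:
            raise ValidationError(f"line {lineno}: character {ch!r} not in alphabet")


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_training_file(path, alphabet: Alphabet) -> list[LigandRecord]:
    """Read a 2- or 3-column training table into :class:`LigandRecord` objects.

    Column count must be consistent across the file; a third column, when
    present, gives the receptor name of every record.  Sequences are
    upper-cased and validated against ``alphabet``.
    """
    records: list[LigandRecord] = []
    ncols: Optional[int] = None
    for lineno, cols in _data_lines(path):
        if ncols is None:
            ncols = len(cols)
            if ncols not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns, found {ncols}")
        elif len(cols) != ncols:
            raise ParseError(
                f"line {lineno}: inconsistent column count ({len(cols)} vs {ncols} elsewhere)"
            )
        seq = cols[0].upper()
        if not seq:
            raise ParseError(f"line {lineno}: empty sequence")
        try:
            target = float(cols[1])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric target {cols[1]!r}") from None
        _validate_sequence(seq, alphabet, lineno)
        receptor = cols[2] if ncols == 3 else None
        records.append(LigandRecord(sequence=seq, target=target, receptor_name=receptor))
    if not records:
        raise ValidationError(f"{path}: no data lines")
    return records


def write_training_file(records: list[LigandRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cols = [rec.sequence, repr(rec.target)]
            if rec.receptor_name is not None:
                cols.append(rec.receptor_name)
            fh.write("\t".join(cols) + "\n")


def read_peptide_list(path, alphabet: Alphabet) -> list[LigandRecord]:
    """Read an evaluation peptide list (one peptide per line, optional target column)."""
    records = []
    for lineno, cols in _data_lines(path):
        if len(cols) > 3:
            raise ParseError(f"line {lineno}: too many columns ({len(cols)})")
        seq = cols[0].upper()
        _validate_sequence(seq, alphabet, lineno, allow_wildcard=True)
        target = float(cols[1]) if len(cols) >= 2 else 0.0
        records.append(LigandRecord(sequence=seq, target=target))
    if not records:
        raise ValidationError(f"{path}: no peptides found")
    return records


def read_pseudosequences(path) -> ReceptorTable:
    """Read a two-column receptor-name / pseudo-sequence table.

    All pseudo-sequences must share one length (they are assumed aligned,
    e.g. a fixed set of polymorphic contact residues).  Duplicate names with
    identical sequences collapse; conflicting duplicates are an error.
    """
    entries: dict[str, str] = {}
    length: Optional[int] = None
    for lineno, cols in _data_lines(path):
        if len(cols) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, found {len(cols)}")
        name, pseudo = cols[0], cols[1].upper()
        if length is None:
            length = len(pseudo)
        elif len(pseudo) != length:
            raise ValidationError(
                f"line {lineno}: pseudo-sequence length {len(pseudo)} != {length} seen earlier"
            )
        if name in entries and entries[name] != pseudo:
            raise ValidationError(f"line {lineno}: receptor {name!r} listed with conflicting sequences")
        entries[name] = pseudo
    if not entries:
        raise ValidationError(f"{path}: no pseudo-sequences found")
    return ReceptorTable(entries)


def digest_fasta(path, peptide_length: int, alphabet: Alphabet) -> list[LigandRecord]:
    """Digest FASTA proteins into all overlapping peptides of ``peptide_length``.

    Every entry of length N contributes N - peptide_length + 1 windows (step
    1); shorter entries are skipped with a warning.  Characters outside the
    alphabet are replaced by the wildcard (the replacement count is logged).
    Targets are set to 0 as placeholders.
    """
    if peptide_length < 1:
        raise ValidationError("peptide_length must be >= 1")
    records: list[LigandRecord] = []
    n_entries = 0
    n_replaced = 0
    allowed = set(alphabet.symbols) | {alphabet.wildcard}
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ValidationError(f"{path}: not a valid FASTA file: {exc}") from exc
    for entry in entries:
        n_entries += 1
        seq = str(entry.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in allowed:
                cleaned.append(ch)
            else:
                cleaned.append(alphabet.wildcard)
                n_replaced += 1
        seq = "".join(cleaned)
        if len(seq) < peptide_length:
            logger.warning(
                "entry %s (length %d) shorter than peptide length %d: skipped",
                entry.id, len(seq), peptide_length,
            )
            continue
        for i in range(len(seq) - peptide_length + 1):
            records.append(
                LigandRecord(
                    sequence=seq[i : i + peptide_length],
                    target=0.0,
                    source_id=entry.id,
                    start=i + 1,
                )
            )
    if n_entries == 0:
        raise ValidationError(f"{path}: empty FASTA file")
    if n_replaced:
        logger.warning("%d characters outside the alphabet replaced by %r", n_replaced, alphabet.wildcard)
    return records


def write_predictions(rows: list[dict], path) -> None:
    """Write a prediction table as TSV.

    Columns: source_id, start, peptide, prediction, core, core_offset.
    """
    header = ["source_id", "start", "peptide", "prediction", "core", "core_offset"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        str(row.get("source_id") or "-"),
                        str(row.get("start") if row.get("start") is not None else "-"),
                        row["peptide"],
                        f"{row['prediction']:.6f}",
                        row["core"],
                        str(row["core_offset"]),
                    ]
                )
                + "\n"
            )
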