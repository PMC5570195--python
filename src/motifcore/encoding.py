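"""Numeric encoding of binding cores (and receptor pseudo-sequences) for the networks.

Two per-symbol representations are supported:

* ``sparse`` — near-one-hot: 0.9 at the symbol's own slot, 0.05 elsewhere;
  the wildcard encodes as a uniform 0.05 vector.  Works for any alphabet
  and is the only choice for non-amino-acid alphabets.
* ``blosum`` — the symbol's BLOSUM50 row over the 20 standard residues,
  divided by 5; the wildcard encodes as a zero vector.  Restricted to the
  standard amino-acid alphabet, where substitution scores are defined.

An input vector is the concatenation of the L core-position encodings, the
pseudo-sequence position encodings (pan-specific mode) and, optionally, a
single clamped-ramp ligand-length feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .errors import ConfigError, ValidationError
from .sequence_io import STANDARD_AA, Alphabet

SPARSE_HI = 0.9
SPARSE_LO = 0.05
BLOSUM_DIVISOR = 5.0


@lru_cache(maxsize=None)
def _blosum50_rows() -> dict[str, tuple[float, ...]]:
    # BLOSUM50 via biopython, reordered to the canonical 20-letter order.
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM50")
    return {
        a: tuple(float(mat[a][b]) / BLOSUM_DIVISOR for b in STANDARD_AA)
        for a in STANDARD_AA
    }


@dataclass(frozen=True)
class EncodingScheme:
    """Fixed description of how raw sequence is turned into network input.

    ``pseudo_length`` = 0 disables receptor conditioning.  ``len_lo`` /
    ``len_hi`` bound the optional ligand-length ramp; they default to
    L - 2 and L + 6.
    """

    mode: str
    alphabet: Alphabet
    motif_length: int
    pseudo_length: int = 0
    use_length_feature: bool = False
    len_lo: Optional[int] = None
    len_hi: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("blosum", "sparse"):
            raise ConfigError(f"unknown encoding mode {self.mode!r}")
        if self.mode == "blosum" and not self.alphabet.is_standard_aa:
            raise ConfigError(
                "blosum encoding requires the standard 20-letter amino-acid alphabet; "
                "use sparse encoding for custom alphabets"
            )
        if self.motif_length < 2:
            raise ConfigError("motif_length must be >= 2")
        if self.pseudo_length < 0:
            raise ConfigError("pseudo_length must be >= 0")
        if self.use_length_feature:
            lo = self.len_lo if self.len_lo is not None else self.motif_length - 2
            hi = self.len_hi if self.len_hi is not None else self.motif_length + 6
            if hi <= lo:
                raise ConfigError("len_hi must exceed len_lo")
            object.__setattr__(self, "len_lo", lo)
            object.__setattr__(self, "len_hi", hi)

    @property
    def dimension(self) -> int:
        d = (self.motif_length + self.pseudo_length) * self.alphabet.size
        if self.use_length_feature:
            d += 1
        return d


def default_mode(alphabet: Alphabet) -> str:
    """Blosum for standard amino acids, sparse otherwise."""
    return "blosum" if alphabet.is_standard_aa else "sparse"


def symbol_matrix(scheme: EncodingScheme) -> np.ndarray:
    """Per-symbol encoding rows; the extra last row is the wildcard."""
    a = scheme.alphabet
    n = a.size
    if scheme.mode == "sparse":
        m = np.full((n + 1, n), SPARSE_LO)
        np.fill_diagonal(m[:n], SPARSE_HI)
        m[n, :] = SPARSE_LO
    else:
        rows = _blosum50_rows()
        m = np.zeros((n + 1, n))
        for i, sym in enumerate(a.symbols):
            m[i] = rows[sym]
        # wildcard row stays zero
    return m


def encode_symbol(symbol: str, scheme: EncodingScheme) -> np.ndarray:
    """Encode one symbol (or the wildcard) as a length-``|alphabet|`` vector."""
    a = scheme.alphabet
    m = symbol_matrix(scheme)
    if symbol == a.wildcard:
        return m[a.size].copy()
    if symbol not in a.symbols:
        raise ValidationError(f"symbol {symbol!r} neither in alphabet nor the wildcard")
    return m[a.index(symbol)].copy()


def _symbol_indices(s: str, alphabet: Alphabet) -> list[int]:
    wc = alphabet.size
    out = []
    for ch in s:
        if ch == alphabet.wildcard:
            out.append(wc)
        elif ch in alphabet.symbols:
            out.append(alphabet.symbols.index(ch))
        else:
            raise ValidationError(f"symbol {ch!r} neither in alphabet nor the wildcard")
    return out


def length_feature(ligand_length: int, scheme: EncodingScheme) -> float:
    lo, hi = scheme.len_lo, scheme.len_hi
    return min(1.0, max(0.0, (ligand_length - lo) / (hi - lo)))


def encode_example(
    core,
    pseudo: Optional[str],
    ligand_length: int,
    scheme: EncodingScheme,
) -> np.ndarray:
    """Encode one resolved core (a string or an object with ``core_symbols``).

    Returns the fixed-dimension input vector: L position encodings, then
    pseudo-sequence position encodings, then the optional length feature.
    """
    core_symbols = getattr(core, "core_symbols", core)
    return encode_cores(
        [core_symbols], pseudo, ligand_length, scheme
    )[0]


def encode_cores(
    core_strings: list[str],
    pseudo: Optional[str],
    ligand_length: int,
    scheme: EncodingScheme,
) -> np.ndarray:
    """Vectorized encoding of many candidate cores of one ligand.

    All rows share the pseudo-sequence and length-feature blocks; only the
    core block differs.  Returns an (n_cores, D) array.
    """
    a = scheme.alphabet
    L, P = scheme.motif_length, scheme.pseudo_length
    if (pseudo is None) != (P == 0):
        raise ValidationError("pseudo-sequence must be given iff pseudo_length > 0")
    if pseudo is not None and len(pseudo) != P:
        raise ValidationError(f"pseudo-sequence length {len(pseudo)} != configured {P}")
    m = symbol_matrix(scheme)
    n = len(core_strings)
    X = np.empty((n, scheme.dimension))
    for r, core in enumerate(core_strings):
        if len(core) != L:
            raise ValidationError(f"core {core!r} has length {len(core)}, expected {L}")
        idx = _symbol_indices(core, a)
        X[r, : L * a.size] = m[idx].ravel()
    off = L * a.size
    if pseudo is not None:
        pvec = m[_symbol_indices(pseudo, a)].ravel()
        X[:, off : off + P * a.size] = pvec
        off += P * a.size
    if scheme.use_length_feature:
        X[:, off] = length_feature(ligand_length, scheme)
    return X
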