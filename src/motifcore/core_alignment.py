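"""Enumeration and scoring of candidate binding-core placements on a ligand.

The motif window has fixed length L.  A ligand longer than L is handled by
sliding the window and, optionally, by *deletions*: a contiguous internal
block of ligand residues skipped inside the window.  A ligand shorter than
L is handled by *insertions*: a contiguous internal block of wildcard
symbols padded into the core.  Exactly one indel block (or none) is allowed
per placement.  Insertion blocks are strictly internal (wildcards never at
the first or last core position) and a deletion's split point leaves at
least one consumed residue on each side, so the core termini always carry
real ligand residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .encoding import EncodingScheme, encode_cores
from .errors import EmptyCandidateError, ValidationError


@dataclass(frozen=True)
class CoreAlignment:
    """One placement of the L-long motif window on a ligand.

    ``offset`` is the 0-based start of the window in the ligand.
    ``deletion_start`` is the window position where ``deletion_length``
    ligand residues are skipped (-1 when none); ``insertion_start`` is the
    core position where ``insertion_length`` wildcards are padded in
    (-1 when none).  ``core_symbols`` is the resolved L-character core.
    """

    offset: int
    deletion_start: int = -1
    deletion_length: int = 0
    insertion_start: int = -1
    insertion_length: int = 0
    core_symbols: str = ""

    @property
    def consumed(self) -> int:
        """Number of ligand residues covered by this placement."""
        return len(self.core_symbols) - self.insertion_length + self.deletion_length

    def layout(self) -> tuple[int, int, int, int, int]:
        return (
            self.offset,
            self.deletion_start,
            self.deletion_length,
            self.insertion_start,
            self.insertion_length,
        )


@dataclass(frozen=True)
class IndelPolicy:
    """Maximum contiguous deletion / insertion block lengths per core.

    With ``length_adaptive`` (the default) indels serve purely as length
    adaptation when candidate sets are built for training and prediction:
    insertions are offered only for ligands shorter than the motif.
    (Deletions need more residues than the window and are geometrically
    impossible for ligands not longer than the motif.)  Exhaustive
    enumeration via :func:`enumerate_cores` is not affected.
    """

    max_deletions: int = 0
    max_insertions: int = 0
    length_adaptive: bool = True

    def __post_init__(self) -> None:
        if self.max_deletions < 0 or self.max_insertions < 0:
            raise ValidationError("indel bounds must be >= 0")

    def effective(self, ligand_length: int, motif_length: int) -> "IndelPolicy":
        from dataclasses import replace

        if self.length_adaptive and ligand_length >= motif_length and self.max_insertions:
            return replace(self, max_insertions=0)
        return self


def resolve_core(sequence: str, offset: int, deletion_start: int, deletion_length: int,
                 insertion_start: int, insertion_length: int, L: int, wildcard: str) -> str:
    """Build the L-character core string for one placement layout."""
    if deletion_length > 0:
        window = sequence[offset : offset + L + deletion_length]
        return window[:deletion_start] + window[deletion_start + deletion_length :]
    if insertion_length > 0:
        window = sequence[offset : offset + L - insertion_length]
        return window[:insertion_start] + wildcard * insertion_length + window[insertion_start:]
    return sequence[offset : offset + L]


def enumerate_cores(
    sequence: str, L: int, policy: IndelPolicy, wildcard: str = "X"
) -> list[CoreAlignment]:
    """All admissible core placements, in deterministic order.

    Order: ungapped placements by offset; then deletions sorted by
    (offset, start, length); then insertions likewise.  Raises
    :class:`EmptyCandidateError` when the ligand is too short even with the
    maximal insertion.
    """
    if L < 2:
        raise ValidationError("motif length must be >= 2")
    N = len(sequence)
    out: list[CoreAlignment] = []
    for off in range(N - L + 1):
        out.append(CoreAlignment(off, core_symbols=sequence[off : off + L]))
    for dl in range(1, policy.max_deletions + 1):
        for off in range(N - (L + dl) + 1):
            for d in range(1, L):
                core = resolve_core(sequence, off, d, dl, -1, 0, L, wildcard)
                out.append(CoreAlignment(off, d, dl, -1, 0, core))
    for il in range(1, policy.max_insertions + 1):
        if il > L - 2:
            break  # insertion block cannot stay internal
        for off in range(N - (L - il) + 1):
            for i in range(1, L - il):
                core = resolve_core(sequence, off, -1, 0, i, il, L, wildcard)
                out.append(CoreAlignment(off, -1, 0, i, il, core))
    if not out:
        raise EmptyCandidateError(
            f"sequence of length {N} admits no core of length {L} "
            f"under indel policy {policy}"
        )
    return out


def candidate_matrix(
    sequence: str,
    pseudo: Optional[str],
    scheme: EncodingScheme,
    policy: IndelPolicy,
) -> tuple[list[CoreAlignment], np.ndarray]:
    """Enumerate placements and encode them all; returns (alignments, X).

    Applies the policy's length-adaptive restriction, so this is the
    candidate set actually used in training and prediction.
    """
    policy = policy.effective(len(sequence), scheme.motif_length)
    alns = enumerate_cores(sequence, scheme.motif_length, policy, scheme.alphabet.wildcard)
    X = encode_cores([a.core_symbols for a in alns], pseudo, len(sequence), scheme)
    return alns, X


def best_core(
    sequence: str,
    member,
    pseudo: Optional[str],
    scheme: EncodingScheme,
    policy: IndelPolicy,
) -> tuple[CoreAlignment, float]:
    """Highest-scoring placement under one network; ties -> first in order.

    ``member`` is any object with a ``forward_batch(X) -> scores`` method
    (a trained network).  This is the alignment step of the method: the
    placement that the current network scores highest is taken as the
    binding core of the ligand.
    """
    alns, X = candidate_matrix(sequence, pseudo, scheme, policy)
    scores = member.forward_batch(X)
    i = int(np.argmax(scores))
    return alns[i], float(scores[i])
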