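"""Motif summaries of a trained ensemble: PSSMs, log-odds and logo heights.

For single-receptor models the motif is read off the consensus cores of the
top-scoring training records.  Pan-specific models blend many receptor
specificities, so a per-receptor motif is instead derived by scanning a
large set of random background peptides and keeping the top-scoring
fraction for that receptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ann_model import EnsembleModel, predict
from .errors import ValidationError
from .sequence_io import Alphabet, LigandRecord

logger = logging.getLogger(__name__)

# Amino-acid background frequencies (Robinson & Robinson counts, normalized
# at load time); the conventional null model for protein sequence logos.
_AA_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}


def default_background(alphabet: Alphabet) -> np.ndarray:
    """Standard residue frequencies for the 20-letter alphabet, flat otherwise."""
    if alphabet.is_standard_aa:
        v = np.array([_AA_BACKGROUND[s] for s in alphabet.symbols])
        return v / v.sum()
    return np.full(alphabet.size, 1.0 / alphabet.size)


@dataclass
class Pssm:
    """Position-specific scoring matrix over the motif positions.

    ``frequencies`` rows are pseudo-count-smoothed and sum to 1;
    ``log_odds`` is in half-bits: 2 * log2(freq / background).
    """

    frequencies: np.ndarray  # (L, |A|)
    log_odds: np.ndarray  # (L, |A|)
    background: np.ndarray  # (|A|,)
    n_sequences: int
    alphabet: Alphabet

    def to_text(self) -> str:
        header = "pos\t" + "\t".join(self.alphabet.symbols)
        lines = ["# frequencies", header]
        for p in range(self.frequencies.shape[0]):
            lines.append(
                f"{p + 1}\t" + "\t".join(f"{v:.6f}" for v in self.frequencies[p])
            )
        lines += ["# log-odds (half-bits)", header]
        for p in range(self.log_odds.shape[0]):
            lines.append(f"{p + 1}\t" + "\t".join(f"{v:.4f}" for v in self.log_odds[p]))
        return "\n".join(lines) + "\n"


@dataclass
class LogoData:
    """Per-position information content (bits) and per-symbol letter heights."""

    information: np.ndarray  # (L,)
    heights: np.ndarray  # (L, |A|)
    alphabet: Alphabet

    def to_text(self) -> str:
        header = "pos\tinformation\t" + "\t".join(self.alphabet.symbols)
        lines = [header]
        for p in range(len(self.information)):
            lines.append(
                f"{p + 1}\t{self.information[p]:.4f}\t"
                + "\t".join(f"{v:.4f}" for v in self.heights[p])
            )
        return "\n".join(lines) + "\n"


def build_pssm(
    cores: list[str],
    alphabet: Alphabet,
    background: Optional[np.ndarray] = None,
    pseudocount_weight: float = 1.0,
) -> Pssm:
    """Count-based PSSM from aligned L-length cores.

    Wildcard symbols (inserted positions) are uninformative and distribute
    their count uniformly over the alphabet.  Smoothing follows
    f' = (n f + beta g) / (n + beta) with g the background and beta the
    pseudo-count weight, so log-odds are always finite.
    """
    if not cores:
        raise ValidationError("cannot build a PSSM from zero cores")
    L = len(cores[0])
    if any(len(c) != L for c in cores):
        raise ValidationError("all cores must share one length")
    if background is None:
        background = default_background(alphabet)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    counts = np.zeros((L, alphabet.size))
    for core in cores:
        for p, ch in enumerate(core):
            if ch == alphabet.wildcard:
                counts[p] += 1.0 / alphabet.size
            else:
                counts[p, alphabet.index(ch)] += 1.0
    n = len(cores)
    freq = counts / n
    beta = float(pseudocount_weight)
    smoothed = (n * freq + beta * background) / (n + beta)
    with np.errstate(divide="ignore"):  # beta=0 legitimately yields -inf
        log_odds = 2.0 * np.log2(smoothed / background)
    return Pssm(
        frequencies=smoothed,
        log_odds=log_odds,
        background=background,
        n_sequences=n,
        alphabet=alphabet,
    )


def logo_from_pssm(pssm: Pssm) -> LogoData:
    """Information content I_p = log2|A| - H_p; letter height = freq * I_p."""
    f = pssm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.log2(pssm.alphabet.size) - entropy
    info = np.clip(info, 0.0, None)
    return LogoData(information=info, heights=f * info[:, None], alphabet=pssm.alphabet)


def model_motif(
    model: EnsembleModel,
    records: list[LigandRecord],
    top_fraction: float = 0.5,
    background: Optional[np.ndarray] = None,
    pseudocount_weight: float = 1.0,
) -> tuple[Pssm, LogoData]:
    """Motif of a single-receptor model from its top-scoring records' cores.

    Every record is predicted by the full ensemble; the consensus cores of
    the top ``top_fraction`` of records by prediction feed the PSSM.
    """
    if not records:
        raise ValidationError("no records to derive a motif from")
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError("top_fraction must lie in (0, 1]")
    results = [
        predict(model, r.sequence, r.receptor_name if model.is_pan_specific else None)
        for r in records
    ]
    order = np.argsort([-res.prediction for res in results], kind="stable")
    n_keep = max(1, int(round(top_fraction * len(records))))
    cores = [results[i].consensus_core for i in order[:n_keep]]
    if len(cores) < 10:
        logger.warning("motif derived from only %d cores", len(cores))
    pssm = build_pssm(cores, model.alphabet, background, pseudocount_weight)
    return pssm, logo_from_pssm(pssm)


def random_peptides(
    n: int,
    length: int,
    alphabet: Alphabet,
    seed: int,
    background: Optional[np.ndarray] = None,
) -> list[str]:
    """Background-distributed random peptides (the 'natural random' scan set)."""
    if background is None:
        background = default_background(alphabet)
    rng = np.random.default_rng(seed)
    draws = rng.choice(alphabet.size, size=(n, length), p=background / background.sum())
    syms = np.array(list(alphabet.symbols))
    return ["".join(row) for row in syms[draws]]


def receptor_motif(
    model: EnsembleModel,
    receptor_name: str,
    random_set_size: int = 100000,
    top_fraction: float = 0.01,
    peptide_length: Optional[int] = None,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
    pseudocount_weight: float = 1.0,
) -> Pssm:
    """Per-receptor motif of a pan-specific model via a random-peptide scan.

    Predicts ``random_set_size`` background peptides under the given
    receptor and builds a PSSM from the consensus cores of the top
    ``top_fraction`` scorers (default: top 1%).
    """
    if not model.is_pan_specific:
        raise ValidationError("receptor_motif requires a pan-specific model")
    if not (0.0 < top_fraction <= 0.5):
        raise ValidationError("top_fraction must lie in (0, 0.5]")
    n_keep = int(random_set_size * top_fraction)
    if n_keep < 20:
        raise ValidationError(
            f"random_set_size * top_fraction = {n_keep} < 20: too few cores for a motif"
        )
    if peptide_length is None:
        peptide_length = model.motif_length
    peptides = random_peptides(random_set_size, peptide_length, model.alphabet, seed, background)
    predictions, cores_of = _batch_scan(model, peptides, receptor_name)
    order = np.argsort(-predictions, kind="stable")
    cores = [cores_of(i) for i in order[:n_keep]]
    return build_pssm(cores, model.alphabet, background, pseudocount_weight)


def _batch_scan(model: EnsembleModel, peptides: list[str], receptor_name: Optional[str]):
    """Score many same-length peptides; returns (predictions, lazy core lookup).

    When every member shares one encoding scheme and indel policy the
    candidate layout is identical across members, so all peptides are
    encoded once and each member does a single batched forward pass.
    Consensus cores are resolved lazily (only the top scorers need them).
    """
    from .core_alignment import candidate_matrix

    schemes = {(m.scheme, m.policy) for m in model.members}
    pseudo = model.receptor_table[receptor_name] if model.is_pan_specific else None
    if len(schemes) != 1 or len({len(p) for p in peptides}) != 1:
        results = [predict(model, p, receptor_name) for p in peptides]
        preds = np.array([r.prediction for r in results])
        return preds, lambda i: results[i].consensus_core

    scheme, policy = next(iter(schemes))
    encoded = [candidate_matrix(p, pseudo, scheme, policy) for p in peptides]
    n_cand = len(encoded[0][0])
    X = np.vstack([e[1] for e in encoded])
    member_pred = []
    member_choice = []
    for m in model.members:
        out = m.params.forward_batch(X).reshape(len(peptides), n_cand)
        member_pred.append(out.max(axis=1))
        member_choice.append(out.argmax(axis=1))
    preds = np.mean(member_pred, axis=0)

    def core_of(i: int) -> str:
        counts: dict[str, int] = {}
        first: dict[str, int] = {}
        for mi, choice in enumerate(member_choice):
            core = encoded[i][0][choice[i]].core_symbols
            counts[core] = counts.get(core, 0) + 1
            first.setdefault(core, mi)
        return min(counts, key=lambda c: (-counts[c], first[c]))

    return preds, core_of
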