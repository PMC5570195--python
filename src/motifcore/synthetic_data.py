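"""Synthetic ligand datasets with known ground truth.

Every record either carries a motif — a core sampled from a generating PSSM
and implanted at a random offset between background-sampled flanks — or is
pure background with a near-zero target (the 'artificial negative' pattern
used when only positive instances exist).  The quantitative target of a
motif record is the min-max-normalized log-probability of its sampled core
under the generating PSSM, plus clipped Gaussian noise, so the ground truth
is linear in the PSSM and independently checkable.

Ligands shorter than the motif are generated by dropping a contiguous
internal block of the sampled core, which a learner with insertions enabled
can re-expand with wildcards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, ValidationError
from .motif_output import default_background
from .sequence_io import Alphabet, LigandRecord, ReceptorTable


@dataclass
class MotifSpec:
    """A generating PSSM with designated low-entropy anchor columns."""

    name: str
    generating_pssm: np.ndarray  # (L, |A|)
    anchor_positions: tuple[int, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        p = self.generating_pssm
        if p.ndim != 2 or p.shape[1] != self.alphabet.size:
            raise ConfigError("generating_pssm must be L x |alphabet|")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("generating_pssm rows must sum to 1")
        for a in self.anchor_positions:
            col = p[a]
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(col > 0, col * np.log2(col), 0.0)
            if -plogp.sum() >= 1.0:
                raise ConfigError(f"anchor column {a} has entropy >= 1 bit")

    @property
    def length(self) -> int:
        return self.generating_pssm.shape[0]


def make_motif_spec(
    alphabet: Optional[Alphabet] = None,
    length: int = 9,
    anchor_positions: tuple[int, ...] = (0, 4, 8),
    anchor_prob: float = 0.9,
    anchor_symbols: Optional[tuple[str, ...]] = None,
    nonanchor_concentration: float = 50.0,
    seed: int = 0,
    name: str = "motif",
) -> MotifSpec:
    """Build a motif with concentrated anchors and mildly tilted other columns.

    Anchors sit by default at the first, central and last motif position,
    so the information of the motif spans its full length and the motif
    length is identifiable from data.  Each anchor puts ``anchor_prob`` on
    one symbol (chosen from ``seed`` unless given) and spreads the rest
    uniformly.  Non-anchor columns are Dirichlet draws around the uniform
    distribution (total concentration ``nonanchor_concentration``),
    emulating the weak secondary preferences real binding motifs show at
    most positions; they stay high-entropy, far from anchor strength.
    """
    if alphabet is None:
        alphabet = Alphabet.amino_acid()
    if any(a < 0 or a >= length for a in anchor_positions):
        raise ConfigError("anchor positions must lie inside the motif")
    rng = np.random.default_rng(seed)
    if anchor_symbols is None:
        picks = rng.choice(alphabet.size, size=len(anchor_positions), replace=False)
        anchor_symbols = tuple(alphabet.symbols[i] for i in picks)
    if len(anchor_symbols) != len(anchor_positions):
        raise ConfigError("need one anchor symbol per anchor position")
    alpha = np.full(alphabet.size, nonanchor_concentration / alphabet.size)
    pssm = np.empty((length, alphabet.size))
    for pos in range(length):
        pssm[pos] = rng.dirichlet(alpha)
    for pos, sym in zip(anchor_positions, anchor_symbols):
        col = np.full(alphabet.size, (1.0 - anchor_prob) / (alphabet.size - 1))
        col[alphabet.index(sym)] = anchor_prob
        pssm[pos] = col
    return MotifSpec(name=name, generating_pssm=pssm,
                     anchor_positions=tuple(anchor_positions), alphabet=alphabet)


@dataclass
class GroundTruth:
    """Per-record generation record: where the core sits and its clean score."""

    offset: int
    clean_score: float
    is_background: bool
    receptor_name: Optional[str] = None
    implanted_core: str = ""
    #: the L-long core an ideal aligner should recover: wildcards at
    #: truncated positions, bulge residues removed
    aligned_core: str = ""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a single-motif quantitative set: 500 ligands of
    length 10-12 with a 9-long three-anchor motif, Gaussian target noise of
    0.05 and 25% background records.  ``receptor_specs`` switches to
    multi-receptor mode: each record is assigned one (motif, pseudo-
    sequence) pair and scored under its own receptor's PSSM.

    ``elongation`` controls how ligands longer than the motif are built:
    ``flank`` (default) places the contiguous core between background
    flanks, the situation plain window sliding resolves; ``bulge`` inserts
    the extra background residues *inside* the core, the situation core
    deletions resolve.
    """

    n_records: int = 500
    lengths: tuple[int, ...] = (10, 11, 12)
    length_probs: Optional[tuple[float, ...]] = None
    noise_sd: float = 0.05
    fraction_background: float = 0.25
    motif: Optional[MotifSpec] = None
    receptor_specs: Optional[list[tuple[MotifSpec, str]]] = None
    max_core_truncation: int = 1
    elongation: str = "flank"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigError("n_records must be >= 1")
        if not (0.0 <= self.fraction_background <= 1.0):
            raise ConfigError("fraction_background must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.elongation not in ("flank", "bulge"):
            raise ConfigError("elongation must be 'flank' or 'bulge'")
        if self.motif is None and self.receptor_specs is None:
            self.motif = make_motif_spec()
        if self.receptor_specs is not None:
            if self.motif is not None:
                raise ConfigError("give either a single motif or receptor_specs, not both")
            lengths = {len(p) for _, p in self.receptor_specs}
            if len(lengths) != 1:
                raise ConfigError("all receptor pseudo-sequences must share one length")
        L = self._motif_length()
        shortfall = L - min(self.lengths)
        if shortfall > self.max_core_truncation:
            raise ConfigError(
                f"minimum ligand length {min(self.lengths)} is too short for the "
                f"{L}-long motif (max core truncation {self.max_core_truncation})"
            )
        if shortfall > L - 2:
            raise ConfigError("truncation would leave no internal core block")

    def _motif_length(self) -> int:
        if self.motif is not None:
            return self.motif.length
        return self.receptor_specs[0][0].length

    @property
    def alphabet(self) -> Alphabet:
        if self.motif is not None:
            return self.motif.alphabet
        return self.receptor_specs[0][0].alphabet


def receptor_table(config: GeneratorConfig) -> ReceptorTable:
    if config.receptor_specs is None:
        raise ConfigError("not a multi-receptor configuration")
    return ReceptorTable({spec.name: pseudo for spec, pseudo in config.receptor_specs})


def _score_bounds(pssm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column bounds of attainable log-probability (min over sampleable symbols)."""
    with np.errstate(divide="ignore"):
        lp = np.log(pssm)
    col_max = lp.max(axis=1)
    col_min = np.array([lp[p][pssm[p] > 0].min() for p in range(pssm.shape[0])])
    return col_min, col_max


def _sample_core(pssm: np.ndarray, alphabet: Alphabet, rng) -> tuple[str, float]:
    idx = [int(rng.choice(alphabet.size, p=pssm[p])) for p in range(pssm.shape[0])]
    logp = float(sum(np.log(pssm[p, i]) for p, i in enumerate(idx)))
    return "".join(alphabet.symbols[i] for i in idx), logp


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[LigandRecord], list[GroundTruth]]:
    """Generate ligands, targets and the per-record ground truth.

    Fully reproducible from ``config.seed``.  The clean score of a motif
    record is (log P(core) - min) / (max - min) over the attainable range
    of its generating PSSM; a degenerate PSSM (deterministic columns) gives
    clean score 1.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = config.alphabet
    background = default_background(alphabet)
    multi = config.receptor_specs is not None
    specs = config.receptor_specs if multi else [(config.motif, None)]

    n = config.n_records
    n_bg = int(round(config.fraction_background * n))
    bg_idx = set(rng.choice(n, size=n_bg, replace=False).tolist()) if n_bg else set()

    probs = None
    if config.length_probs is not None:
        probs = np.asarray(config.length_probs, dtype=float)
        probs = probs / probs.sum()

    bounds_cols = [_score_bounds(spec.generating_pssm) for spec, _ in specs]

    records: list[LigandRecord] = []
    truth: list[GroundTruth] = []
    for i in range(n):
        r = int(rng.integers(len(specs))) if multi else 0
        spec = specs[r][0]
        receptor = spec.name if multi else None
        length = int(rng.choice(config.lengths, p=probs))
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        if i in bg_idx:
            seq_idx = rng.choice(alphabet.size, size=length, p=background)
            seq = "".join(alphabet.symbols[j] for j in seq_idx)
            target = float(np.clip(noise, 0.0, 1.0))
            records.append(LigandRecord(sequence=seq, target=target, receptor_name=receptor))
            truth.append(GroundTruth(offset=-1, clean_score=0.0, is_background=True,
                                     receptor_name=receptor))
            continue
        # Multi-receptor panels measure the same kind of ligand against every
        # receptor, so the implanted core is drawn from a random receptor's
        # motif but scored against the *assigned* receptor's PSSM.  A core
        # matching the wrong receptor gets a low target, which is exactly the
        # ambiguity that receptor conditioning exists to resolve.
        src = int(rng.integers(len(specs))) if multi else r
        core, _ = _sample_core(specs[src][0].generating_pssm, alphabet, rng)
        L = spec.length
        if length < L:
            # short ligand: an internal block of the motif is unrepresented
            drop = L - length
            start = int(rng.integers(1, L - drop))  # internal block only
            implant = core[:start] + core[start + drop :]
            present = list(range(start)) + list(range(start + drop, L))
            aligned = core[:start] + alphabet.wildcard * drop + core[start + drop :]
            offset = 0
        else:
            implant = core
            present = list(range(L))
            aligned = core
            if config.elongation == "bulge" and length > L:
                # long ligand carries extra residues *inside* the core (a
                # bulge out of the groove), the situation deletions resolve
                extra = length - L
                pos = int(rng.integers(1, L))
                bulge_idx = rng.choice(alphabet.size, size=extra, p=background)
                bulge = "".join(alphabet.symbols[j] for j in bulge_idx)
                implant = core[:pos] + bulge + core[pos:]
                offset = 0
            else:
                offset = int(rng.integers(0, length - L + 1))
        # The target reflects the residues the ligand actually carries: the
        # log-probability (and its attainable bounds) is summed over the
        # represented motif positions only.
        pssm_r = spec.generating_pssm
        with np.errstate(divide="ignore"):
            logp = float(
                sum(np.log(pssm_r[p, alphabet.index(implant[j])])
                    for j, p in enumerate(present))
            )
        lo = sum(bounds_cols[r][0][p] for p in present)
        hi = sum(bounds_cols[r][1][p] for p in present)
        clean = 1.0 if hi == lo else float(np.clip((logp - lo) / (hi - lo), 0.0, 1.0))
        n_flank = length - len(implant)
        flank_idx = rng.choice(alphabet.size, size=n_flank, p=background) if n_flank else []
        flanks = "".join(alphabet.symbols[j] for j in flank_idx)
        seq = flanks[:offset] + implant + flanks[offset:]
        target = float(np.clip(clean + noise, 0.0, 1.0))
        records.append(LigandRecord(sequence=seq, target=target, receptor_name=receptor))
        truth.append(GroundTruth(offset=offset, clean_score=clean, is_background=False,
                                 receptor_name=receptor, implanted_core=implant,
                                 aligned_core=aligned))
    return records, truth


def two_receptor_config(
    seed: int = 0,
    n_records: int = 600,
    noise_sd: float = 0.05,
    fraction_background: float = 0.2,
) -> GeneratorConfig:
    """Two receptors with disjoint anchor preferences and distinct pseudo-sequences.

    The motifs share anchor positions but prefer disjoint residues, so a
    model without receptor conditioning can only learn their blend.
    """
    aa = Alphabet.amino_acid()
    spec_a = make_motif_spec(aa, anchor_symbols=("Y", "L", "K"), seed=seed, name="recA")
    spec_b = make_motif_spec(aa, anchor_symbols=("D", "F", "R"), seed=seed + 1, name="recB")
    return GeneratorConfig(
        n_records=n_records,
        lengths=(9, 10),
        noise_sd=noise_sd,
        fraction_background=fraction_background,
        motif=None,
        receptor_specs=[(spec_a, "ADEKLRSTVY"), (spec_b, "CFGHIMNPQW")],
        seed=seed,
    )


def write_ground_truth(truth: list[GroundTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tclean_score\tis_background\treceptor\timplanted_core\n")
        for gt in truth:
            fh.write(
                f"{gt.offset}\t{gt.clean_score:.6f}\t{int(gt.is_background)}\t"
                f"{gt.receptor_name or '-'}\t{gt.implanted_core or '-'}\n"
            )
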