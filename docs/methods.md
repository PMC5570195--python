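# Methods

## The model

motifcore learns a quantitative sequence motif from pairs (ligand sequence,
target value), where the target can be a rescaled binding affinity, an
array intensity, or a 0/1 label.  The central difficulty is that the part
of the ligand that actually contacts the receptor — the *binding core* of
fixed length L — is not annotated in the input and may sit anywhere in a
variable-length sequence.  The method therefore interleaves alignment and
regression: an ensemble of feed-forward networks maps an encoded candidate
core to a predicted target, and during training each ligand is re-aligned
at every gradient step to the core placement its current network scores
highest.  Alignment quality and regression quality improve together; the
converged alignment *is* the discovered motif.

### Core placements and indels

For a ligand of length N and motif length L, candidate placements are:

* ungapped windows at every offset (N ≥ L);
* *deletions*: a window of L + d residues with a contiguous internal block
  of d skipped (length adaptation for bulged, longer ligands), d bounded by
  the policy's `max_deletions`;
* *insertions*: a window of L − i residues with i wildcard symbols padded
  at an internal core position (for ligands shorter than the motif),
  bounded by `max_insertions`.

One contiguous indel block at most per placement; insertion blocks never
occupy a terminal core position, and a deletion's split point keeps at
least one real residue on each side, so both core termini always carry
ligand residues.  By default the policy is *length-adaptive*: insertion
candidates are offered only to ligands shorter than the motif (deletions
are geometrically impossible for ligands not longer than it), so indels
act purely as length adaptation.  Sequences shorter than L −
`max_insertions` admit no placement; they are excluded from training with
a warning, and in cross-validation they receive the fold's mean training
target as a fallback prediction so that reported performance covers the
whole dataset.

### Encoding

Each core position is encoded either *sparse* (0.9 at the own-symbol slot,
0.05 elsewhere; wildcard = uniform 0.05) or by its *BLOSUM50* row divided
by 5 (wildcard = zero vector).  BLOSUM encoding generalizes across
chemically similar residues and is the default for the standard 20-letter
alphabet; sparse encoding is required for custom alphabets (nucleotides,
reduced alphabets, PTM codes), where substitution scores are undefined.
In pan-specific mode the receptor's fixed-length pseudo-sequence (e.g. the
34 MHC residues in peptide contact) is encoded the same way and
concatenated, so one model serves many receptors and can interpolate to
unseen ones.  An optional scalar ligand-length feature (clamped linear
ramp between L − 2 and L + 6, off by default) lets the network use overall
ligand length.

### Networks and training

Each ensemble member is a one-hidden-layer network with logistic
activations throughout, so outputs live in (0, 1) like the rescaled
targets.  Training is online stochastic gradient descent on squared error:
per epoch the records are reshuffled, each record is re-aligned under the
current weights, and one gradient step is taken on its best core's
encoding.  20% of each member's records are held out; the weight snapshot
with the lowest held-out squared error across epochs is kept.  Defaults:
learning rate 0.05, 300 epochs, uniform [−0.1, 0.1] initialization, one
member per (hidden size × random restart).  All randomness flows from a
master seed through per-member seed sequences, so runs are bit-reproducible
and member order never affects the ensemble mean.

Ensemble prediction is the arithmetic mean of member outputs, each member
using its own best core; the reported core is the plurality choice across
members (ties: lowest member index).

### Targets, cross-validation, reporting

Raw targets are rescaled to [0, 1] by one of: the log-IC50 transform
t' = 1 − log(t)/log(50 000) with clamping to [1, cap] (the standard
affinity rescaling, cap 50 000 nM); min–max; min–max of log targets; or
no transform (targets must already be in [0, 1]).  All transforms are
invertible for reporting in original units.

Cross-validation partitions are either random (shuffle + round robin) or
*clustered*: single-linkage clusters of records sharing an identical
subsequence of ≥ 8 residues (5 for nucleotide data) are assigned whole to
folds by greedy size balancing, so trivially similar sequences never
straddle a train/test boundary.  Performance is computed on the
concatenation of all held-out predictions as RMSE, Pearson (PCC) and
Spearman (SRC) correlation; AUC is added for binary targets.  Degenerate
correlations (constant vector) are reported as 0 with a warning flag.
When a motif-length interval is given, each length is cross-validated and
the length with the highest PCC is suggested (ties: shorter).

### Motif output

The motif is summarized as a PSSM over the consensus cores of the
top-scoring half of the training records (configurable): smoothed
frequencies f' = (n·f + β·g)/(n + β) against the background g (Robinson
amino-acid frequencies for the standard alphabet, flat otherwise; β = 1),
log-odds in half-bits 2·log2(f'/g), and logo heights f'·(log2|A| − H) per
position.  Pan-specific models blend many specificities, so per-receptor
motifs are instead derived by scanning a large set of random
background-distributed peptides under one receptor and building the PSSM
from the top 1% of scorers.

## The synthetic-data generator

The generator is the package's ground-truth instrument.  A `MotifSpec` is
an L × |A| probability matrix with designated anchor columns (default:
positions 1, 5 and 9 of a 9-long motif — first, center, last — so the
motif's information spans its full length and L is identifiable from
data).  Anchors put 0.9 on one residue; the other columns are mild
Dirichlet tilts around uniform (concentration 50), emulating the weak
secondary preferences real motifs show — exactly uniform columns would
make gap placement undecidable in principle.  Each motif record samples a
core from the PSSM and implants it; its clean target is the min–max
normalized log-probability of the sampled core under the PSSM, plus
clipped Gaussian noise.  Background records ("artificial negatives") are
fully background-sampled with targets near 0.

Ligand lengths are drawn from a configurable distribution.  Ligands
longer than the motif either get background flanks (default) or, in
`bulge` mode, carry the extra residues *inside* the core — the bulged-
ligand situation deletions exist to resolve.  Ligands shorter than the
motif lose an internal core block; their targets count only the
represented positions, since a physical 8-mer's affinity cannot depend on
a residue it does not have.  In multi-receptor mode each record is
assigned a receptor and a pseudo-sequence, but its core is sampled from a
*random* receptor's motif and scored under the *assigned* receptor's PSSM
— the cross-receptor ambiguity found in real panels, which sequence alone
cannot resolve and pseudo-sequence conditioning can.

What the generator does not emulate: real affinity-measurement error
structure (censoring, inter-assay batch effects), realistic IEDB length
and allele imbalances, PBM probe-sequence dependence.  Passing studies
show the machinery recovers known structure under controlled conditions;
they do not certify performance levels on any real dataset.

## Evaluation studies and problem sizes

`motifcore.studies` fixes the desk-scale study conditions used by the test
suite and `scripts/acceptance.py`:

* single-motif recovery: n = 500 ligands, lengths 10–12, noise 0.05, 25%
  background, 5-fold random CV;
* motif-length scan: same data, interval 7–11;
* pan-specific contrast: 600 records, two receptors with disjoint anchor
  preferences and distinct pseudo-sequences, sparse encoding (motif
  recovery is judged by frequency-matrix correlation, which BLOSUM's
  similarity smearing would confound), random-peptide scan of 20 000;
* indel contrast: n = 400, lengths 8/9/10/11 with probabilities
  0.2/0.5/0.2/0.1 (9-mer dominated, as in real class-I affinity data),
  bulge elongation, ungapped vs (2 deletions, 1 insertion).

All studies train one 5-unit member per fold for 100 epochs.  Early
stopping selects epochs well under that budget on these data, so results
match larger configurations; the sizes keep a full study in the
seconds-to-minutes range on one CPU.

## Numerical and design notes

* Sparse values 0.9/0.05 rather than 1/0: keeps sigmoid inputs off the
  saturated tails.
* Tie-breaks are deterministic everywhere: first candidate in enumeration
  order for equal core scores, lowest member index for consensus-core
  ties, smaller length for equal PCC in interval scans.
* Gradient correctness is enforced by a finite-difference check in the
  test suite (relative error < 1e-6).
* Model files are versioned JSON with a SHA-256 payload checksum;
  loading verifies both and reproduces predictions bit-identically.
* Duplicate peptides with conflicting targets are kept as separate
  records (the average behaviour then emerges from training); no
  deduplication is attempted.
* Known limitations: a single contiguous indel block per core (no
  affine multi-gap alignment); no peptide-flanking-region features; no
  multi-hidden-layer networks; logo output is numeric (information and
  letter heights), not a rendered graphic.
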