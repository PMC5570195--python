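# motifcore

Quantitative sequence-motif discovery with simultaneous binding-core
alignment, for receptor–ligand systems such as peptide–MHC binding, kinase
and protease substrates, peptide-recognition domains (SH2/SH3/PDZ) and
transcription-factor–DNA interactions.

Given ligand sequences paired with quantitative targets (binding
affinities, array intensities, or 0/1 labels), motifcore trains an
ensemble of single-hidden-layer neural networks that learn, at the same
time, *where* the binding core of length L sits in each variable-length
ligand and *how* the aligned core maps to the target:

* during training every ligand is re-aligned at each gradient step to the
  core placement the current network scores highest — alignment and
  regression converge together;
* cores may include bounded **insertions** (wildcard padding for ligands
  shorter than the motif) and **deletions** (skipped bulge residues for
  longer ligands);
* in **pan-specific** mode each record carries a receptor name, and a
  fixed-length receptor pseudo-sequence (e.g. the 34 MHC residues in
  peptide contact) is encoded next to the core, letting one model learn
  many receptor specificities at once;
* **custom alphabets** (e.g. `ACGT`) are supported via sparse encoding;
  the standard 20-letter amino-acid alphabet defaults to BLOSUM50
  encoding.

The trained model is written to a versioned, checksummed file and can be
re-applied to peptide lists or FASTA proteins (digested into overlapping
windows).  Performance is estimated by cross-validation and reported as
RMSE, Pearson (PCC) and Spearman (SRC) correlation of the concatenated
held-out predictions; the learned motif is emitted as a PSSM (smoothed
frequencies plus log-odds in half-bits) and as sequence-logo heights.
Affinity data in IC50 units are rescaled to [0, 1] with the standard
transform 1 − log(IC50)/log(50 000).

See `docs/methods.md` for the model, its assumptions and the synthetic
data used for validation.

## Worked example

Generate a synthetic dataset with a known implanted motif (9 positions,
anchors at P1/P5/P9), train with 5-fold cross-validation, and inspect the
motif:

```sh
motifcore simulate --n 500 --seed 1 --out demo/data
motifcore train --train demo/data/train.tsv --motif-length 9 \
    --hidden 5 --n-seeds 1 --epochs 100 --seed 1 --out demo/run
```

The train command prints the cross-validated performance:

```
PCC 0.915  SRC 0.798  RMSE 0.142
```

meaning: across all held-out folds, predicted and observed targets
correlate at r = 0.915 (rank correlation 0.798) with a root-mean-squared
error of 0.142 on the unit target scale.  `demo/run/` then contains the
serialized ensemble (`model.json`), per-fold and concatenated metrics
(`cv_report.tsv`, `cv_summary.txt`), target-vs-prediction pairs for a
scatterplot (`scatter.tsv`), the motif matrices (`pssm.txt`, `logo.tsv`)
and a reproducibility manifest.  In `logo.tsv` the three positions with
the highest information content are 1, 5 and 9 — exactly the implanted
anchors.

Scanning proteins with the saved model:

```sh
motifcore predict --model demo/run/model.json \
    --fasta proteins.fasta --pep-length 15 --out predictions.tsv
```

writes one row per overlapping 15-mer with its prediction, best core and
core offset.

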