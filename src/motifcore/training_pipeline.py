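"""Target rescaling, cross-validation partitioning, fold training and reporting.

Cross-validated performance is computed on the concatenated held-out
predictions of all folds and reported as RMSE, Pearson correlation (PCC)
and Spearman rank correlation (SRC); AUC is added when the targets are
binary.  When a motif-length interval is given, every length is evaluated
in cross-validation and the length with the highest PCC is suggested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .ann_model import (
    EnsembleMember,
    EnsembleModel,
    TrainConfig,
    predict,
    train_member,
)
from .core_alignment import IndelPolicy, candidate_matrix
from .encoding import EncodingScheme
from .errors import (
    DegenerateDataError,
    EmptyCandidateError,
    TrainingError,
    ValidationError,
)
from .sequence_io import LigandRecord, ReceptorTable

logger = logging.getLogger(__name__)

IC50_CAP_DEFAULT = 50000.0


@dataclass
class RescalingDescriptor:
    """Invertible transform mapping raw targets into [0, 1].

    kinds:
      * ``none``     — targets must already lie in [0, 1];
      * ``ic50_log`` — t' = 1 - log(t)/log(cap), the standard log-IC50
        transform (cap default 50 000 nM); raw values are clamped to
        [1, cap];
      * ``minmax``   — t' = (t - min)/(max - min);
      * ``log``      — minmax applied to log-transformed (positive) targets.
    """

    kind: str
    cap: float = IC50_CAP_DEFAULT
    minimum: Optional[float] = None
    maximum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "ic50_log", "minmax", "log"):
            raise ValidationError(f"unknown rescaling kind {self.kind!r}")
        if self.kind == "ic50_log" and self.cap <= 1:
            raise ValidationError("ic50_log cap must exceed 1")

    def fit(self, targets: np.ndarray) -> "RescalingDescriptor":
        """Record the data-dependent parameters (min/max) where needed."""
        t = np.asarray(targets, dtype=float)
        if self.kind == "none":
            if np.any(t < 0) or np.any(t > 1):
                raise ValidationError(
                    "rescaling 'none' requires all targets in [0, 1]; "
                    f"found range [{t.min():g}, {t.max():g}]"
                )
            return self
        if self.kind == "ic50_log":
            return self
        if self.kind == "log":
            if np.any(t <= 0):
                raise ValidationError("log rescaling requires strictly positive targets")
            t = np.log(t)
        lo, hi = float(t.min()), float(t.max())
        if hi == lo:
            raise DegenerateDataError("cannot min-max rescale: all targets identical")
        return replace(self, minimum=lo, maximum=hi)

    def apply(self, targets) -> np.ndarray:
        t = np.asarray(targets, dtype=float)
        if self.kind == "none":
            return t.copy()
        if self.kind == "ic50_log":
            t = np.clip(t, 1.0, self.cap)
            return 1.0 - np.log(t) / math.log(self.cap)
        if self.minimum is None or self.maximum is None:
            raise ValidationError("descriptor not fitted: call fit() first")
        if self.kind == "log":
            t = np.log(t)
        return (t - self.minimum) / (self.maximum - self.minimum)

    def invert(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "none":
            return v.copy()
        if self.kind == "ic50_log":
            return np.exp((1.0 - v) * math.log(self.cap))
        raw = v * (self.maximum - self.minimum) + self.minimum
        if self.kind == "log":
            raw = np.exp(raw)
        return raw

    def to_dict(self) -> dict:
        return {"kind": self.kind, "cap": self.cap, "minimum": self.minimum, "maximum": self.maximum}

    @classmethod
    def from_dict(cls, d: dict) -> "RescalingDescriptor":
        return cls(**d)


def rescale_targets(
    records: list[LigandRecord], descriptor: RescalingDescriptor
) -> tuple[list[LigandRecord], RescalingDescriptor]:
    """Fit the descriptor on the records' targets and return rescaled copies."""
    targets = np.array([r.target for r in records], dtype=float)
    fitted = descriptor.fit(targets)
    scaled = fitted.apply(targets)
    out = [replace(r, target=float(t)) for r, t in zip(records, scaled)]
    return out, fitted


# ---------------------------------------------------------------------------
# cross-validation partitioning


@dataclass
class CvPartition:
    fold_of_record: np.ndarray
    method: str
    k: int
    seed: int


def _shared_kmer_clusters(sequences: list[str], k: int) -> list[int]:
    """Single-linkage clusters: two sequences link iff they share a k-mer.

    Sharing an identical subsequence of length >= k is equivalent to sharing
    at least one exact k-mer, so union-find over k-mer occurrence lists gives
    the single-linkage components directly.
    """
    parent = list(range(len(sequences)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    owners: dict[str, int] = {}
    for idx, seq in enumerate(sequences):
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            if kmer in owners:
                union(owners[kmer], idx)
            else:
                owners[kmer] = idx
    return [find(i) for i in range(len(sequences))]


def make_partition(
    records: list[LigandRecord],
    k: int,
    method: str = "random",
    seed: int = 0,
    similarity_threshold: Optional[int] = None,
) -> CvPartition:
    """Assign every record to one of ``k`` folds.

    ``random``: seed-determined shuffle followed by round-robin assignment.
    ``clustered``: records sharing an identical subsequence of length >=
    ``similarity_threshold`` (default 8 for amino-acid-like data, 5 for
    nucleotide data) are single-linkage clustered; clusters are assigned
    whole to folds by greedy size balancing, so similar sequences never
    straddle a fold boundary.
    """
    n = len(records)
    if k < 2:
        raise ValidationError("need at least 2 folds")
    if n < k:
        raise ValidationError(f"cannot split {n} records into {k} folds")
    fold = np.empty(n, dtype=int)
    if method == "random":
        perm = np.random.default_rng(seed).permutation(n)
        for pos, idx in enumerate(perm):
            fold[idx] = pos % k
    elif method == "clustered":
        if similarity_threshold is None:
            chars = set("".join(r.sequence for r in records))
            similarity_threshold = 5 if chars <= set("ACGTUN") else 8
        roots = _shared_kmer_clusters([r.sequence for r in records], similarity_threshold)
        clusters: dict[int, list[int]] = {}
        for idx, root in enumerate(roots):
            clusters.setdefault(root, []).append(idx)
        # greedy balancing: biggest clusters first, into the lightest fold
        order = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))
        sizes = [0] * k
        if order and len(order[0]) > n * (k - 1) / k:
            logger.warning(
                "largest sequence cluster holds %d of %d records: folds will be unbalanced",
                len(order[0]), n,
            )
        for members in order:
            f = int(np.argmin(sizes))
            for idx in members:
                fold[idx] = f
            sizes[f] += len(members)
    else:
        raise ValidationError(f"unknown partition method {method!r}")
    return CvPartition(fold_of_record=fold, method=method, k=k, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def regression_metrics(targets: np.ndarray, predictions: np.ndarray) -> dict:
    """RMSE / PCC / SRC on concatenated pairs; degenerate correlations -> 0.

    A constant vector makes Pearson/Spearman undefined; those are reported
    as 0.0 and flagged so interval scans stay robust.
    """
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    out = {"rmse": float(np.sqrt(np.mean((t - p) ** 2))), "degenerate": False}
    if np.std(t) == 0 or np.std(p) == 0:
        out["pcc"] = 0.0
        out["src"] = 0.0
        out["degenerate"] = True
        logger.warning("constant targets or predictions: correlations reported as 0")
    else:
        out["pcc"] = float(stats.pearsonr(t, p).statistic)
        out["src"] = float(stats.spearmanr(t, p).statistic)
    return out


@dataclass
class CvReport:
    """Cross-validated performance on the concatenated held-out predictions."""

    rmse: float
    pcc: float
    src: float
    auc: Optional[float]
    per_fold: list[dict]
    targets: np.ndarray
    predictions: np.ndarray
    record_indices: np.ndarray
    degenerate: bool = False
    n_unalignable: int = 0
    chosen_length: Optional[int] = None


def _member_seed(master: int, fold: int, arch: int, restart: int) -> int:
    ss = np.random.SeedSequence([master, fold, arch, restart])
    return int(ss.generate_state(1)[0] % 2**31)


def run_cv(
    records: list[LigandRecord],
    scheme: EncodingScheme,
    policy: IndelPolicy,
    config: TrainConfig,
    partition: CvPartition,
    receptor_table: Optional[ReceptorTable] = None,
    rescaling: Optional[RescalingDescriptor] = None,
) -> tuple[CvReport, EnsembleModel]:
    """k-fold cross-validation plus a production ensemble.

    Targets must already be rescaled to [0, 1].  For each fold an ensemble
    (one member per hidden size x random restart) is trained on the other
    folds and predicts the held-out records; metrics are computed on the
    concatenation of all held-out predictions.  The returned production
    model unions the members of every fold.

    Ligands that admit no core placement (too short for the motif even with
    the allowed insertions) cannot be used for training and are dropped from
    it with a warning.  They still belong to the evaluated data: every
    record is predicted exactly once across the held-out folds, so an
    unalignable held-out record receives the fold's mean training target as
    fallback prediction — the model abstains and pays for it in the
    reported performance.  Their count is reported.
    """
    n = len(records)
    if partition.fold_of_record.shape[0] != n:
        raise ValidationError("partition does not match the record list")
    if receptor_table is not None:
        for r in records:
            if r.receptor_name is None:
                raise ValidationError("pan-specific mode: every record needs a receptor name")
            receptor_table[r.receptor_name]  # raises if unknown
        pseudo_of = lambda r: receptor_table[r.receptor_name]  # noqa: E731
        if scheme.pseudo_length != receptor_table.pseudo_length:
            raise ValidationError(
                f"scheme.pseudo_length {scheme.pseudo_length} != table length "
                f"{receptor_table.pseudo_length}"
            )
    else:
        pseudo_of = lambda r: None  # noqa: E731

    # pre-encode every record's candidate set once; detect unalignable ligands
    cache: list[Optional[np.ndarray]] = []
    for r in records:
        try:
            cache.append(candidate_matrix(r.sequence, pseudo_of(r), scheme, policy)[1])
        except EmptyCandidateError:
            cache.append(None)
    alignable = np.array([c is not None for c in cache])
    n_unalignable = int((~alignable).sum())
    if n_unalignable:
        logger.warning(
            "%d of %d ligands admit no core placement at L=%d and are dropped",
            n_unalignable, n, scheme.motif_length,
        )

    all_members: list[EnsembleMember] = []
    pred_of = np.full(n, np.nan)
    per_fold: list[dict] = []
    for f in range(partition.k):
        train_idx = [i for i in range(n) if partition.fold_of_record[i] != f and alignable[i]]
        test_idx = [i for i in range(n) if partition.fold_of_record[i] == f and alignable[i]]
        test_idx_fallback = [
            i for i in range(n) if partition.fold_of_record[i] == f and not alignable[i]
        ]
        if len(train_idx) < 2:
            raise TrainingError(f"fold {f}: fewer than 2 training records")
        train_records = [records[i] for i in train_idx]
        train_cache = [cache[i] for i in train_idx]
        fold_members: list[EnsembleMember] = []
        for ai, h in enumerate(config.hidden_sizes):
            for si in range(config.n_seeds):
                params = train_member(
                    train_records, scheme, policy, config,
                    member_seed=_member_seed(config.seed, f, ai, si),
                    hidden_size=h,
                    candidate_cache=train_cache,
                )
                fold_members.append(EnsembleMember(params, scheme, policy))
        logger.info("fold %d/%d trained (%d members)", f + 1, partition.k, len(fold_members))
        for i in test_idx:
            outs = [m.params.forward_batch(cache[i]) for m in fold_members]
            pred_of[i] = float(np.mean([np.max(o) for o in outs]))
        fold_mean = float(np.mean([records[i].target for i in train_idx]))
        for i in test_idx_fallback:
            pred_of[i] = fold_mean
        eval_idx = test_idx + test_idx_fallback
        fold_t = np.array([records[i].target for i in eval_idx])
        if len(eval_idx) >= 2:
            per_fold.append({"fold": f, "n": len(eval_idx),
                             **regression_metrics(fold_t, pred_of[eval_idx])})
        all_members.extend(fold_members)

    idx = np.arange(n)
    t = np.array([r.target for r in records])
    p = pred_of
    m = regression_metrics(t, p)
    auc = None
    if set(np.unique(t)) <= {0.0, 1.0} and len(np.unique(t)) == 2:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(t.astype(int), p))
    report = CvReport(
        rmse=m["rmse"], pcc=m["pcc"], src=m["src"], auc=auc,
        per_fold=per_fold, targets=t, predictions=p, record_indices=idx,
        degenerate=m["degenerate"], n_unalignable=n_unalignable,
    )
    model = EnsembleModel(
        members=all_members,
        motif_length=scheme.motif_length,
        alphabet=scheme.alphabet,
        receptor_table=receptor_table,
        rescaling=rescaling.to_dict() if rescaling is not None else None,
        cv_structure={"k": partition.k, "method": partition.method, "seed": partition.seed},
    )
    return report, model


def scan_motif_lengths(
    records: list[LigandRecord],
    length_range: tuple[int, int],
    scheme: EncodingScheme,
    policy: IndelPolicy,
    config: TrainConfig,
    partition: CvPartition,
    receptor_table: Optional[ReceptorTable] = None,
    rescaling: Optional[RescalingDescriptor] = None,
) -> tuple[dict[int, CvReport], int, EnsembleModel]:
    """Cross-validate every motif length in the interval; suggest the best.

    The suggested length maximizes cross-validated PCC; ties favour the
    smaller length.  Returns (per-length reports, suggested length, the
    production model trained at the suggested length).
    """
    lo, hi = length_range
    if lo > hi:
        raise ValidationError(f"invalid motif-length interval {lo}..{hi}")
    if lo < 2:
        raise ValidationError("motif lengths must be >= 2")
    reports: dict[int, CvReport] = {}
    models: dict[int, EnsembleModel] = {}
    for L in range(lo, hi + 1):
        s = replace(scheme, motif_length=L, len_lo=None, len_hi=None)
        reports[L], models[L] = run_cv(
            records, s, policy, config, partition, receptor_table, rescaling
        )
        reports[L].chosen_length = L
        logger.info("motif length %d: PCC=%.3f RMSE=%.3f", L, reports[L].pcc, reports[L].rmse)
    suggested = min(reports, key=lambda L: (-reports[L].pcc, L))
    return reports, suggested, models[suggested]
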