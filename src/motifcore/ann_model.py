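"""Single-hidden-layer sigmoid networks: training with interleaved core
alignment, ensembling, and model (de)serialization.

The defining mechanism of the method lives in :func:`train_member`: at every
stochastic-gradient step the binding core of the current ligand is
re-selected as the placement the *current* network scores highest, so the
alignment and the regression weights are learned simultaneously.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core_alignment import CoreAlignment, IndelPolicy, candidate_matrix, best_core
from .encoding import EncodingScheme
from .errors import (
    IntegrityError,
    ModelFormatError,
    TrainingError,
    ValidationError,
)
from .sequence_io import Alphabet, LigandRecord, ReceptorTable

MODEL_FORMAT_VERSION = 1


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class NetworkParams:
    """Weights of one feed-forward network: input -> hidden -> scalar output.

    Both layers use the logistic activation, so the output lies in (0, 1)
    and matches targets rescaled to [0, 1].
    """

    W1: np.ndarray  # (hidden, D)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    hidden_size: int
    init_seed: int

    def forward(self, x: np.ndarray) -> float:
        return float(self.forward_batch(x[None, :])[0])

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.W1.shape[1]:
            raise TrainingError(
                f"input dimension {X.shape[1]} != network dimension {self.W1.shape[1]}"
            )
        H = _sigmoid(X @ self.W1.T + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2,
            self.hidden_size, self.init_seed,
        )


def init_network(dim: int, hidden_size: int, seed: int) -> NetworkParams:
    """Uniform [-0.1, 0.1] initialization from the member's own RNG stream."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        W1=rng.uniform(-0.1, 0.1, size=(hidden_size, dim)),
        b1=rng.uniform(-0.1, 0.1, size=hidden_size),
        W2=rng.uniform(-0.1, 0.1, size=hidden_size),
        b2=float(rng.uniform(-0.1, 0.1)),
        hidden_size=hidden_size,
        init_seed=seed,
    )


def forward(params: NetworkParams, x: np.ndarray) -> float:
    """o = sigma(W2 . sigma(W1 x + b1) + b2)."""
    return params.forward(np.asarray(x, dtype=float))


def gradients(params: NetworkParams, x: np.ndarray, t: float) -> dict[str, np.ndarray]:
    """Analytic gradients of the squared error (t - o)^2 w.r.t. all weights."""
    z1 = params.W1 @ x + params.b1
    h = _sigmoid(z1)
    o = _sigmoid(float(params.W2 @ h + params.b2))
    d2 = 2.0 * (o - t) * o * (1.0 - o)
    d1 = d2 * params.W2 * h * (1.0 - h)
    return {
        "W1": np.outer(d1, x),
        "b1": d1,
        "W2": d2 * h,
        "b2": np.array(d2),
    }


@dataclass
class TrainConfig:
    """Hyper-parameters for ensemble training.

    The ensemble contains one member per (architecture, random restart)
    pair.  ``early_stop_fraction`` of each member's training records is
    held out to pick the best epoch snapshot.
    """

    hidden_sizes: tuple[int, ...] = (15,)
    n_seeds: int = 2
    learning_rate: float = 0.05
    epochs: int = 300
    early_stop_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValidationError("hidden_sizes must be positive")
        if self.n_seeds < 1 or self.learning_rate < 0 or self.epochs < 1:
            raise ValidationError("n_seeds and epochs must be positive, learning_rate >= 0")
        if not (0.0 <= self.early_stop_fraction < 0.5):
            raise ValidationError("early_stop_fraction must lie in [0, 0.5)")


def train_member(
    records: list[LigandRecord],
    scheme: EncodingScheme,
    policy: IndelPolicy,
    config: TrainConfig,
    member_seed: int,
    hidden_size: Optional[int] = None,
    pseudo_of: Optional[Callable[[LigandRecord], Optional[str]]] = None,
    candidate_cache: Optional[list[np.ndarray]] = None,
) -> NetworkParams:
    """Train one ensemble member by online backpropagation.

    Per epoch, records are visited in a freshly shuffled order; for each
    record the best core under the *current* weights is selected and one
    gradient step on the squared error of that core's encoding is applied.
    After every epoch the summed squared error on the member's held-out
    early-stop split is computed (cores re-selected); the snapshot with the
    lowest held-out error is returned.

    Targets must already be rescaled to [0, 1].  ``candidate_cache`` may
    hold precomputed candidate encoding matrices (one per record) to avoid
    re-encoding across members.
    """
    n = len(records)
    if n < 2:
        raise TrainingError("need at least 2 records to train")
    if hidden_size is None:
        hidden_size = config.hidden_sizes[0]
    if pseudo_of is None:
        pseudo_of = lambda r: None  # noqa: E731

    if candidate_cache is None:
        candidate_cache = [
            candidate_matrix(r.sequence, pseudo_of(r), scheme, policy)[1] for r in records
        ]
    targets = np.array([r.target for r in records], dtype=float)

    rng = np.random.default_rng(member_seed)
    params = init_network(scheme.dimension, hidden_size, int(rng.integers(2**31)))

    n_val = int(round(config.early_stop_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise TrainingError("early-stop split left no training records")
    monitor_idx = val_idx if n_val > 0 else train_idx

    lr = config.learning_rate
    W1, b1, W2 = params.W1, params.b1, params.W2

    def held_out_sse() -> float:
        sse = 0.0
        for i in monitor_idx:
            out = params.forward_batch(candidate_cache[i])
            sse += (targets[i] - float(np.max(out))) ** 2
        return sse

    best_sse = np.inf
    best_snapshot = params.copy()
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        for i in order:
            X = candidate_cache[i]
            Hm = _sigmoid(X @ W1.T + b1)
            out = _sigmoid(Hm @ W2 + params.b2)
            j = int(np.argmax(out))
            x, h, o, t = X[j], Hm[j], out[j], targets[i]
            d2 = 2.0 * (o - t) * o * (1.0 - o)
            d1 = d2 * W2 * h * (1.0 - h)
            W2 -= lr * d2 * h
            params.b2 -= lr * d2
            W1 -= lr * np.outer(d1, x)
            b1 -= lr * d1
        if not (np.isfinite(W1).all() and np.isfinite(W2).all()):
            raise TrainingError(
                f"non-finite weights after epoch {_epoch} (member seed {member_seed})"
            )
        sse = held_out_sse()
        if sse < best_sse:
            best_sse = sse
            best_snapshot = params.copy()
    return best_snapshot


@dataclass
class EnsembleMember:
    params: NetworkParams
    scheme: EncodingScheme
    policy: IndelPolicy


@dataclass
class PredictionResult:
    prediction: float
    consensus_core: str
    consensus_alignment: CoreAlignment
    member_predictions: list[float]
    member_alignments: list[CoreAlignment]


@dataclass
class EnsembleModel:
    """A trained network ensemble plus everything needed to predict from raw sequences."""

    members: list[EnsembleMember]
    motif_length: int
    alphabet: Alphabet
    receptor_table: Optional[ReceptorTable] = None
    rescaling: Optional[dict] = None
    cv_structure: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("ensemble must contain at least one member")
        for m in self.members:
            if m.scheme.motif_length != self.motif_length:
                raise ValidationError("all members must share the motif length")

    @property
    def is_pan_specific(self) -> bool:
        return self.receptor_table is not None


def predict(
    model: EnsembleModel, sequence: str, receptor_name: Optional[str] = None
) -> PredictionResult:
    """Ensemble prediction: mean of member outputs, each on its own best core.

    The consensus core is the core string chosen by a plurality of members;
    ties go to the core of the lowest-index member among the tied.
    """
    sequence = sequence.upper()
    if model.is_pan_specific:
        if receptor_name is None:
            raise ValidationError("this model is pan-specific: a receptor name is required")
        pseudo = model.receptor_table[receptor_name]
    else:
        if receptor_name is not None:
            raise ValidationError("model has no receptor table: receptor names are not supported")
        pseudo = None

    preds: list[float] = []
    alns: list[CoreAlignment] = []
    for m in model.members:
        aln, score = best_core(sequence, m.params, pseudo, m.scheme, m.policy)
        preds.append(score)
        alns.append(aln)

    counts: dict[str, int] = {}
    first_member: dict[str, int] = {}
    for i, aln in enumerate(alns):
        core = aln.core_symbols
        counts[core] = counts.get(core, 0) + 1
        first_member.setdefault(core, i)
    consensus = min(counts, key=lambda c: (-counts[c], first_member[c]))
    return PredictionResult(
        prediction=float(np.mean(preds)),
        consensus_core=consensus,
        consensus_alignment=alns[first_member[consensus]],
        member_predictions=preds,
        member_alignments=alns,
    )


# ---------------------------------------------------------------------------
# serialization


def _scheme_to_dict(s: EncodingScheme) -> dict:
    return {
        "mode": s.mode,
        "motif_length": s.motif_length,
        "pseudo_length": s.pseudo_length,
        "use_length_feature": s.use_length_feature,
        "len_lo": s.len_lo,
        "len_hi": s.len_hi,
    }


def _scheme_from_dict(d: dict, alphabet: Alphabet) -> EncodingScheme:
    return EncodingScheme(alphabet=alphabet, **d)


def _model_payload(model: EnsembleModel) -> dict:
    return {
        "alphabet": {"symbols": "".join(model.alphabet.symbols), "wildcard": model.alphabet.wildcard},
        "motif_length": model.motif_length,
        "rescaling": model.rescaling,
        "cv_structure": model.cv_structure,
        "receptor_table": dict(model.receptor_table.entries) if model.receptor_table else None,
        "members": [
            {
                "scheme": _scheme_to_dict(m.scheme),
                "policy": {
                    "max_deletions": m.policy.max_deletions,
                    "max_insertions": m.policy.max_insertions,
                    "length_adaptive": m.policy.length_adaptive,
                },
                "hidden_size": m.params.hidden_size,
                "init_seed": m.params.init_seed,
                "W1": m.params.W1.tolist(),
                "b1": m.params.b1.tolist(),
                "W2": m.params.W2.tolist(),
                "b2": m.params.b2,
            }
            for m in model.members
        ],
    }


def _payload_digest(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def save_model(model: EnsembleModel, path) -> None:
    """Serialize the ensemble to a versioned, checksummed JSON file."""
    payload = _model_payload(model)
    doc = {
        "format": "motifcore-model",
        "format_version": MODEL_FORMAT_VERSION,
        "checksum": _payload_digest(payload),
        "payload": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> EnsembleModel:
    """Load a model file; verifies format version and payload checksum."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"model file {path} is truncated or not valid JSON: {exc}") from exc
    if doc.get("format") != "motifcore-model":
        raise ModelFormatError(f"{path} is not a model file")
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {doc.get('format_version')} is not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    payload = doc["payload"]
    if _payload_digest(payload) != doc.get("checksum"):
        raise IntegrityError(f"model file {path} failed its checksum")

    alphabet = Alphabet(tuple(payload["alphabet"]["symbols"]), payload["alphabet"]["wildcard"])
    members = []
    for md in payload["members"]:
        scheme = _scheme_from_dict(md["scheme"], alphabet)
        policy = IndelPolicy(**md["policy"])
        params = NetworkParams(
            W1=np.array(md["W1"], dtype=float),
            b1=np.array(md["b1"], dtype=float),
            W2=np.array(md["W2"], dtype=float),
            b2=float(md["b2"]),
            hidden_size=md["hidden_size"],
            init_seed=md["init_seed"],
        )
        members.append(EnsembleMember(params, scheme, policy))
    table = ReceptorTable(payload["receptor_table"]) if payload["receptor_table"] else None
    return EnsembleModel(
        members=members,
        motif_length=payload["motif_length"],
        alphabet=alphabet,
        receptor_table=table,
        rescaling=payload["rescaling"],
        cv_structure=payload["cv_structure"],
    )
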