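"""Per-V-gene humanness classifiers and the kappa/lambda chain-type classifier.

Random-forest binary classifiers over one-hot encoded IMGT-numbered sequences,
with Youden's-J threshold calibration, rank-statistic ROC/AUC, MCC, and
impurity-based feature importances mapped back to (position, residue) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .ab_sequence import (
    ALPHABET,
    Chain,
    ImgtPosition,
    NumberedSequence,
    default_universe,
    encode,
    is_framework,
)

__all__ = [
    "HumannessModel",
    "ChainTypeModel",
    "SplitDataset",
    "ScoreReport",
    "ThresholdMetrics",
    "FeatureImportance",
    "split_dataset",
    "train_model",
    "calibrate_threshold",
    "youden_threshold",
    "mcc_threshold",
    "auc_score",
    "roc_auc",
    "classify_sequence",
    "classify_pair",
    "train_chain_type_model",
    "classify_chain_type",
    "feature_importance",
]

_N_STATES = len(ALPHABET)


def _encode_matrix(seqs: Sequence[NumberedSequence], universe: Sequence[ImgtPosition]) -> np.ndarray:
    return np.stack([encode(s, universe) for s in seqs]) if seqs else np.empty((0, len(universe) * _N_STATES))


@dataclass
class HumannessModel:
    """Trained binary humanness classifier for one chain / V gene.

    The score of a sequence is the forest's mean per-tree positive-class
    probability, in [0,1]. ``threshold`` is None until calibrated.
    """

    chain: Chain
    v_gene: str
    forest: RandomForestClassifier
    n_estimators: int
    universe: list[ImgtPosition]
    threshold: Optional[float] = None
    metadata: dict = field(default_factory=dict)
    # per-feature (position, residue) frequencies in the training corpus
    positive_feature_freq: Optional[np.ndarray] = None
    negative_feature_freq: Optional[np.ndarray] = None

    def _check_chain(self, seq: NumberedSequence) -> None:
        if seq.chain != self.chain:
            raise ValueError(
                f"chain mismatch: model is {self.chain.value}, sequence {seq.id!r} is {seq.chain.value}"
            )

    def score(self, seq: NumberedSequence) -> float:
        self._check_chain(seq)
        return float(self.score_vectors(encode(seq, self.universe)[None, :])[0])

    def score_many(self, seqs: Sequence[NumberedSequence]) -> np.ndarray:
        for s in seqs:
            self._check_chain(s)
        if not seqs:
            return np.empty(0)
        return self.score_vectors(_encode_matrix(seqs, self.universe))

    def score_vectors(self, X: np.ndarray) -> np.ndarray:
        proba = self.forest.predict_proba(X)
        pos_col = int(np.where(self.forest.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def is_human(self, seq: NumberedSequence) -> bool:
        if self.threshold is None:
            raise ValueError("model threshold not calibrated")
        return self.score(seq) > self.threshold


class ChainTypeModel(HumannessModel):
    """Kappa-vs-lambda classifier over light chains (kappa = positive class)."""

    def _check_chain(self, seq: NumberedSequence) -> None:
        if not seq.chain.is_light:
            raise ValueError(f"chain-type model accepts light chains only, got {seq.chain.value}")


@dataclass
class SplitDataset:
    train: list[NumberedSequence]
    validation: list[NumberedSequence]
    test: list[NumberedSequence]
    train_labels: np.ndarray
    validation_labels: np.ndarray
    test_labels: np.ndarray


@dataclass
class ThresholdMetrics:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    mcc: float
    auc: Optional[float] = None
    mcc_optimal_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        expected = self.sensitivity + self.specificity - 1.0
        if abs(self.youden_j - expected) > 1e-12:
            raise ValueError("YJS identity violated")


@dataclass
class ScoreReport:
    sequence_id: str
    chain: Chain
    scores: dict[tuple[str, str], float]  # (chain value, v_gene) -> score
    thresholds: dict[tuple[str, str], float]
    best_model: tuple[str, str]
    is_human: bool


@dataclass
class FeatureImportance:
    position: ImgtPosition
    residue: str
    importance: float
    frequency_positive: float
    frequency_negative: float

    @property
    def in_framework(self) -> bool:
        return is_framework(self.position)


# --------------------------------------------------------------------------
# Dataset splitting
# --------------------------------------------------------------------------

def split_dataset(
    seqs: Sequence[NumberedSequence],
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitDataset:
    """Stratified train/validation/test split, reproducible under ``seed``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(seqs):
        raise ValueError("labels length must match sequences")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one record per class")
    rng = np.random.default_rng(seed)
    fr = np.asarray(fractions, dtype=float)
    n_total = len(labels)
    # global split sizes by largest remainder, ties toward earlier splits
    targets = np.floor(fr * n_total).astype(int)
    order = np.argsort(-(fr * n_total - targets), kind="stable")
    for k in order[: n_total - targets.sum()]:
        targets[k] += 1
    classes = np.unique(labels)
    # per-class floor shares first, then hand leftovers to the split with the
    # largest remaining global deficit so targets are met exactly
    base = {cls: np.floor(fr * np.sum(labels == cls)).astype(int) for cls in classes}
    alloc = np.sum(list(base.values()), axis=0)
    counts = {cls: b.copy() for cls, b in base.items()}
    for cls in classes:
        for _ in range(int(np.sum(labels == cls) - base[cls].sum())):
            k = int(np.argmax(targets - alloc))
            counts[cls][k] += 1
            alloc[k] += 1
    parts: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train, n_val, _ = counts[cls]
        parts["train"].extend(idx[:n_train])
        parts["validation"].extend(idx[n_train : n_train + n_val])
        parts["test"].extend(idx[n_train + n_val :])
    out = {}
    for name, idxs in parts.items():
        idxs = sorted(idxs)
        out[name] = [seqs[i] for i in idxs]
        out[name + "_labels"] = labels[idxs]
    return SplitDataset(
        train=out["train"],
        validation=out["validation"],
        test=out["test"],
        train_labels=out["train_labels"],
        validation_labels=out["validation_labels"],
        test_labels=out["test_labels"],
    )


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _feature_frequencies(X: np.ndarray) -> np.ndarray:
    return X.mean(axis=0) if len(X) else np.zeros(X.shape[1])


def _train_forest(
    positives: Sequence[NumberedSequence],
    negatives: Sequence[NumberedSequence],
    n_estimators: int,
    seed: int,
    universe: Optional[Sequence[ImgtPosition]],
    model_cls,
    chain: Chain,
    v_gene: str,
) -> HumannessModel:
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    if universe is None:
        universe = default_universe(list(positives) + list(negatives))
    universe = list(universe)
    Xp = _encode_matrix(positives, universe)
    Xn = _encode_matrix(negatives, universe)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xn), dtype=int)])
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return model_cls(
        chain=chain,
        v_gene=v_gene,
        forest=forest,
        n_estimators=n_estimators,
        universe=universe,
        metadata={
            "n_positive": len(positives),
            "n_negative": len(negatives),
            "seed": seed,
        },
        positive_feature_freq=_feature_frequencies(Xp),
        negative_feature_freq=_feature_frequencies(Xn),
    )


def train_model(
    positives: Sequence[NumberedSequence],
    negatives: Sequence[NumberedSequence],
    n_estimators: int = 200,
    seed: int = 0,
    universe: Optional[Sequence[ImgtPosition]] = None,
) -> HumannessModel:
    """Train a humanness classifier: one V gene's human sequences vs all
    non-human sequences of the same chain."""
    chains = {s.chain for s in list(positives) + list(negatives)}
    if len(chains) != 1:
        raise ValueError(f"all training sequences must share a chain, got {sorted(c.value for c in chains)}")
    chain = chains.pop()
    v_genes = {s.v_gene for s in positives if s.v_gene}
    v_gene = v_genes.pop() if len(v_genes) == 1 else "mixed"
    return _train_forest(positives, negatives, n_estimators, seed, universe, HumannessModel, chain, v_gene)


def train_chain_type_model(
    kappa_seqs: Sequence[NumberedSequence],
    lambda_seqs: Sequence[NumberedSequence],
    n_estimators: int = 200,
    seed: int = 0,
    universe: Optional[Sequence[ImgtPosition]] = None,
) -> ChainTypeModel:
    """Kappa-vs-lambda light-chain classifier (kappa is the positive class)."""
    for s in list(kappa_seqs) + list(lambda_seqs):
        if not s.chain.is_light:
            raise ValueError(f"chain-type training requires light chains, got {s.chain.value} ({s.id!r})")
    if any(s.chain != Chain.KAPPA for s in kappa_seqs) or any(s.chain != Chain.LAMBDA for s in lambda_seqs):
        raise ValueError("kappa_seqs must be kappa and lambda_seqs must be lambda")
    model = _train_forest(
        kappa_seqs, lambda_seqs, n_estimators, seed, universe, ChainTypeModel, Chain.KAPPA, "chain_type"
    )
    model.threshold = 0.5
    return model


def classify_chain_type(model: ChainTypeModel, seq: NumberedSequence) -> Chain:
    if not seq.chain.is_light:
        raise ValueError(f"chain-type classification applies to light chains only, got {seq.chain.value}")
    return Chain.KAPPA if model.score(seq) > model.threshold else Chain.LAMBDA


# --------------------------------------------------------------------------
# Threshold calibration and ROC/AUC
# --------------------------------------------------------------------------

def _candidate_cutpoints(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus sentinels 0 and 1."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def _confusion_at(scores: np.ndarray, labels: np.ndarray, tau: float) -> tuple[int, int, int, int]:
    pred = scores > tau  # strict: score == tau classifies negative
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp, fp, tn, fn


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, ThresholdMetrics]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints of adjacent distinct scores plus 0 and 1; ties
    are broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold calibration requires both classes")
    best_tau, best_j, best = None, -np.inf, None
    for tau in _candidate_cutpoints(scores):
        tp, fp, tn, fn = _confusion_at(scores, labels, tau)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-15:  # strict improvement: ties keep the smaller tau
            best_tau, best_j = float(tau), j
            best = (sens, spec, _mcc(tp, fp, tn, fn))
    sens, spec, mcc = best
    metrics = ThresholdMetrics(
        threshold=best_tau, sensitivity=sens, specificity=spec, youden_j=best_j, mcc=mcc
    )
    return best_tau, metrics


def mcc_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximizing the Matthews correlation coefficient."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold calibration requires both classes")
    best_tau, best_m = None, -np.inf
    for tau in _candidate_cutpoints(scores):
        m = _mcc(*_confusion_at(scores, labels, tau))
        if m > best_m + 1e-15:
            best_tau, best_m = float(tau), m
    return best_tau


def calibrate_threshold(
    model: HumannessModel,
    validation: Sequence[NumberedSequence],
    labels: Sequence[int],
) -> ThresholdMetrics:
    """Set the model's classification threshold from a validation set."""
    scores = model.score_many(validation)
    tau, metrics = youden_threshold(scores, labels)
    metrics.auc = auc_score(scores, labels)
    metrics.mcc_optimal_threshold = mcc_threshold(scores, labels)
    model.threshold = tau
    model.metadata["calibration"] = {
        "n_validation": len(validation),
        "youden_j": metrics.youden_j,
        "mcc_optimal_threshold": metrics.mcc_optimal_threshold,
    }
    return metrics


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the rank statistic: P(random positive outscores a random
    negative), ties counting one half."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(model: HumannessModel, test: Sequence[NumberedSequence], labels: Sequence[int]) -> float:
    return auc_score(model.score_many(test), labels)


# --------------------------------------------------------------------------
# Classification rules
# --------------------------------------------------------------------------

def classify_sequence(models: Sequence[HumannessModel], seq: NumberedSequence) -> ScoreReport:
    """Score against every model of the sequence's chain; human iff any score
    strictly exceeds its model's threshold."""
    if not models:
        raise ValueError("at least one model required")
    for m in models:
        if m.chain != seq.chain:
            raise ValueError(
                f"chain mismatch: model {m.v_gene} is {m.chain.value}, sequence is {seq.chain.value}"
            )
        if m.threshold is None:
            raise ValueError(f"model {m.v_gene} has no calibrated threshold")
    scores = {(m.chain.value, m.v_gene): m.score(seq) for m in models}
    thresholds = {(m.chain.value, m.v_gene): m.threshold for m in models}
    best = max(scores, key=lambda k: (scores[k], k))
    human = any(scores[k] > thresholds[k] for k in scores)
    return ScoreReport(
        sequence_id=seq.id,
        chain=seq.chain,
        scores=scores,
        thresholds=thresholds,
        best_model=best,
        is_human=human,
    )


def classify_pair(vh_report: ScoreReport, vl_report: ScoreReport) -> bool:
    """A VH+VL pair is human iff both chains are individually human."""
    if (vh_report.chain == Chain.HEAVY) == (vl_report.chain == Chain.HEAVY):
        raise ValueError("classify_pair requires one heavy and one light report")
    return vh_report.is_human and vl_report.is_human


# --------------------------------------------------------------------------
# Feature importances
# --------------------------------------------------------------------------

def feature_importance(model: HumannessModel, top_k: int = 10) -> list[FeatureImportance]:
    """Top-k impurity importances mapped back to (position, residue), with the
    feature's frequency in the positive and negative training corpora."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    imp = model.forest.feature_importances_
    order = np.argsort(imp)[::-1][:top_k]
    out = []
    for i in order:
        pos = model.universe[i // _N_STATES]
        residue = ALPHABET[i % _N_STATES]
        out.append(
            FeatureImportance(
                position=pos,
                residue=residue,
                importance=float(imp[i]),
                frequency_positive=float(model.positive_feature_freq[i]),
                frequency_negative=float(model.negative_feature_freq[i]),
            )
        )
    return out
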