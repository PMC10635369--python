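"""Per-sequence metric battery and cross-validation orchestration.

Metrics are reported per protein sequence and averaged unweighted across
sequences: trapezoidal AUC-ROC, average precision (the recall-increment
weighted mean of precision, degenerating to precision x recall for a binary
predictor), and precision/recall among the top L, L/2, L/5 and L/10 scored
pairs, where L is the total concatenated TM-helix length of the sequence.

Cross-validation splits BY SEQUENCE: all candidate pairs of a protein stay on
one side of every fold, which also prevents window-overlap leakage between
train and test pairs of the same chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from helixcontact.contact_map import ResiduePair
from helixcontact.features import FeatureMatrix, fit_scaler
from helixcontact.model import ModelConfig, TrainedModel, predict_scores, train

logger = logging.getLogger(__name__)

__all__ = [
    "TOPK_FRACTIONS",
    "UndefinedMetricError",
    "SequenceData",
    "SequenceMetrics",
    "MetricsReport",
    "roc_auc",
    "average_precision",
    "binary_annotation_ap",
    "topk_precision_recall",
    "feature_stats",
    "concat_features",
    "score_sequences",
    "annotation_baseline_report",
    "cross_validate",
    "compare_sources",
]

TOPK_FRACTIONS = {"L": 1.0, "L/2": 0.5, "L/5": 0.2, "L/10": 0.1}


class UndefinedMetricError(ValueError):
    """The metric is undefined for this label/score configuration."""


@dataclass
class SequenceData:
    """One protein's feature matrix with aligned labels.

    ``features`` is the raw (unscaled) matrix; ``labels`` always come from the
    experimental structure.  ``baseline_labels`` are the binary contact
    annotations implied by the predicted structure's own coordinates, used for
    the annotation baseline.  ``L`` is the concatenated TM-helix length.
    """

    sequence_id: str
    features: FeatureMatrix
    labels: np.ndarray
    L: int
    baseline_labels: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.features),):
            raise ValueError("labels must align with feature rows")
        if self.baseline_labels is not None:
            self.baseline_labels = np.asarray(self.baseline_labels, dtype=int)
            if self.baseline_labels.shape != self.labels.shape:
                raise ValueError("baseline labels must align with labels")


@dataclass
class SequenceMetrics:
    sequence_id: str
    ap: float
    auc: float
    topk: dict[str, tuple[float, float]]
    n_pairs: int
    n_contacts: int
    L: int


@dataclass
class MetricsReport:
    per_sequence: list[SequenceMetrics]
    mean_ap: float
    mean_auc: float
    std_ap: float = 0.0
    std_auc: float = 0.0
    n_excluded: int = 0
    feature_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def ap_by_sequence(self) -> dict[str, float]:
        return {m.sequence_id: m.ap for m in self.per_sequence}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.per_sequence:
            row = {
                "sequence_id": m.sequence_id,
                "ap": m.ap,
                "auc": m.auc,
                "n_pairs": m.n_pairs,
                "n_contacts": m.n_contacts,
                "L": m.L,
            }
            for label, (p, r) in m.topk.items():
                row[f"precision@{label}"] = p
                row[f"recall@{label}"] = r
            rows.append(row)
        return pd.DataFrame(rows)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC-ROC; ties get the standard half credit."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with a single label class")
    return float(roc_auc_score(labels, scores))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Recall-increment weighted mean of precision over score thresholds.

    A score vector taking only the values {0, 1} is a binary annotation: it
    has a single meaningful threshold (score 0 means "not predicted" at any
    threshold), so AP degenerates to precision x recall rather than gaining
    the trivial predict-everything point.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise UndefinedMetricError("AP undefined without positive labels")
    unique = set(np.unique(scores))
    if unique == {0.0, 1.0}:
        return binary_annotation_ap((scores == 1.0).astype(int), labels)
    return float(average_precision_score(labels, scores))


def binary_annotation_ap(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """AP of a binary predictor: precision x recall (single-threshold case)."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    n_pred = pred_labels.sum()
    n_true = true_labels.sum()
    if n_pred == 0:
        raise UndefinedMetricError("no predicted positives: precision undefined")
    if n_true == 0:
        raise UndefinedMetricError("no true positives: recall undefined")
    tp = int(((pred_labels == 1) & (true_labels == 1)).sum())
    return (tp / n_pred) * (tp / n_true)


def topk_precision_recall(
    scores: np.ndarray,
    labels: np.ndarray,
    L: int,
    fractions: dict[str, float] = TOPK_FRACTIONS,
    pairs: list[ResiduePair] | None = None,
) -> dict[str, tuple[float, float]]:
    """Precision/recall among the top floor(L * fraction) scored pairs.

    Ties at the cut are broken by (i, j) lexicographic order when ``pairs``
    is given, else by position, so the ranking is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if L < 1:
        raise ValueError("L must be >= 1")
    if pairs is not None:
        keys = [(-s, p.i, p.j) for s, p in zip(scores, pairs)]
    else:
        keys = [(-s, idx) for idx, s in enumerate(scores)]
    order = sorted(range(len(scores)), key=lambda t: keys[t])
    sorted_labels = labels[np.array(order)] if len(order) else labels
    total_pos = int(labels.sum())
    out = {}
    for name, frac in fractions.items():
        k = max(1, int(L * frac))
        if k > len(scores):
            logger.warning("top-%s: k=%d exceeds %d pairs; clamping", name, k, len(scores))
            k = len(scores)
        tp = int(sorted_labels[:k].sum())
        precision = tp / k
        recall = tp / total_pos if total_pos else float("nan")
        out[name] = (precision, recall)
    return out


def feature_stats(m: FeatureMatrix) -> tuple[float, float]:
    """Grand mean and grand standard deviation over every matrix entry.

    (The paper's tables label the second number 'variance' but define it as a
    standard deviation; the SD is what is computed here.)
    """
    if len(m) == 0:
        raise ValueError("feature stats undefined for an empty matrix")
    return float(m.vectors.mean()), float(m.vectors.std())


def _sequence_metrics(
    seq: SequenceData, scores: np.ndarray
) -> SequenceMetrics | None:
    """None when the sequence has no positive labels (excluded from means)."""
    n_contacts = int(seq.labels.sum())
    if n_contacts == 0 or n_contacts == len(seq.labels):
        return None
    return SequenceMetrics(
        sequence_id=seq.sequence_id,
        ap=average_precision(scores, seq.labels),
        auc=roc_auc(scores, seq.labels),
        topk=topk_precision_recall(
            scores, seq.labels, seq.L, pairs=seq.features.pair_index
        ),
        n_pairs=len(seq.labels),
        n_contacts=n_contacts,
        L=seq.L,
    )


def _report_from_metrics(
    metrics: list[SequenceMetrics], n_excluded: int
) -> MetricsReport:
    if not metrics:
        raise UndefinedMetricError("no sequence yielded defined metrics")
    return MetricsReport(
        per_sequence=metrics,
        mean_ap=float(np.mean([m.ap for m in metrics])),
        mean_auc=float(np.mean([m.auc for m in metrics])),
        n_excluded=n_excluded,
    )


def score_sequences(
    model: TrainedModel, dataset: list[SequenceData]
) -> MetricsReport:
    """Apply a trained model to each sequence and summarize."""
    metrics, excluded = [], 0
    for seq in dataset:
        scores = predict_scores(model, seq.features)
        m = _sequence_metrics(seq, scores)
        if m is None:
            excluded += 1
            logger.info("sequence %s excluded (degenerate labels)", seq.sequence_id)
            continue
        metrics.append(m)
    return _report_from_metrics(metrics, excluded)


def annotation_baseline_report(dataset: list[SequenceData]) -> MetricsReport:
    """Score each sequence by the predicted structure's own binary contacts.

    AP is precision x recall (the single-threshold degenerate case); AUC uses
    the binary labels as scores with tie handling.
    """
    metrics, excluded = [], 0
    for seq in dataset:
        if seq.baseline_labels is None:
            raise ValueError(f"sequence {seq.sequence_id} has no baseline labels")
        n_contacts = int(seq.labels.sum())
        if n_contacts == 0 or n_contacts == len(seq.labels) or seq.baseline_labels.sum() == 0:
            excluded += 1
            logger.info("sequence %s excluded from baseline", seq.sequence_id)
            continue
        scores = seq.baseline_labels.astype(float)
        metrics.append(
            SequenceMetrics(
                sequence_id=seq.sequence_id,
                ap=binary_annotation_ap(seq.baseline_labels, seq.labels),
                auc=roc_auc(scores, seq.labels),
                topk=topk_precision_recall(
                    scores, seq.labels, seq.L, pairs=seq.features.pair_index
                ),
                n_pairs=len(seq.labels),
                n_contacts=n_contacts,
                L=seq.L,
            )
        )
    return _report_from_metrics(metrics, excluded)


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    return FeatureMatrix(
        kind=parts[0].kind,
        vectors=np.vstack([p.vectors for p in parts]),
        pair_index=[pr for p in parts for pr in p.pair_index],
        sequence_ids=[s for p in parts for s in p.sequence_ids],
    )


def cross_validate(
    dataset: list[SequenceData],
    config: ModelConfig,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    test_dataset: list[SequenceData] | None = None,
) -> MetricsReport:
    """k-fold cross-validation with sequence-level splits, repeated.

    ``test_dataset``, when given, must parallel ``dataset`` (same sequence
    ids, same kept pairs) and supplies the feature matrices scored on the
    held-out side — e.g. features from predicted structures while training on
    experimental ones.  Labels always come from ``dataset``.

    Reported mean/std are across repeat-level means; per-sequence entries are
    averaged over repeats.
    """
    if len(dataset) < k:
        raise ValueError(f"need at least k={k} sequences, got {len(dataset)}")
    if test_dataset is not None:
        if [s.sequence_id for s in test_dataset] != [s.sequence_id for s in dataset]:
            raise ValueError("test_dataset must parallel dataset sequence ids")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    repeat_ap, repeat_auc = [], []
    per_seq_aps: dict[str, list[float]] = {}
    per_seq_last: dict[str, SequenceMetrics] = {}
    excluded = 0

    for rep in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        held_out_seen: set[str] = set()
        rep_metrics: list[SequenceMetrics] = []
        for fold in folds:
            test_idx = set(int(t) for t in fold)
            train_parts = [dataset[t] for t in range(n) if t not in test_idx]
            train_features = concat_features([s.features for s in train_parts])
            train_labels = np.concatenate([s.labels for s in train_parts])
            # leakage guard: no held-out sequence contributes training pairs
            train_ids = {s.sequence_id for s in train_parts}
            fold_ids = {dataset[t].sequence_id for t in test_idx}
            assert not (train_ids & fold_ids), "sequence leaked across the fold split"
            held_out_seen |= fold_ids

            fold_config = ModelConfig(**{**config.__dict__, "seed": config.seed + 1000 * rep})
            scaler = fit_scaler(train_features)
            model = train(train_features, train_labels, fold_config, scaler=scaler)
            for t in sorted(test_idx):
                seq = dataset[t]
                source = test_dataset[t] if test_dataset is not None else seq
                scores = predict_scores(model, source.features)
                m = _sequence_metrics(seq, scores)
                if m is None:
                    excluded += 1
                    continue
                rep_metrics.append(m)
                per_seq_aps.setdefault(seq.sequence_id, []).append(m.ap)
                per_seq_last[seq.sequence_id] = m
        assert held_out_seen == {s.sequence_id for s in dataset}
        if rep_metrics:
            repeat_ap.append(float(np.mean([m.ap for m in rep_metrics])))
            repeat_auc.append(float(np.mean([m.auc for m in rep_metrics])))

    if not repeat_ap:
        raise UndefinedMetricError("no defined metrics in any repeat")
    per_sequence = []
    for sid, m in per_seq_last.items():
        avg = SequenceMetrics(
            sequence_id=sid,
            ap=float(np.mean(per_seq_aps[sid])),
            auc=m.auc,
            topk=m.topk,
            n_pairs=m.n_pairs,
            n_contacts=m.n_contacts,
            L=m.L,
        )
        per_sequence.append(avg)
    return MetricsReport(
        per_sequence=per_sequence,
        mean_ap=float(np.mean(repeat_ap)),
        mean_auc=float(np.mean(repeat_auc)),
        std_ap=float(np.std(repeat_ap)),
        std_auc=float(np.std(repeat_auc)),
        n_excluded=excluded,
    )


def compare_sources(
    report_pred: MetricsReport,
    baseline_pred_annotations: MetricsReport,
) -> pd.DataFrame:
    """Per-sequence AP delta of the classifier on predicted-structure features
    over the predicted structure's own binary contact annotations."""
    pred = report_pred.ap_by_sequence()
    base = baseline_pred_annotations.ap_by_sequence()
    common = sorted(set(pred) & set(base))
    if not common:
        raise ValueError("no common sequence ids between reports")
    rows = [
        {
            "sequence_id": sid,
            "classifier_ap": pred[sid],
            "baseline_ap": base[sid],
            "delta": pred[sid] - base[sid],
            "improved": pred[sid] > base[sid],
        }
        for sid in common
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["n_improved"] = int(frame["improved"].sum())
    frame.attrs["pct_improved"] = 100.0 * frame["improved"].mean()
    return frame
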