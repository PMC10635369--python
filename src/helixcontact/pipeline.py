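"""Glue between paired structures and the training/evaluation protocol.

For every sequence the candidate pair list and the ground-truth contact
labels are always derived from the EXPERIMENTAL structure; the predicted
structure contributes a second feature matrix over the identical pair set
plus its own binary contact annotations (the comparison baseline).  Pairs
whose 3x3 window is incomplete in either structure are dropped from both
sides so the two feature sources score the same pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from helixcontact.contact_map import (
    CONTACT_THRESHOLD,
    SEPARATION_THRESHOLD,
    ResiduePair,
    candidate_pairs,
    label_contacts,
    min_heavy_atom_distance,
)
from helixcontact.evaluate import (
    MetricsReport,
    SequenceData,
    annotation_baseline_report,
    compare_sources,
    cross_validate,
)
from helixcontact.features import FeatureMatrix, extract_features
from helixcontact.model import ModelConfig
from helixcontact.structure_io import (
    PairedStructure,
    parse_pdb_coordinates,
    read_annotation,
    reconcile_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SequencePair",
    "build_sequence_data",
    "build_datasets",
    "load_benchmark",
    "run_protocol",
]


@dataclass
class SequencePair:
    """Experimental- and predicted-source views of one sequence."""

    sequence_id: str
    experimental: SequenceData
    predicted: SequenceData
    n_skipped: int


def _subset(matrix: FeatureMatrix, keep: list[ResiduePair]) -> FeatureMatrix:
    index = {(p.i, p.j): r for r, p in enumerate(matrix.pair_index)}
    rows = [index[(p.i, p.j)] for p in keep]
    return FeatureMatrix(
        kind=matrix.kind,
        vectors=matrix.vectors[rows],
        pair_index=list(keep),
        sequence_ids=[matrix.sequence_ids[r] for r in rows],
    )


def build_sequence_data(
    sequence_id: str,
    paired: PairedStructure,
    kind: str,
    *,
    separation: int = SEPARATION_THRESHOLD,
    threshold: float = CONTACT_THRESHOLD,
    theta_mode: str = "center",
) -> SequencePair:
    """Feature matrices, labels and the annotation baseline for one pair."""
    exp, pred, ann = paired.experimental, paired.predicted, paired.annotation
    pairs = candidate_pairs(exp, ann, separation=separation)

    exp_matrix, kept, n_skip_exp = extract_features(
        exp, ann, pairs, kind, sequence_id, theta_mode=theta_mode
    )
    pred_matrix, kept2, n_skip_pred = extract_features(
        pred, ann, kept, kind, sequence_id,
        index_map=paired.full_mapping, theta_mode=theta_mode,
    )
    if len(kept2) < len(kept):
        exp_matrix = _subset(exp_matrix, kept2)
    n_skipped = n_skip_exp + n_skip_pred
    if n_skipped:
        logger.info(
            "%s: skipped %d of %d pairs with incomplete neighborhoods",
            sequence_id, n_skipped, len(pairs),
        )

    labels = label_contacts(exp, kept2, threshold=threshold).labels
    baseline = np.fromiter(
        (
            min_heavy_atom_distance(
                pred[paired.mapping[p.i]], pred[paired.mapping[p.j]]
            ) < threshold
            for p in kept2
        ),
        dtype=int,
        count=len(kept2),
    )
    L = ann.total_length
    return SequencePair(
        sequence_id=sequence_id,
        experimental=SequenceData(
            sequence_id=sequence_id,
            features=exp_matrix,
            labels=labels,
            L=L,
            baseline_labels=baseline,
        ),
        predicted=SequenceData(
            sequence_id=sequence_id,
            features=pred_matrix,
            labels=labels,
            L=L,
            baseline_labels=baseline,
        ),
        n_skipped=n_skipped,
    )


def build_datasets(
    benchmark: list[tuple[str, PairedStructure]],
    kind: str,
    **kwargs,
) -> tuple[list[SequenceData], list[SequenceData]]:
    """(experimental-source, predicted-source) datasets over a benchmark."""
    exp_data, pred_data = [], []
    for sid, paired in benchmark:
        sp = build_sequence_data(sid, paired, kind, **kwargs)
        exp_data.append(sp.experimental)
        pred_data.append(sp.predicted)
    return exp_data, pred_data


def load_benchmark(data_dir: str | Path) -> list[tuple[str, PairedStructure]]:
    """Load a simulate-style directory via its manifest.tsv.

    Manifest columns: sequence_id, experimental, predicted, annotation and an
    optional integer offset (default 0) aligning the two numbering schemes.
    """
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"expected manifest file {manifest}")
    out = []
    lines = [ln for ln in manifest.read_text().splitlines() if ln.strip()]
    for ln in lines[1:]:
        parts = ln.split("\t")
        sid, exp_name, pred_name, ann_name = parts[:4]
        offset = int(parts[4]) if len(parts) > 4 else 0
        exp = parse_pdb_coordinates((data_dir / exp_name).read_text(), "A")
        pred = parse_pdb_coordinates((data_dir / pred_name).read_text(), "A")
        pred.source_tag = "predicted"
        ann = read_annotation((data_dir / ann_name).read_text())
        out.append((sid, reconcile_pair(exp, pred, offset, ann)))
    return out


def run_protocol(
    benchmark: list[tuple[str, PairedStructure]],
    config: ModelConfig,
    *,
    kinds: tuple[str, ...] = ("SDF", "CF"),
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    theta_mode: str = "center",
) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """Cross-validate each feature kind on both structure sources.

    Emits one summary row per (structure source, feature kind) plus the
    predicted-structure binary-annotation baseline, mirroring the layout of a
    classifier-comparison table.  Returns (summary frame, named reports).
    """
    rows = []
    reports: dict[str, MetricsReport] = {}
    for kind in kinds:
        exp_data, pred_data = build_datasets(benchmark, kind, theta_mode=theta_mode)
        rep_exp = cross_validate(exp_data, config, k=k, repeats=repeats, seed=seed)
        rep_pred = cross_validate(
            exp_data, config, k=k, repeats=repeats, seed=seed, test_dataset=pred_data
        )
        reports[f"experimental+{kind}"] = rep_exp
        reports[f"predicted+{kind}"] = rep_pred
        rows.append({
            "classifier": "NN", "source": "experimental", "features": kind,
            "ap": rep_exp.mean_ap, "ap_std": rep_exp.std_ap,
            "auc": rep_exp.mean_auc, "auc_std": rep_exp.std_auc,
        })
        rows.append({
            "classifier": "NN", "source": "predicted", "features": kind,
            "ap": rep_pred.mean_ap, "ap_std": rep_pred.std_ap,
            "auc": rep_pred.mean_auc, "auc_std": rep_pred.std_auc,
        })
        if kind == kinds[0]:
            baseline = annotation_baseline_report(pred_data)
            reports["annotation-baseline"] = baseline
            rows.append({
                "classifier": "structure annotations", "source": "predicted",
                "features": "-",
                "ap": baseline.mean_ap, "ap_std": 0.0,
                "auc": baseline.mean_auc, "auc_std": 0.0,
            })
    summary = pd.DataFrame(rows)
    if "predicted+SDF" in reports and "annotation-baseline" in reports:
        improvement = compare_sources(
            reports["predicted+SDF"], reports["annotation-baseline"]
        )
        summary.attrs["n_improved"] = improvement.attrs["n_improved"]
        summary.attrs["pct_improved"] = improvement.attrs["pct_improved"]
    return summary, reports
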