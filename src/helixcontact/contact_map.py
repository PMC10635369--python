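"""Candidate inter-helical residue pairs, binary contact labels and the
contact ratio.

A residue pair (i, j) is a candidate when i and j sit on two distinct
annotated helices and |i - j| exceeds the sequence-separation threshold
(default 5, i.e. |i - j| > 5).  A candidate is a contact when the least
distance between any pair of heavy atoms of the two residues is strictly
below the distance threshold (default 5.5 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from helixcontact.structure_io import (
    ChainStructure,
    HelixAnnotation,
    Residue,
    StructureError,
)

__all__ = [
    "ResiduePair",
    "ContactMap",
    "DatasetStats",
    "CONTACT_THRESHOLD",
    "SEPARATION_THRESHOLD",
    "min_heavy_atom_distance",
    "candidate_pairs",
    "label_contacts",
    "contact_ratio",
    "write_contact_map",
    "read_contact_map",
]

#: Heavy-atom distance below which a pair is a contact (strict '<').
CONTACT_THRESHOLD = 5.5
#: Candidates require |i - j| > SEPARATION_THRESHOLD.
SEPARATION_THRESHOLD = 5


@dataclass(frozen=True)
class ResiduePair:
    """An unordered inter-helical candidate pair, stored with i < j."""

    i: int
    j: int
    helix_i: int
    helix_j: int

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError(f"require i < j, got ({self.i}, {self.j})")
        if self.helix_i == self.helix_j:
            raise ValueError("pair members must lie on distinct helices")


@dataclass
class ContactMap:
    """Candidate pairs with binary labels and optional real-valued scores."""

    pairs: list[ResiduePair]
    labels: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.pairs),):
            raise ValueError("labels must align with pairs")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != (len(self.pairs),):
                raise ValueError("scores must align with pairs")
            if not np.all(np.isfinite(self.scores)):
                raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DatasetStats:
    n_pairs: int
    n_contacts: int
    contact_ratio: float


def min_heavy_atom_distance(a: Residue, b: Residue) -> float:
    """Least Euclidean distance between any heavy atoms of two residues."""
    if not a.atoms or not b.atoms:
        raise StructureError("residue with no atoms")
    return float(cdist(a.heavy_coords, b.heavy_coords).min())


def candidate_pairs(
    chain: ChainStructure,
    ann: HelixAnnotation,
    separation: int = SEPARATION_THRESHOLD,
) -> list[ResiduePair]:
    """All inter-helical pairs with |i - j| > ``separation``, (i asc, j asc)."""
    ann.validate_on(chain)
    members = [
        (si, k)
        for k, (a, b) in enumerate(ann.segments)
        for si in range(a, b + 1)
    ]
    out = []
    for x, (i, hi) in enumerate(members):
        for j, hj in members[x + 1:]:
            if hi != hj and j - i > separation:
                out.append(ResiduePair(i=i, j=j, helix_i=hi, helix_j=hj))
    return out


def label_contacts(
    chain: ChainStructure,
    pairs: list[ResiduePair],
    threshold: float = CONTACT_THRESHOLD,
) -> ContactMap:
    """Label each pair 1 iff its minimum heavy-atom distance is < threshold."""
    labels = np.fromiter(
        (min_heavy_atom_distance(chain[p.i], chain[p.j]) < threshold for p in pairs),
        dtype=int,
        count=len(pairs),
    )
    return ContactMap(pairs=list(pairs), labels=labels)


def contact_ratio(cm: ContactMap) -> DatasetStats:
    """Contacts over candidate pairs (CR)."""
    if len(cm) == 0:
        raise ValueError("contact ratio undefined for an empty contact map")
    n_contacts = int(cm.labels.sum())
    return DatasetStats(
        n_pairs=len(cm),
        n_contacts=n_contacts,
        contact_ratio=n_contacts / len(cm),
    )


def write_contact_map(cm: ContactMap) -> str:
    """Tab-separated 'i  j  label  score' serialization, 0-based indices."""
    lines = ["i\tj\tlabel\tscore"]
    scores = cm.scores if cm.scores is not None else [float("nan")] * len(cm)
    for p, lab, sc in zip(cm.pairs, cm.labels, scores):
        lines.append(f"{p.i}\t{p.j}\t{int(lab)}\t{sc:.10g}")
    return "\n".join(lines) + "\n"


def read_contact_map(text: str, pairs: list[ResiduePair] | None = None) -> ContactMap:
    """Read the tab-separated serialization.

    When ``pairs`` is given it supplies the helix assignments (and must match
    the (i, j) keys in the file); otherwise helix indices are synthesized as
    0/1, which suffices for score-only comparison files.
    """
    by_key = {(p.i, p.j): p for p in pairs} if pairs is not None else None
    out_pairs, labels, scores = [], [], []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        i_s, j_s, lab_s, sc_s = ln.split("\t")
        i, j = int(i_s), int(j_s)
        if by_key is not None:
            try:
                pair = by_key[(i, j)]
            except KeyError:
                raise ValueError(f"pair ({i}, {j}) not in the supplied pair list")
        else:
            pair = ResiduePair(i=i, j=j, helix_i=0, helix_j=1)
        out_pairs.append(pair)
        labels.append(int(lab_s))
        scores.append(float(sc_s))
    scores_arr = np.asarray(scores, dtype=float)
    return ContactMap(
        pairs=out_pairs,
        labels=np.asarray(labels, dtype=int),
        scores=None if np.isnan(scores_arr).all() else scores_arr,
    )
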