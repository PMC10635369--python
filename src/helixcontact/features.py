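"""Geometric features for inter-helical residue pairs.

Five per-pair features are computed from atomic coordinates:

* ``theta``   -- inter-helical tilt angle: angle between the axes of the two
  helices hosting the pair, where each axis is the normalized mean of the unit
  vectors from O(i) to N(i+4) over the helix.
* ``d1_mean`` -- mean Euclidean distance over all heavy-atom pairs of the two
  residues.
* ``d1_sd``   -- population standard deviation of those same distances
  (divisor M*N, not M*N - 1).
* ``d_alpha`` -- the Calpha-Calpha distance.
* ``delta``   -- angle between the residue-plane normals, where a residue's
  plane is spanned by (N - CA) and (C - CA).

For a candidate pair (i, j) the structurally derived feature (SDF) vector
concatenates these five numbers for each of the eight positions of the 3x3
window around (i, j) (the center excluded), giving length 40.  The coordinate
feature (CF) baseline concatenates raw x, y, z of N, CA, O, CB for both
residues of each window position, giving length 192.  All angles are reported
in degrees in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from helixcontact.contact_map import ResiduePair
from helixcontact.structure_io import (
    ChainStructure,
    HelixAnnotation,
    Residue,
    StructureError,
)

__all__ = [
    "SDF_LENGTH",
    "CF_LENGTH",
    "WINDOW_OFFSETS",
    "HelixAxis",
    "PairFeatures",
    "FeatureMatrix",
    "ScalingParams",
    "IncompleteNeighborhoodError",
    "helix_axis",
    "interhelical_tilt",
    "pair_distance_features",
    "residue_plane_normal",
    "relative_residue_angle",
    "sdf_vector",
    "cf_vector",
    "extract_features",
    "fit_scaler",
    "apply_scaler",
    "write_feature_matrix",
    "read_feature_matrix",
]

SDF_LENGTH = 40
CF_LENGTH = 192

#: Fixed row-major order of the 3x3 window positions (center excluded).
WINDOW_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

#: CF atom order per residue; glycine's missing CB falls back to CA.
CF_ATOMS = ("N", "CA", "O", "CB")


class IncompleteNeighborhoodError(StructureError):
    """A window position is missing from the chain or lacks required atoms."""


@dataclass(frozen=True)
class HelixAxis:
    """Unit axis direction of a helix segment (N- to C-terminus)."""

    direction: np.ndarray
    segment: tuple[int, int]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise StructureError("helix axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class PairFeatures:
    theta: float
    d1_mean: float
    d1_sd: float
    d_alpha: float
    delta: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.theta, self.d1_mean, self.d1_sd, self.d_alpha, self.delta]
        )


@dataclass
class FeatureMatrix:
    """Per-pair feature vectors aligned with their (sequence, pair) keys."""

    kind: str
    vectors: np.ndarray
    pair_index: list[ResiduePair]
    sequence_ids: list[str]

    def __post_init__(self):
        if self.kind not in ("SDF", "CF"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.vectors = np.asarray(self.vectors, dtype=float)
        width = SDF_LENGTH if self.kind == "SDF" else CF_LENGTH
        if self.vectors.ndim != 2 or self.vectors.shape[1] != width:
            raise ValueError(
                f"{self.kind} matrix must have width {width}, "
                f"got shape {self.vectors.shape}"
            )
        if len(self.pair_index) != len(self.vectors) or len(self.sequence_ids) != len(self.vectors):
            raise ValueError("pair_index/sequence_ids must align with vectors")

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class ScalingParams:
    """Per-feature min/max fitted on training data, for [-1, 1] scaling."""

    kind: str
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        width = SDF_LENGTH if self.kind == "SDF" else CF_LENGTH
        if self.minimum.shape != (width,) or self.maximum.shape != (width,):
            raise ValueError("scaling params must match the feature width")
        if np.any(self.minimum > self.maximum):
            raise ValueError("per-feature min must not exceed max")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise StructureError(f"{what}: zero-length vector")
    return v / n


def helix_axis(chain: ChainStructure, segment: tuple[int, int]) -> HelixAxis:
    """Axis = normalized mean of unit O(i) -> N(i+4) vectors over the helix."""
    start, end = segment
    if end - start + 1 < 5:
        raise StructureError(f"helix too short: segment ({start}, {end})")
    directions = []
    for i in range(start, end - 3):
        o = chain[i].atom("O")
        if o is None:
            raise StructureError(f"missing backbone atom O in residue {i}")
        n = chain[i + 4].atom("N")
        if n is None:
            raise StructureError(f"missing backbone atom N in residue {i + 4}")
        directions.append(_unit(n.coords - o.coords, f"O({i})->N({i + 4})"))
    mean_dir = np.mean(directions, axis=0)
    return HelixAxis(direction=_unit(mean_dir, "helix axis"), segment=(start, end))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(np.dot(u, v), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interhelical_tilt(axis_a: HelixAxis, axis_b: HelixAxis) -> float:
    """Angle between two helix axes, degrees in [0, 180] (not folded)."""
    return _angle_deg(axis_a.direction, axis_b.direction)


def pair_distance_features(a: Residue, b: Residue) -> tuple[float, float, float]:
    """(mean, population SD) of all heavy-atom pair distances, and CA-CA."""
    d = cdist(a.heavy_coords, b.heavy_coords).ravel()
    ca_a, ca_b = a.atom("CA"), b.atom("CA")
    if ca_a is None or ca_b is None:
        raise StructureError("missing alpha carbon")
    d_alpha = float(np.linalg.norm(ca_a.coords - ca_b.coords))
    return float(d.mean()), float(d.std()), d_alpha


def residue_plane_normal(r: Residue) -> np.ndarray:
    """Unit normal of the plane spanned by (N - CA) and (C - CA)."""
    n = r.coords_of("N") - r.coords_of("CA")
    c = r.coords_of("C") - r.coords_of("CA")
    cross = np.cross(n, c)
    norm = np.linalg.norm(cross)
    if norm < 1e-9:
        raise StructureError(f"degenerate plane: N, CA, C collinear in residue {r.seq_index}")
    return cross / norm


def relative_residue_angle(a: Residue, b: Residue) -> float:
    """Angle between the two residue-plane normals, degrees in [0, 180]."""
    return _angle_deg(residue_plane_normal(a), residue_plane_normal(b))


def _neighbor(
    chain: ChainStructure,
    idx: int,
    index_map: dict[int, int] | None,
) -> Residue:
    if index_map is not None:
        if idx not in index_map:
            raise IncompleteNeighborhoodError(f"residue {idx} has no mapped counterpart")
        idx = index_map[idx]
    if not 0 <= idx < len(chain):
        raise IncompleteNeighborhoodError(f"residue {idx} outside the chain")
    return chain[idx]


def sdf_vector(
    chain: ChainStructure,
    ann: HelixAnnotation,
    pair: ResiduePair,
    *,
    index_map: dict[int, int] | None = None,
    axes: dict[int, HelixAxis] | None = None,
    theta_mode: str = "center",
) -> np.ndarray:
    """Length-40 structurally derived feature vector for one candidate pair.

    The tilt angle is a helix-pair property; by default (``theta_mode
    'center'``) it is computed once from the two helices hosting the center
    pair and repeated at every window position, which keeps the vector
    well-defined when a window neighbor falls off its helix.  ``theta_mode
    'neighbor'`` instead uses each neighbor's own helices and raises
    ``IncompleteNeighborhoodError`` when a neighbor is off-helix.

    ``index_map`` translates annotation-space indices into this chain's
    indices (used when scoring a predicted structure against the experimental
    chain's pair list); ``axes`` caches helix axes keyed by segment index.
    """
    if theta_mode not in ("center", "neighbor"):
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    segments = ann.segments
    if axes is None:
        axes = {}

    def axis_for(seg_idx: int) -> HelixAxis:
        if seg_idx not in axes:
            a, b = segments[seg_idx]
            if index_map is not None:
                if a not in index_map or b not in index_map:
                    raise IncompleteNeighborhoodError(
                        f"segment {seg_idx} not fully mapped onto the chain"
                    )
                a, b = index_map[a], index_map[b]
            axes[seg_idx] = helix_axis(chain, (a, b))
        return axes[seg_idx]

    center_theta = interhelical_tilt(axis_for(pair.helix_i), axis_for(pair.helix_j))

    out = np.empty(SDF_LENGTH)
    for w, (di, dj) in enumerate(WINDOW_OFFSETS):
        ri = _neighbor(chain, pair.i + di, index_map)
        rj = _neighbor(chain, pair.j + dj, index_map)
        if not ri.atoms or not rj.atoms:
            raise IncompleteNeighborhoodError("window residue has no atoms")
        try:
            if theta_mode == "center":
                theta = center_theta
            else:
                hi = ann.segment_of(pair.i + di)
                hj = ann.segment_of(pair.j + dj)
                if hi is None or hj is None or hi == hj:
                    raise IncompleteNeighborhoodError(
                        f"window position ({di}, {dj}) is off-helix"
                    )
                theta = interhelical_tilt(axis_for(hi), axis_for(hj))
            d1_mean, d1_sd, d_alpha = pair_distance_features(ri, rj)
            delta = relative_residue_angle(ri, rj)
        except IncompleteNeighborhoodError:
            raise
        except StructureError as exc:
            raise IncompleteNeighborhoodError(str(exc)) from exc
        out[5 * w: 5 * w + 5] = (theta, d1_mean, d1_sd, d_alpha, delta)
    return out


def _cf_residue_block(r: Residue) -> np.ndarray:
    block = np.empty(12)
    for k, name in enumerate(CF_ATOMS):
        atom = r.atom(name)
        if atom is None and name == "CB":
            atom = r.atom("CA")  # glycine fallback
        if atom is None:
            raise IncompleteNeighborhoodError(
                f"residue {r.seq_index}: missing atom {name!r}"
            )
        block[3 * k: 3 * k + 3] = atom.coords
    return block


def cf_vector(
    chain: ChainStructure,
    pair: ResiduePair,
    *,
    index_map: dict[int, int] | None = None,
) -> np.ndarray:
    """Length-192 coordinate baseline: x,y,z of N, CA, O, CB for both residues
    of each window position (24 numbers x 8 positions)."""
    out = np.empty(CF_LENGTH)
    for w, (di, dj) in enumerate(WINDOW_OFFSETS):
        ri = _neighbor(chain, pair.i + di, index_map)
        rj = _neighbor(chain, pair.j + dj, index_map)
        out[24 * w: 24 * w + 12] = _cf_residue_block(ri)
        out[24 * w + 12: 24 * w + 24] = _cf_residue_block(rj)
    return out


def extract_features(
    chain: ChainStructure,
    ann: HelixAnnotation,
    pairs: list[ResiduePair],
    kind: str,
    sequence_id: str,
    *,
    index_map: dict[int, int] | None = None,
    theta_mode: str = "center",
) -> tuple[FeatureMatrix, list[ResiduePair], int]:
    """Build a FeatureMatrix over ``pairs``, skipping incomplete neighborhoods.

    Returns the matrix, the pairs actually kept (in input order) and the
    number skipped.  Pairs are keyed in the annotation's index space even when
    ``index_map`` redirects atom lookups into another chain.
    """
    if kind not in ("SDF", "CF"):
        raise ValueError(f"unknown feature kind {kind!r}")
    axes: dict[int, HelixAxis] = {}
    rows, kept = [], []
    skipped = 0
    for pair in pairs:
        try:
            if kind == "SDF":
                vec = sdf_vector(
                    chain, ann, pair,
                    index_map=index_map, axes=axes, theta_mode=theta_mode,
                )
            else:
                vec = cf_vector(chain, pair, index_map=index_map)
        except IncompleteNeighborhoodError:
            skipped += 1
            continue
        rows.append(vec)
        kept.append(pair)
    width = SDF_LENGTH if kind == "SDF" else CF_LENGTH
    vectors = np.array(rows) if rows else np.empty((0, width))
    matrix = FeatureMatrix(
        kind=kind,
        vectors=vectors,
        pair_index=kept,
        sequence_ids=[sequence_id] * len(kept),
    )
    return matrix, kept, skipped


def fit_scaler(train: FeatureMatrix) -> ScalingParams:
    """Per-feature min/max from the training matrix."""
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalingParams(
        kind=train.kind,
        minimum=train.vectors.min(axis=0),
        maximum=train.vectors.max(axis=0),
    )


def apply_scaler(params: ScalingParams, m: FeatureMatrix) -> FeatureMatrix:
    """Scale to [-1, 1]: -1 + 2 (f - min) / (max - min); no clipping.

    Constant training columns map to 0 (the midpoint).
    """
    if params.kind != m.kind:
        raise ValueError(f"scaler kind {params.kind!r} != matrix kind {m.kind!r}")
    span = params.maximum - params.minimum
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = -1.0 + 2.0 * (m.vectors - params.minimum) / safe_span
    scaled[:, constant] = 0.0
    return FeatureMatrix(
        kind=m.kind,
        vectors=scaled,
        pair_index=list(m.pair_index),
        sequence_ids=list(m.sequence_ids),
    )


def write_feature_matrix(m: FeatureMatrix) -> str:
    """TSV: (sequence_id, i, j) key columns then the feature columns."""
    width = m.vectors.shape[1]
    header = ["sequence_id", "i", "j"] + [f"f{k}" for k in range(width)]
    lines = ["\t".join(header)]
    for sid, pair, row in zip(m.sequence_ids, m.pair_index, m.vectors):
        lines.append(
            "\t".join([sid, str(pair.i), str(pair.j)] + [f"{v:.10g}" for v in row])
        )
    return "\n".join(lines) + "\n"


def read_feature_matrix(text: str, kind: str) -> FeatureMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    width = SDF_LENGTH if kind == "SDF" else CF_LENGTH
    sids, pairs, rows = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        sids.append(parts[0])
        i, j = int(parts[1]), int(parts[2])
        pairs.append(ResiduePair(i=i, j=j, helix_i=0, helix_j=1))
        rows.append([float(v) for v in parts[3:]])
    vectors = np.array(rows) if rows else np.empty((0, width))
    return FeatureMatrix(kind=kind, vectors=vectors, pair_index=pairs, sequence_ids=sids)


def write_scaling_params(params: ScalingParams) -> str:
    width = len(params.minimum)
    header = ["stat"] + [f"f{k}" for k in range(width)]
    lines = [
        "\t".join(header),
        "\t".join(["min"] + [f"{v:.10g}" for v in params.minimum]),
        "\t".join(["max"] + [f"{v:.10g}" for v in params.maximum]),
    ]
    return "\n".join(lines) + "\n"


def read_scaling_params(text: str, kind: str) -> ScalingParams:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = {ln.split("\t")[0]: [float(v) for v in ln.split("\t")[1:]] for ln in lines[1:]}
    return ScalingParams(kind=kind, minimum=np.array(rows["min"]), maximum=np.array(rows["max"]))
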