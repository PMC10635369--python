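"""PDB-format coordinate I/O, the chain data model, TM-helix annotations and
experimental/predicted residue-numbering reconciliation.

Only fixed-column ``ATOM`` records are interpreted (``HETATM`` is ignored and
only the first model of a multi-model file is read).  Hydrogens are dropped at
parse time so that every downstream consumer sees heavy atoms only.  Internally
residues are addressed by a contiguous 0-based ``seq_index``; the author
numbering from the file is retained solely for I/O and for aligning a predicted
structure against its experimental counterpart via an integer offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainStructure",
    "HelixAnnotation",
    "PairedStructure",
    "StructureError",
    "EmptyChainError",
    "PdbParseError",
    "PdbFormatError",
    "PartialMatchError",
    "parse_pdb_coordinates",
    "write_pdb_coordinates",
    "reconcile_pair",
    "read_annotation",
    "write_annotation",
]


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class EmptyChainError(StructureError):
    """No ATOM records found for the requested chain."""


class PdbParseError(StructureError):
    """A malformed ATOM record; the message names the offending line."""


class PdbFormatError(StructureError):
    """A chain cannot be expressed in fixed-column PDB format."""


class PartialMatchError(StructureError):
    """Experimental and predicted chains disagree inside a TM segment."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element, 3-d coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(
                f"atom {self.name!r}: coords must be 3 finite components"
            )
        object.__setattr__(self, "coords", c)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """A residue with its retained heavy atoms.

    ``seq_index`` is the 0-based contiguous position within the chain;
    ``author_number`` is the residue number printed in the source file.
    """

    seq_index: int
    author_number: int
    aa_code: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_of(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise StructureError(
                f"residue {self.seq_index} ({self.aa_code}): missing atom {name!r}"
            )
        return a.coords

    @property
    def heavy_coords(self) -> np.ndarray:
        """(n_atoms, 3) array of all retained (heavy) atom coordinates."""
        if not self.atoms:
            raise StructureError(f"residue {self.seq_index}: no atoms")
        return np.stack([a.coords for a in self.atoms])

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))


@dataclass
class ChainStructure:
    """Ordered residues of one protein chain."""

    chain_id: str
    residues: list[Residue]
    source_tag: str = "experimental"

    def __post_init__(self):
        if not self.residues:
            raise EmptyChainError(f"chain {self.chain_id!r} has no residues")
        if self.source_tag not in ("experimental", "predicted"):
            raise StructureError(f"bad source_tag {self.source_tag!r}")
        for k, r in enumerate(self.residues):
            if r.seq_index != k:
                raise StructureError(
                    f"chain {self.chain_id!r}: seq_index not contiguous at {k}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, seq_index: int) -> Residue:
        return self.residues[seq_index]

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)


@dataclass
class HelixAnnotation:
    """TM-helix segments as inclusive ``(start, end)`` seq_index ranges."""

    segments: list[tuple[int, int]]

    def __post_init__(self):
        segs = [(int(a), int(b)) for a, b in self.segments]
        segs.sort()
        for a, b in segs:
            if b - a + 1 < 5:
                raise StructureError(
                    f"segment ({a}, {b}) shorter than 5 residues"
                )
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            if s1 <= e0:
                raise StructureError("overlapping TM segments")
        self.segments = segs

    def segment_of(self, seq_index: int) -> int | None:
        """Index of the segment containing ``seq_index``, or None."""
        for k, (a, b) in enumerate(self.segments):
            if a <= seq_index <= b:
                return k
        return None

    @property
    def total_length(self) -> int:
        """Total concatenated TM-helix length (the 'L' of top-L metrics)."""
        return sum(b - a + 1 for a, b in self.segments)

    def validate_on(self, chain: ChainStructure) -> None:
        for a, b in self.segments:
            if a < 0 or b >= len(chain):
                raise StructureError(
                    f"segment ({a}, {b}) outside chain of length {len(chain)}"
                )


@dataclass
class PairedStructure:
    """An experimental chain paired with its predicted counterpart.

    ``offset`` is added to experimental author numbering to obtain the
    predicted chain's author numbering.  ``mapping`` sends experimental
    seq_index to predicted seq_index over the annotated segments.
    """

    experimental: ChainStructure
    predicted: ChainStructure
    offset: int
    annotation: HelixAnnotation
    mapping: dict[int, int]
    full_mapping: dict[int, int]

    def predicted_annotation(self) -> HelixAnnotation:
        """The TM annotation translated into the predicted chain's indices."""
        return HelixAnnotation(
            segments=[(self.mapping[a], self.mapping[b]) for a, b in self.annotation.segments]
        )


def _parse_float(text: str, line: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PdbParseError(f"malformed {what} field in line: {line.rstrip()!r}")


def _element_of(line: str, atom_name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.upper()
    # Fall back to the atom-name convention: columns 13-16, element
    # right-justified in the first two characters.
    name = atom_name.strip()
    if name and name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper()


def parse_pdb_coordinates(text: str, chain_id: str) -> ChainStructure:
    """Parse ATOM records for one chain from a PDB-format string.

    Hydrogens are discarded.  When the same atom name appears with several
    alternate locations, the record with the highest occupancy wins (ties:
    first encountered).  Residues are re-indexed contiguously from 0 in file
    order.  Only the first model of a multi-model file is read.
    """
    residues: list[Residue] = []
    index_of: dict[tuple[int, str], int] = {}

    for line in text.splitlines():
        rec = line[:6]
        if rec.strip() in ("ENDMDL", "END"):
            break
        if rec != "ATOM  ":
            continue
        if (line[21:22] or " ") != (chain_id or " "):
            continue
        atom_name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:20].strip()
        try:
            author_number = int(line[22:26])
        except ValueError:
            raise PdbParseError(f"malformed residue number in line: {line.rstrip()!r}")
        icode = line[26:27].strip()
        x = _parse_float(line[30:38], line, "x coordinate")
        y = _parse_float(line[38:46], line, "y coordinate")
        z = _parse_float(line[46:54], line, "z coordinate")
        occ_text = line[54:60].strip()
        occupancy = _parse_float(occ_text, line, "occupancy") if occ_text else 1.0
        element = _element_of(line, line[12:16])
        if element in _HYDROGEN_ELEMENTS:
            continue

        key = (author_number, icode)
        if key not in index_of:
            index_of[key] = len(residues)
            residues.append(
                Residue(
                    seq_index=len(residues),
                    author_number=author_number,
                    aa_code=THREE_TO_ONE.get(res_name, "X"),
                )
            )
        res = residues[index_of[key]]
        atom = AtomRecord(
            name=atom_name,
            element=element,
            coords=(x, y, z),
            occupancy=occupancy,
            altloc=altloc,
        )
        existing = res.atom(atom_name)
        if existing is None:
            res.atoms.append(atom)
        elif atom.occupancy > existing.occupancy:
            res.atoms[res.atoms.index(existing)] = atom

    if not residues:
        raise EmptyChainError(f"no ATOM records for chain {chain_id!r}")
    return ChainStructure(chain_id=chain_id, residues=residues)


def write_pdb_coordinates(chain: ChainStructure) -> str:
    """Serialize a chain as fixed-column PDB ATOM records (3-decimal coords)."""
    lines = []
    serial = 0
    for res in chain.residues:
        res_name = ONE_TO_THREE.get(res.aa_code, "UNK")
        for atom in res.atoms:
            serial += 1
            name = atom.name
            if len(name) > 4:
                raise PdbFormatError(f"atom name {name!r} longer than 4 characters")
            # Standard alignment: names of <4 chars with 1-char element start
            # in column 14.
            padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
            x, y, z = atom.coords
            if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999
                    and -999.999 <= z <= 9999.999):
                raise PdbFormatError(f"coordinate out of PDB column range: {atom.coords}")
            lines.append(
                f"ATOM  {serial:>5d} {padded}{'':1s}{res_name:>3s} "
                f"{chain.chain_id:1s}{res.author_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def reconcile_pair(
    exp: ChainStructure,
    pred: ChainStructure,
    offset: int,
    annotation: HelixAnnotation,
) -> PairedStructure:
    """Align experimental and predicted chains under an integer offset.

    The annotation lives in the experimental chain's seq_index space.  Every
    annotated residue must be present in the predicted chain at author number
    ``exp_author + offset`` with an identical amino acid; otherwise the pair is
    rejected, mirroring the removal of partially matching chains.
    """
    annotation.validate_on(exp)
    pred_by_author = {r.author_number: r for r in pred.residues}
    mapping: dict[int, int] = {}
    for a, b in annotation.segments:
        for si in range(a, b + 1):
            exp_res = exp[si]
            target = exp_res.author_number + offset
            pred_res = pred_by_author.get(target)
            if pred_res is None:
                raise PartialMatchError(
                    f"annotated residue seq_index {si} (author {exp_res.author_number}) "
                    f"has no counterpart at predicted author number {target}"
                )
            if pred_res.aa_code != exp_res.aa_code:
                raise PartialMatchError(
                    f"amino-acid mismatch at seq_index {si}: "
                    f"{exp_res.aa_code} (experimental) vs {pred_res.aa_code} (predicted)"
                )
            mapping[si] = pred_res.seq_index
    # TM segments must map onto contiguous runs of the predicted chain.
    for a, b in annotation.segments:
        run = [mapping[si] for si in range(a, b + 1)]
        if run != list(range(run[0], run[0] + len(run))):
            raise PartialMatchError(
                f"segment ({a}, {b}) does not map to a contiguous predicted run"
            )
    # Best-effort mapping over the whole common span, used only to look up
    # window neighbors that fall outside the annotated segments.
    full_mapping = {
        r.seq_index: pred_by_author[r.author_number + offset].seq_index
        for r in exp.residues
        if r.author_number + offset in pred_by_author
    }
    return PairedStructure(
        experimental=exp,
        predicted=pred,
        offset=offset,
        annotation=annotation,
        mapping=mapping,
        full_mapping=full_mapping,
    )


def read_annotation(text: str) -> HelixAnnotation:
    """Parse 'start end' lines ('#' comments allowed) into an annotation."""
    segments = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructureError(f"bad annotation line: {raw!r}")
        segments.append((int(parts[0]), int(parts[1])))
    return HelixAnnotation(segments=segments)


def write_annotation(ann: HelixAnnotation) -> str:
    lines = ["# TM helix segments: start end (0-based, inclusive)"]
    lines += [f"{a} {b}" for a, b in ann.segments]
    return "\n".join(lines) + "\n"
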