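"""Ground-truth substructure matching and the detection-backend contract.

The primary path matches vocabulary SMARTS against the molecular graph
(the "ground truth" a trained image detector approximates).  Each match
becomes a :class:`SubstructureInstance`; automorphic repeats on the same
atom set are collapsed, R-group placeholder atoms never participate, and
single-atom fragments (counter-ions, solvents) yield no instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Protocol, Sequence

from rdkit import Chem

from .vocabulary import Vocabulary

Box = tuple[float, float, float, float]


class MatchingError(ValueError):
    """Raised for invalid matching inputs (e.g. missing coordinates)."""


@dataclass(frozen=True)
class AtomRecord:
    element: str
    charge: int = 0
    is_rgroup: bool = False


@dataclass
class MoleculeRecord:
    """A molecule as seen by the pipeline.

    ``coords2d`` holds one (x, y) depiction coordinate per atom when a
    layout is available (SDF input or a computed depiction); R-group
    placeholder atoms are flagged so matching can exclude them.
    """

    id: str
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, float]]
    coords2d: list[tuple[float, float]] | None = None
    rdmol: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for a, b, _order in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise MatchingError(f"molecule {self.id!r}: bad bond ({a}, {b})")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise MatchingError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)
        if self.coords2d is not None and len(self.coords2d) != n:
            raise MatchingError(
                f"molecule {self.id!r}: coords2d length {len(self.coords2d)} "
                f"!= atom count {n}"
            )

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str = "") -> "MoleculeRecord":
        atoms = [
            AtomRecord(
                element=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                is_rgroup=a.GetAtomicNum() == 0,
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        coords = None
        if mol.GetNumConformers():
            conf = mol.GetConformer()
            coords = [
                (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
                for i in range(mol.GetNumAtoms())
            ]
        return cls(id=mol_id, atoms=atoms, bonds=bonds, coords2d=coords,
                   rdmol=mol)

    @classmethod
    def from_smiles(cls, text: str, mol_id: str = "") -> "MoleculeRecord":
        """Parse SMILES or CXSMILES (R-group labels become flagged atoms)."""
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise MatchingError(f"unparseable SMILES: {text!r}")
        return cls.from_rdkit(mol, mol_id or text)

    @property
    def fragments(self) -> list[frozenset[int]]:
        """Connected components as atom-index sets."""
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.atoms))}
        for a, b, _ in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[int] = set()
        comps: list[frozenset[int]] = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        return comps

    def require_rdmol(self) -> Chem.Mol:
        if self.rdmol is None:
            raise MatchingError(
                f"molecule {self.id!r} carries no RDKit mol; build records "
                "via from_smiles/from_rdkit for matching"
            )
        return self.rdmol


@dataclass(frozen=True)
class SubstructureInstance:
    """One occurrence of a vocabulary substructure in a molecule or image."""

    substructure_index: int
    atom_indices: frozenset[int] = frozenset()
    box: Box | None = None
    score: float = 1.0
    is_backbone: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.score <= 1.0):
            raise MatchingError(f"instance score {self.score} outside (0, 1]")
        if self.box is not None:
            x0, y0, x1, y1 = self.box
            if x0 > x1 or y0 > y1:
                raise MatchingError(f"degenerate box {self.box}")


def match_substructures(
    mol: MoleculeRecord, vocab: Vocabulary
) -> list[SubstructureInstance]:
    """All distinct (substructure, atom-set) occurrences in ``mol``.

    Automorphic repeats of the same atom set count once; R-group atoms
    and atoms in single-atom fragments are excluded.  Graph matches
    carry score 1.
    """
    rd = mol.require_rdmol()
    excluded = {i for i, a in enumerate(mol.atoms) if a.is_rgroup}
    for frag in mol.fragments:
        if len(frag) == 1:
            excluded |= frag
    out: list[SubstructureInstance] = []
    seen: set[tuple[int, frozenset[int]]] = set()
    for sub in vocab:
        for match in rd.GetSubstructMatches(
            sub.query(), uniquify=True, maxMatches=100000
        ):
            atom_set = frozenset(match)
            if atom_set & excluded:
                continue
            key = (sub.index, atom_set)
            if key in seen:
                continue
            seen.add(key)
            out.append(SubstructureInstance(
                substructure_index=sub.index,
                atom_indices=atom_set,
                score=1.0,
                is_backbone=sub.is_backbone,
            ))
    return out


def suppress_redundant_backbones(
    instances: Sequence[SubstructureInstance],
) -> list[SubstructureInstance]:
    """Drop backbone instances fully covered by functional-group atoms.

    A carbon-backbone instance survives iff at least one of its atoms is
    not claimed by any functional-group instance; the overlap that
    remains is what links the substructure graph together.  Idempotent,
    never drops functional groups.
    """
    for inst in instances:
        if not inst.atom_indices:
            raise MatchingError(
                "suppress_redundant_backbones needs atom_indices on every "
                "instance"
            )
    fg_cover: set[int] = set()
    for inst in instances:
        if not inst.is_backbone:
            fg_cover |= inst.atom_indices
    return [
        inst
        for inst in instances
        if not inst.is_backbone or (inst.atom_indices - fg_cover)
    ]


def median_bond_length(mol: MoleculeRecord) -> float:
    """Median 2D bond length of the depiction; 1.0 when bond-free."""
    if mol.coords2d is None:
        raise MatchingError(f"molecule {mol.id!r} has no 2D coordinates")
    lengths = sorted(
        math.dist(mol.coords2d[a], mol.coords2d[b]) for a, b, _ in mol.bonds
    )
    if not lengths:
        return 1.0
    mid = len(lengths) // 2
    if len(lengths) % 2:
        return lengths[mid]
    return 0.5 * (lengths[mid - 1] + lengths[mid])


def instances_to_boxes(
    instances: Sequence[SubstructureInstance],
    mol: MoleculeRecord,
    atom_pad: float | None = None,
) -> list[SubstructureInstance]:
    """Attach axis-aligned bounding boxes derived from the 2D layout.

    Each box is the min/max over member-atom coordinates, padded on all
    sides by ``atom_pad`` (default 0.25 x median bond length) so that
    single-atom instances get nonzero area — the geometric oracle that
    stands in for a detector's predicted boxes.
    """
    if mol.coords2d is None:
        raise MatchingError(f"molecule {mol.id!r} has no 2D coordinates")
    if atom_pad is None:
        atom_pad = 0.25 * median_bond_length(mol)
    out: list[SubstructureInstance] = []
    for inst in instances:
        if not inst.atom_indices:
            raise MatchingError("instance without atom_indices cannot be boxed")
        xs = [mol.coords2d[i][0] for i in inst.atom_indices]
        ys = [mol.coords2d[i][1] for i in inst.atom_indices]
        box = (
            min(xs) - atom_pad, min(ys) - atom_pad,
            max(xs) + atom_pad, max(ys) + atom_pad,
        )
        out.append(replace(inst, box=box))
    return out


class DetectionBackend(Protocol):
    """Contract for image-based substructure detectors.

    ``detect`` maps a raster image (or an opaque key identifying one) to
    instances whose boxes are in image pixel coordinates and whose
    scores lie in (0, 1].  Only a fixture-replay test double ships here;
    trained segmentation models are out of scope.
    """

    def detect(self, image: object) -> list[SubstructureInstance]:
        ...


class FixtureReplayBackend:
    """Test double replaying stored detections keyed by image id."""

    def __init__(
        self, fixtures: Mapping[object, Sequence[SubstructureInstance]]
    ) -> None:
        self._fixtures = {k: list(v) for k, v in fixtures.items()}

    def detect(self, image: object) -> list[SubstructureInstance]:
        detections = self._fixtures.get(image, [])
        for inst in detections:
            if not (0.0 < inst.score <= 1.0):
                raise MatchingError(
                    f"fixture detection score {inst.score} outside (0, 1]"
                )
        return list(detections)
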