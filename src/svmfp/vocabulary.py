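"""Substructure vocabulary: the patterns that index the fingerprint axes.

A vocabulary is an ordered list of :class:`Substructure` entries, each a
SMARTS query of one of two kinds:

* ``functional_group`` — contains at least one heteroatom; attachment
  points are implicit single bonds to carbon.
* ``carbon_backbone`` — an all-carbon chain or ring pattern used to cover
  molecular regions not already claimed by functional groups.

The fingerprint side length ``n`` is the number of vocabulary entries
(optionally padded to a larger reserved index space, see
:class:`svmfp.fingerprint.SVMFConfig`).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

FUNCTIONAL_GROUP = "functional_group"
CARBON_BACKBONE = "carbon_backbone"
_KINDS = (FUNCTIONAL_GROUP, CARBON_BACKBONE)

# chain-end atom: a non-ring aliphatic carbon with at most one non-ring
# aliphatic carbon neighbour, i.e. the run cannot be extended -- this makes
# the shipped chain patterns mutually non-contained (maximal-run semantics)
_CAP = "[C;!R;!$([C;!R](~[C;!R])~[C;!R])]"
_MID = "[C;!R]"


class VocabularyError(ValueError):
    """Raised for malformed vocabulary files or invalid entries."""


@dataclass(frozen=True)
class Substructure:
    """One vocabulary entry occupying one index of the fingerprint axis."""

    index: int
    name: str
    smarts: str
    kind: str
    smiles: str | None = None

    def query(self) -> Chem.Mol:
        """RDKit query molecule compiled from the SMARTS (cached)."""
        return _compile_query(self.smarts)

    def structure(self) -> Chem.Mol:
        """A concrete structure for this entry, used as a *target* when
        testing whether another pattern is contained in it.

        Prefers the SMILES annotation; falls back to the SMARTS query
        graph itself.
        """
        if self.smiles:
            mol = Chem.MolFromSmiles(self.smiles)
            if mol is not None:
                return mol
        return self.query()

    @property
    def is_backbone(self) -> bool:
        return self.kind == CARBON_BACKBONE


_QUERY_CACHE: dict[str, Chem.Mol] = {}


def _compile_query(smarts: str) -> Chem.Mol:
    mol = _QUERY_CACHE.get(smarts)
    if mol is None:
        mol = Chem.MolFromSmarts(smarts)
        if mol is None:
            raise VocabularyError(f"unparseable SMARTS: {smarts!r}")
        _QUERY_CACHE[smarts] = mol
    return mol


def canonical_smarts(smarts: str) -> str:
    """Canonical text form of a SMARTS query, used for deduplication."""
    return Chem.MolToSmarts(_compile_query(smarts))


def validate_substructure(sub: Substructure) -> None:
    """Check the per-entry invariants; raise :class:`VocabularyError`.

    Heteroatom/carbon checks inspect the definite atomic numbers of the
    query atoms; entries whose elements are not determinable (pure
    wildcards) fail the functional-group check.
    """
    if sub.kind not in _KINDS:
        raise VocabularyError(f"entry {sub.name!r}: unknown kind {sub.kind!r}")
    if sub.index < 0:
        raise VocabularyError(f"entry {sub.name!r}: negative index")
    query = _compile_query(sub.smarts)
    nums = [a.GetAtomicNum() for a in query.GetAtoms()]
    if not nums:
        raise VocabularyError(f"entry {sub.name!r}: pattern has no atoms")
    if sub.kind == FUNCTIONAL_GROUP:
        if not any(z not in (0, 1, 6) for z in nums):
            raise VocabularyError(
                f"entry {sub.name!r}: functional group contains no heteroatom"
            )
    else:
        if not all(z == 6 for z in nums):
            raise VocabularyError(
                f"entry {sub.name!r}: carbon backbone contains a non-carbon atom"
            )


@dataclass(frozen=True)
class Vocabulary:
    """An ordered, validated collection of substructures.

    Indices are contiguous 0..n-1 and entry order follows index order.
    """

    entries: tuple[Substructure, ...]

    def __post_init__(self) -> None:
        seen_canon: dict[str, str] = {}
        for pos, sub in enumerate(self.entries):
            if sub.index != pos:
                raise VocabularyError(
                    f"entry {sub.name!r}: index {sub.index} out of order "
                    f"(expected {pos})"
                )
            validate_substructure(sub)
            canon = canonical_smarts(sub.smarts)
            if canon in seen_canon:
                raise VocabularyError(
                    f"entries {seen_canon[canon]!r} and {sub.name!r} share "
                    f"the same canonical SMARTS"
                )
            seen_canon[canon] = sub.name
        if not self.entries:
            raise VocabularyError("empty vocabulary")

    @classmethod
    def from_entries(cls, entries: Iterable[Substructure]) -> "Vocabulary":
        """Build a vocabulary, reindexing entries contiguously."""
        reindexed = tuple(
            replace(sub, index=i) for i, sub in enumerate(entries)
        )
        return cls(reindexed)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Substructure]:
        return iter(self.entries)

    def __getitem__(self, index: int) -> Substructure:
        return self.entries[index]

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def n_fg(self) -> int:
        return sum(1 for s in self.entries if s.kind == FUNCTIONAL_GROUP)

    @property
    def n_cb(self) -> int:
        return sum(1 for s in self.entries if s.kind == CARBON_BACKBONE)

    def is_backbone(self, index: int) -> bool:
        return self.entries[index].is_backbone


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary from a tab-separated file.

    Expected columns: ``index  name  smarts  smiles  kind``.  Lines whose
    first non-blank character is ``#`` are comments.  The ``smiles``
    column may be empty.
    """
    path = Path(path)
    rows: list[tuple[int, Substructure]] = []
    header: list[str] | None = None
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, raw in enumerate(reader, start=1):
            if not raw or not any(cell.strip() for cell in raw):
                continue
            if raw[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                if header != ["index", "name", "smarts", "smiles", "kind"]:
                    raise VocabularyError(
                        f"{path}:{lineno}: bad header {header!r}; expected "
                        "index, name, smarts, smiles, kind"
                    )
                continue
            if len(raw) != 5:
                raise VocabularyError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(raw)}"
                )
            idx_text, name, smarts, smiles, kind = (c.strip() for c in raw)
            try:
                idx = int(idx_text)
            except ValueError:
                raise VocabularyError(
                    f"{path}:{lineno}: non-integer index {idx_text!r}"
                ) from None
            sub = Substructure(
                index=idx, name=name, smarts=smarts,
                smiles=smiles or None, kind=kind,
            )
            try:
                validate_substructure(sub)
            except VocabularyError as exc:
                raise VocabularyError(f"{path}:{lineno}: {exc}") from None
            rows.append((lineno, sub))
    if header is None:
        raise VocabularyError(f"{path}: missing header row")
    if not rows:
        raise VocabularyError("empty vocabulary")
    seen: dict[int, int] = {}
    for lineno, sub in rows:
        if sub.index in seen:
            raise VocabularyError(
                f"{path}:{lineno}: duplicate index {sub.index} "
                f"(first used on line {seen[sub.index]})"
            )
        seen[sub.index] = lineno
    ordered = sorted((sub for _, sub in rows), key=lambda s: s.index)
    expected = list(range(len(ordered)))
    if [s.index for s in ordered] != expected:
        raise VocabularyError(f"{path}: indices are not contiguous 0..n-1")
    return Vocabulary(tuple(ordered))


def _chain_pattern(length: int, bond_pos: int | None = None,
                   bond: str = "-") -> tuple[str, str]:
    """SMARTS and SMILES for a carbon chain with one optional multiple bond.

    ``bond_pos`` is the 1-based bond position along the chain.
    """
    atoms = [_CAP] + [_MID] * (length - 2) + [_CAP]
    bonds = ["-"] * (length - 1)
    if bond_pos is not None:
        bonds[bond_pos - 1] = bond
    smarts = atoms[0] + "".join(b + a for a, b in zip(atoms[1:], bonds))
    smiles = "C" + "".join(("" if b == "-" else b) + "C" for b in bonds)
    return smarts, smiles


def default_backbone_vocabulary() -> Vocabulary:
    """The 27-pattern default carbon-backbone set.

    Linear chains of 3-6 carbons, all single bonds (4); chains of 3-6
    carbons with exactly one double bond, positions unique under chain
    reversal (8); the same with one triple bond (8); saturated rings of
    3-6 members (4); benzene (1); cyclopentene and cyclohexene (2).

    Chain patterns match maximal non-ring aliphatic carbon runs: a chain
    of length L only matches runs of exactly L carbons, so no default
    pattern is contained in another and :func:`prune_contained` leaves
    the set unchanged.
    """
    entries: list[Substructure] = []

    def add(name: str, smarts: str, smiles: str) -> None:
        entries.append(Substructure(
            index=len(entries), name=name, smarts=smarts,
            smiles=smiles, kind=CARBON_BACKBONE,
        ))

    for length in range(3, 7):
        smarts, smiles = _chain_pattern(length)
        add(f"chain-C{length}", smarts, smiles)
    for bond, tag in (("=", "ene"), ("#", "yne")):
        for length in range(3, 7):
            n_bonds = length - 1
            seen: set[frozenset[int]] = set()
            for pos in range(1, n_bonds + 1):
                key = frozenset({pos, n_bonds + 1 - pos})
                if key in seen:
                    continue
                seen.add(key)
                smarts, smiles = _chain_pattern(length, pos, bond)
                add(f"chain-C{length}-{tag}-{pos}", smarts, smiles)
    for size, name in ((3, "cyclopropane"), (4, "cyclobutane"),
                       (5, "cyclopentane"), (6, "cyclohexane")):
        smiles = "C1" + "C" * (size - 2) + "C1"
        add(name, smiles, smiles)
    add("benzene", "c1ccccc1", "c1ccccc1")
    add("cyclopentene", "C1=CCCC1", "C1=CCCC1")
    add("cyclohexene", "C1=CCCCC1", "C1=CCCCC1")
    return Vocabulary(tuple(entries))


def default_functional_groups() -> Vocabulary:
    """The curated starter set of common functional groups shipped in-repo."""
    ref = resources.files("svmfp.data").joinpath("functional_groups.tsv")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)


def default_vocabulary() -> Vocabulary:
    """Functional groups followed by the 27 default backbones."""
    return Vocabulary.from_entries(
        list(default_functional_groups()) + list(default_backbone_vocabulary())
    )


def pattern_contained(inner: Substructure, outer: Substructure) -> bool:
    """True if ``inner``'s query matches into ``outer``'s structure."""
    return outer.structure().HasSubstructMatch(inner.query())


def prune_contained(vocab: Vocabulary) -> Vocabulary:
    """Drop carbon-backbone entries contained in a larger entry.

    A backbone entry A is removed when some other entry B contains A
    (A's query matches into B's structure) but A does not contain B.
    Functional groups are never removed.  Containment is evaluated on
    the original entry set, so the operation is idempotent.
    """
    keep: list[Substructure] = []
    for sub in vocab:
        if not sub.is_backbone:
            keep.append(sub)
            continue
        contained = any(
            other is not sub
            and pattern_contained(sub, other)
            and not pattern_contained(other, sub)
            for other in vocab
        )
        if not contained:
            keep.append(sub)
    return Vocabulary.from_entries(keep)


#: Expansion fragments per heteroatom used by the candidate enumerator.
#: Each fragment is the core element followed by fully parenthesised
#: branches, so fragments concatenate into linear chain SMILES.
HETEROATOM_SUBSTITUTIONS: dict[str, tuple[str, ...]] = {
    "O": ("O",),
    "S": ("S", "S(=O)", "S(=O)(=O)"),
    "N": ("N", "N(=O)(=O)"),
    "B": ("B",),
    "P": ("P", "P(=O)"),
    "C": ("C",),
}

_CHAIN_ELEMENTS = ("C", "O", "S", "N", "B", "P")


def enumerate_functional_group_candidates(
    max_chain_len: int = 5,
) -> list[Substructure]:
    """Enumerate candidate functional-group patterns.

    Connected chains of 2..``max_chain_len`` atoms over C/O/S/N/B/P with
    at least one heteroatom, each heteroatom optionally expanded with
    the fragments in :data:`HETEROATOM_SUBSTITUTIONS` (for example
    S -> sulfoxide, sulfone).  Chains are deduplicated under reversal
    and by canonical SMILES; chemically invalid expansions are skipped.
    Attachment points are implicit single bonds to carbon.
    """
    if not 2 <= max_chain_len <= 5:
        raise ValueError("max_chain_len must be in [2, 5]")
    seqs: set[tuple[str, ...]] = set()
    for length in range(2, max_chain_len + 1):
        for seq in itertools.product(_CHAIN_ELEMENTS, repeat=length):
            if all(e == "C" for e in seq):
                continue
            if tuple(reversed(seq)) in seqs:
                continue
            seqs.add(seq)
    seen_canon: set[str] = set()
    out: list[Substructure] = []
    for seq in sorted(seqs):
        options = [HETEROATOM_SUBSTITUTIONS[e] for e in seq]
        for combo in itertools.product(*options):
            smiles = "".join(combo)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen_canon:
                continue
            seen_canon.add(canon)
            out.append(Substructure(
                index=len(out), name=f"candidate:{canon}",
                smarts=canon, smiles=canon, kind=FUNCTIONAL_GROUP,
            ))
    return out
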