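"""Synthetic molecules, analog benchmark sets, Markush structures, layouts.

Everything the retrieval benchmarks need is generated here, offline and
seed-deterministic:

* drug-like molecules (ring scaffolds + linkers + substituents,
  15-40 heavy atoms by default);
* analog sets: near-duplicate distractors built by small random graph
  edits of a reference, kept only when a path-fingerprint Tanimoto
  similarity to the reference stays above a threshold (default 0.90) —
  the offline stand-in for sampling high-similarity neighbours from a
  large compound database;
* Markush structures as CXSMILES with R-group labels;
* perturbed 2D layouts emulating depiction variability (rotation,
  scaling, jitter).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, rdDepictor

from .fingerprint import SVMF, SVMFConfig
from .pipeline import fingerprint_smiles
from .vocabulary import Vocabulary

RDLogger.DisableLog("rdApp.error")

#: Path length of the binary fingerprint used for the similarity filter.
#: Short enough that single-atom edits on drug-sized references can stay
#: above a 0.90 Tanimoto, long enough to separate unrelated scaffolds.
SIMILARITY_FP_MAX_PATH = 5


class SynthesisError(RuntimeError):
    pass


def _path_fp(mol: Chem.Mol):
    return Chem.RDKFingerprint(mol, maxPath=SIMILARITY_FP_MAX_PATH)


def tanimoto_to_reference(reference: str, smiles: str) -> float:
    """Tanimoto similarity of the filter fingerprints of two SMILES."""
    ref = Chem.MolFromSmiles(reference)
    mol = Chem.MolFromSmiles(smiles)
    if ref is None or mol is None:
        raise SynthesisError("unparseable SMILES")
    return DataStructs.TanimotoSimilarity(_path_fp(ref), _path_fp(mol))


# ---------------------------------------------------------------------------
# drug-like molecule generator

_SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1",
    "c1cc[nH]n1", "c1cnc[nH]1", "C1CCCCC1", "C1CCNCC1", "C1CNCCN1",
    "C1COCCN1", "C1CCNC1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
)

# (smiles, attachment atom a, attachment atom b)
_LINKERS = (
    ("C", 0, 0), ("CC", 0, 1), ("CCC", 0, 2),
    ("C(=O)N", 0, 2), ("C(=O)O", 0, 2), ("O", 0, 0), ("N", 0, 0),
    ("S(=O)(=O)N", 0, 3), ("OC", 0, 1), ("NC(=O)C", 0, 3),
)

# attachment point is always atom 0
_SUBSTITUENTS = (
    "F", "Cl", "Br", "O", "OC", "N", "NC", "N(C)C", "C", "CC", "C(C)C",
    "C#N", "C(=O)O", "C(=O)N", "C(F)(F)F", "S(=O)(=O)C", "OCC", "CO",
)


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() > 1 and a.GetTotalNumHs() > 0
    ]


def _attach(
    core: Chem.Mol, frag_smiles: str, core_idx: int, frag_idx: int = 0
) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    combo.AddBond(
        core_idx, core.GetNumAtoms() + frag_idx, Chem.BondType.SINGLE
    )
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_druglike(
    n: int,
    seed: int,
    min_heavy: int = 15,
    max_heavy: int = 40,
    max_attempts_per_molecule: int = 200,
) -> list[str]:
    """Generate ``n`` unique drug-like molecules as canonical SMILES.

    Each molecule is one or two ring scaffolds joined by a linker and
    decorated with common medicinal-chemistry substituents until its
    heavy-atom count falls in [min_heavy, max_heavy].
    """
    rng = random.Random(seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        smiles = None
        for _ in range(max_attempts_per_molecule):
            smiles = _random_druglike(rng, min_heavy, max_heavy)
            if smiles is not None and smiles not in seen:
                break
            smiles = None
        if smiles is None:
            raise SynthesisError(
                f"could not generate molecule {len(out) + 1} of {n}"
            )
        seen.add(smiles)
        out.append(smiles)
    return out


def _random_druglike(
    rng: random.Random, min_heavy: int, max_heavy: int
) -> str | None:
    mol = Chem.MolFromSmiles(rng.choice(_SCAFFOLDS))
    # usually bridge in a second ring system
    if rng.random() < 0.8:
        linker, a_idx, b_idx = rng.choice(_LINKERS)
        second = rng.choice(_SCAFFOLDS)
        sites = _free_valence_atoms(mol)
        if sites:
            with_linker = _attach(mol, linker, rng.choice(sites))
            if with_linker is not None:
                link_b = mol.GetNumAtoms() + b_idx
                frag = Chem.MolFromSmiles(second)
                ring_sites = [
                    i for i in _free_valence_atoms(frag)
                ]
                if ring_sites:
                    combo = Chem.RWMol(Chem.CombineMols(with_linker, frag))
                    combo.AddBond(
                        link_b,
                        with_linker.GetNumAtoms() + rng.choice(ring_sites),
                        Chem.BondType.SINGLE,
                    )
                    try:
                        candidate = combo.GetMol()
                        Chem.SanitizeMol(candidate)
                        mol = candidate
                    except Exception:
                        pass
    for _ in range(rng.randint(2, 6)):
        if mol.GetNumHeavyAtoms() >= max_heavy:
            break
        sites = _free_valence_atoms(mol)
        if not sites:
            break
        grown = _attach(mol, rng.choice(_SUBSTITUENTS), rng.choice(sites))
        if grown is not None:
            mol = grown
    if not min_heavy <= mol.GetNumHeavyAtoms() <= max_heavy:
        return None
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# analog sets

@dataclass(frozen=True)
class AnalogSetSpec:
    """Parameters of an analog benchmark set.

    Defaults mirror the published retrieval protocol: 500 analogs per
    reference at >= 0.90 similarity.
    """

    reference: str
    n_analogs: int = 500
    similarity_threshold: float = 0.90
    seed: int = 0
    max_edits: int = 2
    max_attempts: int | None = None

    def __post_init__(self) -> None:
        if self.n_analogs < 1:
            raise ValueError("n_analogs must be >= 1")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.max_edits < 0:
            raise ValueError("max_edits must be >= 0")


def _edit_add_substituent(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    sites = _free_valence_atoms(mol)
    if not sites:
        return None
    return _attach(mol, rng.choice(_SUBSTITUENTS), rng.choice(sites))


def _edit_halogenate(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    sites = [
        i for i in _free_valence_atoms(mol)
        if mol.GetAtomWithIdx(i).GetAtomicNum() == 6
    ]
    if not sites:
        return None
    return _attach(mol, rng.choice(("F", "Cl")), rng.choice(sites))


def _edit_remove_terminal(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    terminals = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetDegree() == 1 and not a.IsInRing()
    ]
    if not terminals or mol.GetNumHeavyAtoms() <= 4:
        return None
    editable = Chem.RWMol(mol)
    editable.RemoveAtom(rng.choice(terminals))
    try:
        out = editable.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _edit_swap_heteroatom(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    candidates = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8, 16) and a.GetFormalCharge() == 0
    ]
    if not candidates:
        return None
    idx = rng.choice(candidates)
    editable = Chem.RWMol(mol)
    atom = editable.GetAtomWithIdx(idx)
    current = atom.GetAtomicNum()
    targets = [z for z in (7, 8, 16) if z != current]
    target = rng.choice(targets)
    if target in (8, 16) and atom.GetDegree() > 2:
        return None
    atom.SetAtomicNum(target)
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    try:
        out = editable.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _edit_homologate(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    bonds = [
        b for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() == 6
        and b.GetEndAtom().GetAtomicNum() == 6
    ]
    if not bonds:
        return None
    bond = rng.choice(bonds)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    editable = Chem.RWMol(mol)
    new_c = editable.AddAtom(Chem.Atom(6))
    editable.RemoveBond(a, b)
    editable.AddBond(a, new_c, Chem.BondType.SINGLE)
    editable.AddBond(new_c, b, Chem.BondType.SINGLE)
    try:
        out = editable.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


_EDITS = (
    _edit_add_substituent,
    _edit_halogenate,
    _edit_remove_terminal,
    _edit_swap_heteroatom,
    _edit_homologate,
)


def generate_analog_set(
    spec: AnalogSetSpec,
    accept: "callable | None" = None,
) -> list[str]:
    """Build a set of unique analogs of the reference molecule.

    Each analog is the product of at most ``max_edits`` random edits
    (substituent add/remove, N/O/S swap, chain homologation, halogen
    decoration) and passes the similarity filter against the reference.
    ``accept``, when given, is an extra predicate on the candidate
    canonical SMILES evaluated after all built-in filters.
    Deterministic for a fixed seed.  Raises :class:`SynthesisError`
    reporting the achieved count when the attempt budget runs out.
    """
    reference = Chem.MolFromSmiles(spec.reference)
    if reference is None:
        raise SynthesisError(f"unparseable reference {spec.reference!r}")
    rng = random.Random(spec.seed)
    ref_fp = _path_fp(reference)
    ref_canon = Chem.MolToSmiles(reference)
    budget = spec.max_attempts
    if budget is None:
        budget = 1000 + 200 * spec.n_analogs
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < spec.n_analogs and attempts < budget:
        attempts += 1
        if spec.max_edits == 0:
            candidate: Chem.Mol | None = reference
        else:
            candidate = reference
            for _ in range(rng.randint(1, spec.max_edits)):
                edit = rng.choice(_EDITS)
                edited = edit(candidate, rng)
                if edited is not None:
                    candidate = edited
            if candidate is reference:
                candidate = None
        if candidate is None:
            continue
        smiles = Chem.MolToSmiles(candidate)
        if smiles in seen:
            continue
        if smiles != ref_canon:
            sim = DataStructs.TanimotoSimilarity(ref_fp, _path_fp(candidate))
            if sim < spec.similarity_threshold:
                continue
        if accept is not None and not accept(smiles):
            continue
        seen.add(smiles)
        out.append(smiles)
    if len(out) < spec.n_analogs:
        raise SynthesisError(
            f"only generated {len(out)} of {spec.n_analogs} analogs within "
            f"{budget} attempts"
        )
    return out


def generate_analog_benchmark(
    spec: AnalogSetSpec,
    vocab: Vocabulary,
    cfg: SVMFConfig | None = None,
) -> list[str]:
    """Analog set whose members have pairwise-distinct ground-truth SVMFs.

    The self-query retrieval benchmark asks at which rank a molecule's
    own fingerprint retrieves it; that question is only well-posed when
    the dataset entries are distinguishable by the representation being
    ranked.  Positional isomers can share identical class counts and
    instance distances — and therefore identical fingerprints — so this
    builder additionally rejects candidates whose topological SVMF
    duplicates one already accepted.
    """
    seen_fps: set[tuple] = set()

    def distinct_fingerprint(smiles: str) -> bool:
        fp = fingerprint_smiles(smiles, vocab, cfg, mode="topological")
        key = tuple(fp.flatten())
        if key in seen_fps:
            return False
        seen_fps.add(key)
        return True

    return generate_analog_set(spec, accept=distinct_fingerprint)


# ---------------------------------------------------------------------------
# Markush structures

def generate_markush(smiles: str, seed: int) -> str:
    """Turn a molecule into a Markush CXSMILES with 1-3 R-group labels.

    Operations: replace a terminal atom with an R-group placeholder, or
    attach a new R-group to a ring atom.  The output round-trips through
    the CXSMILES reader with the R atoms flagged as placeholders.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SynthesisError(f"unparseable SMILES {smiles!r}")
    if mol.GetRingInfo().NumRings() == 0 and mol.GetNumHeavyAtoms() < 3:
        raise SynthesisError("molecule too small for Markush construction")
    rng = random.Random(seed)
    editable = Chem.RWMol(mol)
    n_ops = rng.randint(1, 3)
    applied = 0
    for _ in range(n_ops):
        ops = ["replace_terminal", "attach_ring"]
        rng.shuffle(ops)
        done = False
        for op in ops:
            if op == "replace_terminal":
                terminals = [
                    a.GetIdx() for a in editable.GetAtoms()
                    if a.GetDegree() == 1 and not a.IsInRing()
                    and a.GetAtomicNum() > 0
                ]
                if not terminals:
                    continue
                idx = rng.choice(terminals)
                atom = editable.GetAtomWithIdx(idx)
                atom.SetAtomicNum(0)
                atom.SetFormalCharge(0)
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(True)
                atom.SetProp("atomLabel", f"R{applied + 1}")
                done = True
            else:
                ring_sites = [
                    a.GetIdx() for a in editable.GetAtoms()
                    if a.IsInRing() and a.GetTotalNumHs() > 0
                ]
                if not ring_sites:
                    continue
                site = rng.choice(ring_sites)
                dummy = Chem.Atom(0)
                dummy.SetProp("atomLabel", f"R{applied + 1}")
                new_idx = editable.AddAtom(dummy)
                editable.AddBond(site, new_idx, Chem.BondType.SINGLE)
                done = True
            if done:
                applied += 1
                break
    if applied == 0:
        raise SynthesisError("no applicable Markush site")
    out = editable.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToCXSmiles(out)


# ---------------------------------------------------------------------------
# layout perturbation

def perturb_layout(
    coords: Sequence[tuple[float, float]],
    seed: int,
    magnitude: float,
    rotate: bool = True,
) -> list[tuple[float, float]]:
    """Randomly rotate, rescale and jitter a 2D layout about its centroid.

    Scale is uniform in [1 - magnitude, 1 + magnitude]; per-atom jitter
    has radius at most magnitude x the median nearest-neighbour
    distance (a bond-length proxy available from coordinates alone).
    ``magnitude`` 0 leaves a rigid rotation only; ``rotate=False`` as
    well gives the identity.  Deterministic per seed.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0:
        return []
    rng = np.random.default_rng(seed)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    angle = rng.uniform(0.0, 2.0 * math.pi) if rotate else 0.0
    cos_a, sin_a = math.cos(angle), math.sin(angle)
    rot = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
    scale = rng.uniform(1.0 - magnitude, 1.0 + magnitude)
    moved = centered @ rot.T * scale
    if magnitude > 0 and len(pts) > 1:
        diffs = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diffs[..., 0], diffs[..., 1])
        np.fill_diagonal(dist, np.inf)
        bond_proxy = float(np.median(dist.min(axis=1)))
        radii = rng.uniform(0.0, magnitude * bond_proxy, size=len(pts))
        angles = rng.uniform(0.0, 2.0 * math.pi, size=len(pts))
        moved = moved + np.stack(
            [radii * np.cos(angles), radii * np.sin(angles)], axis=1
        )
    moved = moved + centroid
    return [(float(x), float(y)) for x, y in moved]


def fingerprint_from_cxsmiles(
    cxsmiles: str,
    vocab: Vocabulary,
    cfg: SVMFConfig | None = None,
) -> SVMF:
    """Ground-truth topological fingerprint of a SMILES/CXSMILES string.

    R-group placeholder atoms are excluded from matching, so adding an
    R label outside every matched substructure leaves the fingerprint
    unchanged.
    """
    return fingerprint_smiles(cxsmiles, vocab, cfg, mode="topological")
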