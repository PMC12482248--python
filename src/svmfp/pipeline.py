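"""End-to-end fingerprinting pipelines.

Composes matching, backbone suppression, graph construction and the
fingerprint computation.  Two modes mirror the two graph routes:
``topological`` works on the molecular graph alone, ``geometric`` goes
through depiction coordinates and bounding boxes (the route an image
detector feeds).
"""

from __future__ import annotations

from rdkit.Chem import rdDepictor

from .fingerprint import SVMF, SVMFConfig, compute_svmf
from .graphbuild import build_graph_geometric, build_graph_topological
from .matching import (
    MatchingError,
    MoleculeRecord,
    instances_to_boxes,
    match_substructures,
    suppress_redundant_backbones,
)
from .vocabulary import Vocabulary

MODES = ("topological", "geometric")


def ensure_coords(mol: MoleculeRecord) -> MoleculeRecord:
    """Populate coords2d from a computed 2D depiction if absent."""
    if mol.coords2d is not None:
        return mol
    rd = mol.require_rdmol()
    rdDepictor.Compute2DCoords(rd)
    conf = rd.GetConformer()
    mol.coords2d = [
        (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
        for i in range(rd.GetNumAtoms())
    ]
    return mol


def fingerprint_molecule(
    mol: MoleculeRecord,
    vocab: Vocabulary,
    cfg: SVMFConfig | None = None,
    mode: str = "topological",
    fraction: float = 0.10,
    atom_pad: float | None = None,
) -> SVMF:
    """Match, suppress redundant backbones, build the graph, fingerprint."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    cfg = cfg or SVMFConfig()
    instances = suppress_redundant_backbones(match_substructures(mol, vocab))
    if mode == "topological":
        graph = build_graph_topological(instances, mol)
    else:
        if mol.coords2d is None:
            ensure_coords(mol)
        boxed = instances_to_boxes(instances, mol, atom_pad=atom_pad)
        graph = build_graph_geometric(boxed, fraction=fraction)
    return compute_svmf(graph, vocab, cfg)


def fingerprint_smiles(
    smiles: str,
    vocab: Vocabulary,
    cfg: SVMFConfig | None = None,
    mode: str = "topological",
    **kwargs,
) -> SVMF:
    """Fingerprint a SMILES or CXSMILES string."""
    mol = MoleculeRecord.from_smiles(smiles)
    return fingerprint_molecule(mol, vocab, cfg, mode=mode, **kwargs)
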