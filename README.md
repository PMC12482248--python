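# svmfp

Substructure-based visual molecular fingerprints for molecule and
Markush-structure retrieval.

Patent and literature chemistry mining needs a molecular representation
that can be computed from what a detector sees in a depiction — the
functional groups and carbon skeleton — rather than from a fully
resolved connection table.  `svmfp` implements such a representation: a
sparse, count-based, continuous fingerprint built from substructure
instances and their arrangement, together with the matching, graph
construction, retrieval and benchmark tooling around it.  It is aimed at
cheminformaticians working on chemical structure search, optical
chemical structure recognition (OCSR) post-processing, and
patent-chemistry (Markush) retrieval.

## The fingerprint

A vocabulary of *n* substructures — functional groups (patterns with at
least one heteroatom) and carbon backbones (all-carbon chain and ring
patterns) — indexes an *n* × *n* upper-triangular matrix.  For a
molecule *m*, every occurrence of a vocabulary substructure becomes an
instance; instances form a *substructure graph* whose edges are overlaps
(shared atoms / bonded atoms, or intersecting bounding boxes when
working from a 2D layout).  With n_i the number of instances of class
*i* and d(i_α, j_β) the number of intermediate instances on the shortest
path between two instances, the matrix entries are

    f_ii = h1 · n_i + g_ii                        (diagonal)
    g_ij = Σ_{α,β} w(i_α, j_β) · h2(d(i_α, j_β))  (off-diagonal)

with h1 = 10, h2(d) = 2, 2, 2/4, 2/16, 2/256 for d = 0…4 and 0 beyond,
and w = 1/2 when either instance is a carbon backbone (functional groups
carry more identity than generic scaffolding).  Sums run over unordered
instance pairs, self-pairs excluded.  Only non-zero coefficients are
stored, as a sparse vector over the flattened index space of length
n² (2,436,721 for the full 1561-slot space: 1534 functional groups +
27 carbon backbones).

Two fingerprints are compared with the normalized Euclidean measure

    s(f1, f2) = ‖f1 − f2‖ / ‖f1 + f2‖  ∈ [0, 1],

which is 0 exactly for identical fingerprints and 1 for disjoint
supports; retrieval ranks a collection by *s* ascending.

## Worked example

```python
import svmfp

vocab = svmfp.default_vocabulary()          # 101 functional groups + 27 backbones
fp = svmfp.fingerprint_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O", vocab)  # ibuprofen
print(f"n = {fp.n}, non-zero coefficients = {fp.nnz}")
for (i, j), value in sorted(fp.entries.items()):
    print(f"  ({vocab[i].name}, {vocab[j].name}) = {value}")
```

prints

```
n = 128, non-zero coefficients = 10
  (hydroxyl, hydroxyl) = 10.0
  (hydroxyl, carboxylic-acid) = 2.0
  (hydroxyl, chain-C3) = 1.5625
  (hydroxyl, benzene) = 1.0
  (carboxylic-acid, carboxylic-acid) = 10.0
  (carboxylic-acid, chain-C3) = 1.5625
  (carboxylic-acid, benzene) = 1.0
  (chain-C3, chain-C3) = 45.25
  (chain-C3, benzene) = 4.0
  (benzene, benzene) = 10.0
```

Ibuprofen contains one carboxylic acid (whose O–H also matches the
hydroxyl pattern), six 3-carbon chain instances over its branched
aliphatic part, and a benzene ring: diagonal entries are 10 × count
plus same-class intersections (the large chain-C3 self term), and
off-diagonal entries decay with the instance distance, halved for the
backbone-involving pairs.  Comparing against its methyl ester gives
`svmf_distance = 0.1895` — close, but not identical.

The same pipeline is available from the shell:

```bash
svmfp fingerprint --in molecules.smi --out fps.jsonl
svmfp search --query "CC(=O)Oc1ccccc1C(=O)O" --db fps.jsonl
svmfp synth analogs --reference "<SMILES>" --n 100 --seed 7 --out analogs.smi
svmfp benchmark --config run.yaml --reference "<SMILES>" --out metrics.json
```

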