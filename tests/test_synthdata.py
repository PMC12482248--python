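import math
import statistics

import pytest
from rdkit import Chem

from conftest import REFERENCE_SMILES

import svmfp
from svmfp.matching import MoleculeRecord, match_substructures, \
    suppress_redundant_backbones, instances_to_boxes
from svmfp.graphbuild import build_graph_geometric, build_graph_topological
from svmfp.pipeline import ensure_coords
from svmfp.synthdata import (
    AnalogSetSpec,
    SynthesisError,
    fingerprint_from_cxsmiles,
    generate_analog_benchmark,
    generate_analog_set,
    generate_druglike,
    generate_markush,
    perturb_layout,
    tanimoto_to_reference,
)


class TestDruglikeGenerator:
    def test_count_validity_and_size_range(self):
        mols = generate_druglike(30, seed=5, min_heavy=15, max_heavy=40)
        assert len(mols) == len(set(mols)) == 30
        for smi in mols:
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            assert 15 <= mol.GetNumHeavyAtoms() <= 40

    def test_seed_determinism(self):
        assert generate_druglike(10, seed=3) == generate_druglike(10, seed=3)
        assert generate_druglike(10, seed=3) != generate_druglike(10, seed=4)


class TestAnalogSet:
    def test_zero_edits_returns_reference(self):
        spec = AnalogSetSpec(
            reference=REFERENCE_SMILES, n_analogs=1, max_edits=0, seed=1
        )
        assert generate_analog_set(spec) == [
            Chem.CanonSmiles(REFERENCE_SMILES)
        ]

    def test_outputs_parse_and_meet_threshold(self):
        spec = AnalogSetSpec(
            reference=REFERENCE_SMILES, n_analogs=25, seed=2, max_edits=2
        )
        analogs = generate_analog_set(spec)
        assert len(analogs) == len(set(analogs)) == 25
        ref_canon = Chem.CanonSmiles(REFERENCE_SMILES)
        for smi in analogs:
            assert Chem.MolFromSmiles(smi) is not None
            if smi != ref_canon:
                assert tanimoto_to_reference(REFERENCE_SMILES, smi) >= 0.90

    def test_seed_fixed_run_is_bit_identical(self):
        spec = AnalogSetSpec(
            reference=REFERENCE_SMILES, n_analogs=10, seed=9, max_edits=2
        )
        assert generate_analog_set(spec) == generate_analog_set(spec)

    def test_budget_exhaustion_reports_achieved_count(self):
        spec = AnalogSetSpec(
            reference="C1CC1",  # tiny: single edits crater the similarity
            n_analogs=50, seed=4, max_edits=1, max_attempts=60,
        )
        with pytest.raises(SynthesisError, match=r"\d+ of 50"):
            generate_analog_set(spec)

    def test_benchmark_variant_has_distinct_fingerprints(self, full_vocab):
        spec = AnalogSetSpec(
            reference=REFERENCE_SMILES, n_analogs=15, seed=6, max_edits=2
        )
        analogs = generate_analog_benchmark(spec, full_vocab)
        fps = [
            tuple(svmfp.fingerprint_smiles(s, full_vocab).flatten())
            for s in analogs
        ]
        assert len(set(fps)) == len(fps) == 15


class TestMarkush:
    def test_benzene_gets_ring_rgroup(self):
        cx = generate_markush("c1ccccc1", seed=1)
        assert "R1" in cx
        mol = Chem.MolFromSmiles(cx)
        assert mol is not None
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        assert len(dummies) >= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_output_always_carries_rgroup(self, seed):
        cx = generate_markush("CC(C)Cc1ccc(cc1)C(C)C(=O)O", seed=seed)
        mol = Chem.MolFromSmiles(cx)
        assert any(a.GetAtomicNum() == 0 for a in mol.GetAtoms())

    def test_too_small_molecule_rejected(self):
        with pytest.raises(SynthesisError):
            generate_markush("CC", seed=0)

    def test_rgroup_outside_matches_leaves_fingerprint_unchanged(
        self, full_vocab
    ):
        # toluene's methyl carbon sits in no matched substructure, so
        # replacing it with an R label must not change the fingerprint
        plain = svmfp.fingerprint_smiles("Cc1ccccc1", full_vocab)
        markush = fingerprint_from_cxsmiles("*c1ccccc1 |$R1;;;;;;$|", full_vocab)
        assert markush == plain


class TestFingerprintFromCxsmiles:
    def test_plain_smiles_equals_standard_path(self, full_vocab):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        assert fingerprint_from_cxsmiles(smi, full_vocab) == \
            svmfp.fingerprint_smiles(smi, full_vocab)

    def test_empty_match_molecule_gives_empty_fingerprint(self, full_vocab):
        assert fingerprint_from_cxsmiles("O", full_vocab).nnz == 0

    def test_parse_failure(self, full_vocab):
        with pytest.raises(ValueError):
            fingerprint_from_cxsmiles("not-a-molecule", full_vocab)


class TestPerturbLayout:
    COORDS = [(0.0, 0.0), (1.5, 0.0), (3.0, 0.2), (1.0, 2.0)]

    def test_identity_at_zero_magnitude_without_rotation(self):
        out = perturb_layout(self.COORDS, seed=1, magnitude=0.0, rotate=False)
        assert out == pytest.approx(self.COORDS)

    def test_rigid_at_zero_magnitude(self):
        out = perturb_layout(self.COORDS, seed=1, magnitude=0.0)
        for (a, b) in [(0, 1), (1, 2), (0, 3), (2, 3)]:
            assert math.dist(out[a], out[b]) == pytest.approx(
                math.dist(self.COORDS[a], self.COORDS[b])
            )

    def test_deterministic_per_seed(self):
        a = perturb_layout(self.COORDS, seed=5, magnitude=0.2)
        b = perturb_layout(self.COORDS, seed=5, magnitude=0.2)
        c = perturb_layout(self.COORDS, seed=6, magnitude=0.2)
        assert a == b
        assert a != c

    def test_graph_routes_agree_at_small_magnitude(self, full_vocab):
        # the geometric route reproduces most topological links under a
        # mild layout perturbation (and exactly, for compact fused
        # systems like caffeine); a perfect match is not expected since
        # box expansion is deliberately small
        jaccards = []
        for smi in ("Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
                    "CC(=O)Oc1ccccc1C(=O)O",       # aspirin
                    "CC(=O)Nc1ccc(O)cc1"):         # paracetamol
            rec = MoleculeRecord.from_smiles(smi)
            ensure_coords(rec)
            inst = suppress_redundant_backbones(
                match_substructures(rec, full_vocab)
            )
            topo = build_graph_topological(inst, rec).edges
            rec.coords2d = perturb_layout(rec.coords2d, seed=3, magnitude=0.1)
            geo = build_graph_geometric(
                instances_to_boxes(inst, rec)
            ).edges
            union = topo | geo
            jaccards.append(
                1.0 if not union else len(topo & geo) / len(union)
            )
        assert min(jaccards) >= 0.5
        assert max(jaccards) == 1.0


class TestRetrievalEndToEnd:
    def test_self_query_mean_rank_and_perturbed_median(self, full_vocab):
        cfg = svmfp.SVMFConfig()
        spec = AnalogSetSpec(
            reference=REFERENCE_SMILES, n_analogs=40, seed=7, max_edits=2
        )
        analogs = generate_analog_benchmark(spec, full_vocab, cfg)
        dataset = [
            (f"a{i}", svmfp.fingerprint_smiles(s, full_vocab, cfg))
            for i, s in enumerate(analogs)
        ]
        queries = [(fp, mol_id) for mol_id, fp in dataset]
        assert svmfp.mean_rank(queries, dataset) == 1.0
        geo = []
        for i, smi in enumerate(analogs):
            rec = MoleculeRecord.from_smiles(smi, f"a{i}")
            ensure_coords(rec)
            rec.coords2d = perturb_layout(
                rec.coords2d, seed=1000 + i, magnitude=0.1
            )
            geo.append((
                f"a{i}",
                svmfp.fingerprint_molecule(
                    rec, full_vocab, cfg, mode="geometric"
                ),
            ))
        ranks = svmfp.retrieval.per_query_ranks(queries, geo)
        assert statistics.median(ranks) <= 5
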