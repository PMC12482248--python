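import itertools
import math
import random

import pytest

from svmfp.graphbuild import (
    INFINITE,
    GraphBuildError,
    SubstructureGraph,
    build_graph_geometric,
    build_graph_topological,
    expand_boxes,
    instance_distance,
)
from svmfp.matching import AtomRecord, MoleculeRecord, SubstructureInstance


def boxed(index, box, backbone=False):
    return SubstructureInstance(
        substructure_index=index, box=box, is_backbone=backbone
    )


class TestExpandBoxes:
    def test_hand_computed_margin(self):
        # diagonal of (0,0,3,4) is 5; 10% margin = 0.5 on each side
        (out,) = expand_boxes([boxed(0, (0.0, 0.0, 3.0, 4.0))], 0.10)
        assert out.box == pytest.approx((-0.5, -0.5, 3.5, 4.5))

    def test_fraction_zero_is_identity(self):
        instances = [boxed(0, (1.0, 2.0, 3.0, 4.0)), boxed(1, (0.0, 0.0, 1.0, 1.0))]
        assert [i.box for i in expand_boxes(instances, 0.0)] == [
            i.box for i in instances
        ]

    def test_margin_from_smallest_box_applies_to_all(self):
        big = boxed(0, (0.0, 0.0, 30.0, 40.0))
        small = boxed(1, (0.0, 0.0, 3.0, 4.0))
        out = expand_boxes([big, small], 0.10)
        # both grown by 10% of the SMALL diagonal (0.5), not their own
        assert out[0].box == pytest.approx((-0.5, -0.5, 30.5, 40.5))
        assert out[1].box == pytest.approx((-0.5, -0.5, 3.5, 4.5))

    def test_empty_list_ok(self):
        assert expand_boxes([], 0.10) == []


class TestGeometricGraph:
    def test_corner_touch_after_expansion_is_an_edge(self):
        a = boxed(0, (0.0, 0.0, 1.0, 1.0))
        b = boxed(1, (1.2, 1.2, 2.2, 2.2))
        g = build_graph_geometric([a, b], fraction=0.10)
        assert g.edges == {(0, 1)}

    def test_far_apart_boxes_unlinked(self):
        a = boxed(0, (0.0, 0.0, 1.0, 1.0))
        b = boxed(1, (10.0, 10.0, 11.0, 11.0))
        assert build_graph_geometric([a, b], 0.10).edges == set()

    def test_collinear_boxes_form_path(self):
        # margin = 0.1 * sqrt(5) ~ 0.224 per box; gaps of 0.4 close,
        # the 2.8 gap between the outer boxes stays open
        instances = [
            boxed(i, (2.4 * i, 0.0, 2.4 * i + 2.0, 1.0)) for i in range(3)
        ]
        g = build_graph_geometric(instances, fraction=0.10)
        assert g.edges == {(0, 1), (1, 2)}

    def test_invariant_under_translation_and_scaling(self):
        rng = random.Random(5)
        for _ in range(20):
            instances = []
            for i in range(rng.randint(2, 8)):
                x, y = rng.uniform(-5, 5), rng.uniform(-5, 5)
                w, h = rng.uniform(0.2, 3), rng.uniform(0.2, 3)
                instances.append(boxed(i, (x, y, x + w, y + h)))
            base = build_graph_geometric(instances, 0.10).edges
            dx, dy, scale = rng.uniform(-50, 50), rng.uniform(-50, 50), 7.5
            moved = [
                boxed(i.substructure_index, (
                    scale * (i.box[0] + dx), scale * (i.box[1] + dy),
                    scale * (i.box[2] + dx), scale * (i.box[3] + dy),
                ))
                for i in instances
            ]
            assert build_graph_geometric(moved, 0.10).edges == base


class TestTopologicalGraph:
    def record(self, n_atoms, bonds):
        return MoleculeRecord(
            id="r",
            atoms=[AtomRecord("C") for _ in range(n_atoms)],
            bonds=[(a, b, 1.0) for a, b in bonds],
        )

    def inst(self, index, atoms):
        return SubstructureInstance(index, frozenset(atoms))

    def test_shared_atom_links(self):
        mol = self.record(4, [(0, 1), (1, 2), (2, 3)])
        g = build_graph_topological(
            [self.inst(0, {3}), self.inst(1, {1, 2, 3})], mol
        )
        assert g.edges == {(0, 1)}

    def test_disconnected_fragments_unlinked(self):
        mol = self.record(4, [(0, 1), (2, 3)])
        g = build_graph_topological(
            [self.inst(0, {0, 1}), self.inst(1, {2, 3})], mol
        )
        assert g.edges == set()

    def test_bonded_instances_link_without_shared_atom(self):
        mol = self.record(4, [(0, 1), (1, 2), (2, 3)])
        g = build_graph_topological(
            [self.inst(0, {0, 1}), self.inst(1, {2, 3})], mol
        )
        assert g.edges == {(0, 1)}

    def test_matches_brute_force_oracle(self):
        rng = random.Random(9)
        for _ in range(25):
            n = rng.randint(2, 10)
            bonds = [
                (a, b)
                for a in range(n) for b in range(a + 1, n)
                if rng.random() < 0.3
            ]
            mol = self.record(n, bonds)
            instances = [
                self.inst(i, rng.sample(range(n), rng.randint(1, min(3, n))))
                for i in range(rng.randint(2, 6))
            ]
            g = build_graph_topological(instances, mol)
            bondset = {frozenset(b) for b in bonds}
            for i, j in itertools.combinations(range(len(instances)), 2):
                ai, aj = instances[i].atom_indices, instances[j].atom_indices
                expect = bool(ai & aj) or any(
                    frozenset((u, v)) in bondset for u in ai for v in aj
                )
                assert ((i, j) in g.edges) == expect


class TestInstanceDistance:
    def graph(self, k, edges):
        nodes = [SubstructureInstance(i, frozenset()) for i in range(k)]
        return SubstructureGraph(nodes=nodes, edges=set(edges))

    def test_direct_edge_distance_zero(self):
        assert instance_distance(self.graph(2, {(0, 1)}), 0, 1) == 0

    def test_one_intermediate(self):
        g = self.graph(3, {(0, 2), (2, 1)})
        assert instance_distance(g, 0, 1) == 1

    def test_disconnected_infinite(self):
        assert instance_distance(self.graph(2, set()), 0, 1) == INFINITE

    def test_self_distance_undefined(self):
        with pytest.raises(GraphBuildError):
            instance_distance(self.graph(2, {(0, 1)}), 1, 1)

    def test_matches_exhaustive_path_enumeration(self):
        rng = random.Random(21)
        for _ in range(15):
            k = rng.randint(2, 7)
            edges = {
                (i, j)
                for i in range(k) for j in range(i + 1, k)
                if rng.random() < 0.35
            }
            g = self.graph(k, edges)
            for a in range(k):
                for b in range(a + 1, k):
                    best = math.inf
                    for length in range(2, k + 1):
                        for path in itertools.permutations(range(k), length):
                            if path[0] != a or path[-1] != b:
                                continue
                            ok = all(
                                (min(u, v), max(u, v)) in g.edges
                                for u, v in zip(path, path[1:])
                            )
                            if ok:
                                best = min(best, length - 2)
                        if best < math.inf:
                            break
                    assert instance_distance(g, a, b) == best

    def test_shifted_triangle_inequality(self):
        rng = random.Random(2)
        for _ in range(20):
            k = rng.randint(3, 9)
            edges = {
                (i, j)
                for i in range(k) for j in range(i + 1, k)
                if rng.random() < 0.4
            }
            g = self.graph(k, edges)
            for a, b, c in itertools.permutations(range(k), 3):
                dab = instance_distance(g, a, b)
                dbc = instance_distance(g, b, c)
                dac = instance_distance(g, a, c)
                if dab < INFINITE and dbc < INFINITE:
                    assert dac <= dab + dbc + 1
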