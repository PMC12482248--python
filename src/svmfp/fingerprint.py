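"""The sparse upper-triangular count-based fingerprint (SVMF).

For a molecule with substructure classes i, j and instance multisets
{i_a}, {j_b}, the fingerprint is an n x n upper-triangular matrix with

* diagonal      f_ii = h1 * n_i + g_ii
* off-diagonal  g_ij = sum over unordered instance pairs (a, b), a != b,
                 of w(a, b) * h2(d(a, b))

where n_i is the instance count of class i, d is the substructure-graph
distance (number of intermediate instances), h2 is a rapidly decaying
step table that is 0 beyond d_max, and w halves the contribution when
either endpoint is a carbon-backbone instance (functional groups carry
more identity than generic carbon scaffolding).  Only non-zero
coefficients are stored; the flattened index space has length n*n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .graphbuild import SubstructureGraph, all_pairs_distances
from .vocabulary import Vocabulary


class FingerprintError(ValueError):
    pass


def _default_h2() -> dict[int, float]:
    return {0: 2.0, 1: 2.0, 2: 0.5, 3: 0.125, 4: 0.0078125}


@dataclass
class SVMFConfig:
    """Hyper-parameters of the fingerprint.

    Defaults follow the published configuration: h1 = 10, h2(d) = 2, 2,
    2/4, 2/16, 2/256 for d = 0..4 (0 beyond), backbone contributions
    halved.  ``n_slots`` fixes the matrix side length; leave ``None``
    to use the vocabulary size, or set 1561 to reserve the full
    published index space.
    """

    h1: float = 10.0
    h2_table: dict[int, float] = field(default_factory=_default_h2)
    d_max: int = 4
    backbone_factor: float = 0.5
    n_slots: int | None = None

    def __post_init__(self) -> None:
        if self.h1 <= 0:
            raise FingerprintError("h1 must be > 0")
        if not 0 < self.backbone_factor <= 1:
            raise FingerprintError("backbone_factor must be in (0, 1]")
        prev = math.inf
        for d in sorted(self.h2_table):
            v = self.h2_table[d]
            if v < 0:
                raise FingerprintError("h2 values must be >= 0")
            if v > prev:
                raise FingerprintError("h2 must be non-increasing in d")
            prev = v

    def h2(self, d: float) -> float:
        if d > self.d_max or d != int(d):
            return 0.0
        return self.h2_table.get(int(d), 0.0)

    def side_length(self, vocab: Vocabulary | None = None) -> int:
        if self.n_slots is not None:
            return self.n_slots
        if vocab is None:
            raise FingerprintError("n_slots unset and no vocabulary given")
        return vocab.n


@dataclass(frozen=True)
class SVMF:
    """Sparse upper-triangular fingerprint matrix."""

    n: int
    entries: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (i, j), value in self.entries.items():
            if not (0 <= i <= j < self.n):
                raise FingerprintError(
                    f"entry ({i}, {j}) outside upper triangle of n={self.n}"
                )
            if value <= 0:
                raise FingerprintError(
                    f"stored value at ({i}, {j}) must be positive, got {value}"
                )

    @property
    def flat_length(self) -> int:
        return self.n * self.n

    @property
    def nnz(self) -> int:
        return len(self.entries)

    def flatten(self) -> list[tuple[int, float]]:
        """Sparse vector of (i*n + j, value), ascending by flat index."""
        return sorted(
            (i * self.n + j, v) for (i, j), v in self.entries.items()
        )

    @classmethod
    def unflatten(
        cls, n: int, pairs: Sequence[tuple[int, float]]
    ) -> "SVMF":
        entries: dict[tuple[int, int], float] = {}
        for flat, value in pairs:
            if not 0 <= flat < n * n:
                raise FingerprintError(f"flat index {flat} outside n*n")
            entries[(flat // n, flat % n)] = value
        return cls(n=n, entries=entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SVMF):
            return NotImplemented
        return self.n == other.n and dict(self.entries) == dict(other.entries)


def compute_svmf(
    g: SubstructureGraph,
    vocab: Vocabulary | None = None,
    cfg: SVMFConfig | None = None,
) -> SVMF:
    """Assemble the fingerprint from a substructure graph.

    Instance pairs are unordered and self-pairs are excluded (for i = j
    each pair a < b counts once); pairs farther apart than d_max, and
    pairs in different components, contribute nothing.  Backbone
    weighting reads the ``is_backbone`` flag the matcher stamped on each
    instance; ``vocab`` is only needed to derive the side length when
    ``cfg.n_slots`` is unset.
    """
    cfg = cfg or SVMFConfig()
    n = cfg.side_length(vocab)
    for node in g.nodes:
        if node.substructure_index >= n:
            raise FingerprintError(
                f"substructure index {node.substructure_index} >= n_slots {n}"
            )
    entries: dict[tuple[int, int], float] = {}
    for (u, v), d in all_pairs_distances(g, cfg.d_max).items():
        h2 = cfg.h2(d)
        if h2 == 0.0:
            continue
        nu, nv = g.nodes[u], g.nodes[v]
        weight = (
            cfg.backbone_factor if (nu.is_backbone or nv.is_backbone) else 1.0
        )
        i = min(nu.substructure_index, nv.substructure_index)
        j = max(nu.substructure_index, nv.substructure_index)
        entries[(i, j)] = entries.get((i, j), 0.0) + weight * h2
    for node in g.nodes:
        i = node.substructure_index
        entries[(i, i)] = entries.get((i, i), 0.0) + cfg.h1
    entries = {k: v for k, v in entries.items() if v != 0.0}
    return SVMF(n=n, entries=entries)


def svmf_distance(f1: SVMF, f2: SVMF) -> float:
    """Normalized Euclidean distance ||f1 - f2|| / ||f1 + f2||.

    0 iff the fingerprints are identical (or both empty); 1 when the
    supports are disjoint and both non-empty; lower means more similar.
    """
    if f1.n != f2.n:
        raise FingerprintError(
            f"fingerprint dimensions differ: {f1.n} != {f2.n}"
        )
    keys = set(f1.entries) | set(f2.entries)
    if not keys:
        return 0.0
    num = 0.0
    den = 0.0
    # sorted accumulation keeps the measure exactly symmetric in floats
    for key in sorted(keys):
        a = f1.entries.get(key, 0.0)
        b = f2.entries.get(key, 0.0)
        num += (a - b) ** 2
        den += (a + b) ** 2
    if den == 0.0:
        return 0.0
    return math.sqrt(num) / math.sqrt(den)
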