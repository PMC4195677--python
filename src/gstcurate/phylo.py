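"""Distance matrices from pairwise protein alignments and neighbor-joining.

Distances are Jukes-Cantor-corrected mismatch fractions over mutually
aligned columns of pairwise global alignments scored with BLOSUM62 under a
linear gap penalty of 1 (the tree-building preset); the alphabet size k of
the correction is a parameter (20 for proteins, 4 for nucleotides).

Neighbor joining follows Saitou & Nei with the Q criterion.  Ties in Q are
broken on the lexicographically smallest taxon-id pair, negative branch
lengths are clamped to zero (flagged), and the unrooted result carries one
trifurcation at the center, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import PAPER_TREE, ScoringScheme, global_align, jukes_cantor


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise PhyloError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise PhyloError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise PhyloError("diagonal not zero")
        if not np.isfinite(m).all() or (m < 0).any():
            raise PhyloError("entries must be finite and non-negative")
        self.matrix = m

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids,
                     columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, tid in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.matrix[i])
                fh.write(f"{tid}  {row}\n")


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths; negative NJ lengths clamped to 0."""

    newick: str                       # full precision
    clamped_branches: int = 0
    _tree: dendropy.Tree | None = field(default=None, repr=False)

    @property
    def tree(self) -> dendropy.Tree:
        if self._tree is None:
            self._tree = dendropy.Tree.get(data=self.newick, schema="newick")
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def path_length_matrix(self, ids: Sequence[str]) -> np.ndarray:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(ids)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.distance(taxa[ids[i]], taxa[ids[j]])
                out[i, j] = out[j, i] = d
        return out


def distance_matrix(proteins: Mapping[str, str],
                    scheme: ScoringScheme = PAPER_TREE,
                    k: int = 20) -> DistanceMatrix:
    """All-pairs JC-corrected distances from global alignments."""
    ids = list(proteins)
    if len(ids) < 3:
        raise PhyloError("need at least 3 sequences")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(proteins[ids[i]], proteins[ids[j]], scheme)
            p = 1.0 - aln.identity_fraction
            try:
                d = jukes_cantor(p, k)
            except Exception as e:
                raise PhyloError(
                    f"saturated pair ({ids[i]}, {ids[j]}): {e}") from e
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices."""
    ids = list(D.ids)
    if len(ids) < 3:
        raise PhyloError("need at least 3 taxa")
    # working state: node key -> (newick fragment, smallest leaf label)
    frags = {tid: (tid, tid) for tid in ids}
    d: dict[tuple[str, str], float] = {}
    active = sorted(ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if a != b:
                d[(a, b)] = float(D.matrix[i, j])
    clamped = 0

    def dist(a, b):
        return d[(a, b)]

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                pair_key = tuple(sorted((frags[a][1], frags[b][1])))
                key = (q, pair_key)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = dist(a, b) / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist(a, b) - la
        if la < 0:
            clamped += 1
            la = 0.0
        if lb < 0:
            clamped += 1
            lb = 0.0
        counter += 1
        u = f"__u{counter}"
        frags[u] = (f"({frags[a][0]}:{_fmt(la)},{frags[b][0]}:{_fmt(lb)})",
                    min(frags[a][1], frags[b][1]))
        for c in active:
            if c in (a, b):
                continue
            duc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = sorted((set(active) - {a, b}) | {u})
    a, b, c = active
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    parts = []
    for x, lx in sorted(((a, la), (b, lb), (c, lc)),
                        key=lambda t: frags[t[0]][1]):
        if lx < 0:
            clamped += 1
            lx = 0.0
        parts.append(f"{frags[x][0]}:{_fmt(lx)}")
    newick = f"({','.join(parts)});"
    return PhyloTree(newick=newick, clamped_branches=clamped)


def to_newick(tree: PhyloTree, sig_digits: int = 6) -> str:
    """Newick text with branch lengths at ``sig_digits`` significant digits."""
    t = dendropy.Tree.get(data=tree.newick, schema="newick")
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = float(f"%.{sig_digits}g" % e.length)
    s = t.as_string(schema="newick", suppress_rooting=True,
                    unquoted_underscores=True)
    return s.strip()


def parse_newick(text: str) -> PhyloTree:
    try:
        t = dendropy.Tree.get(data=text, schema="newick")
    except Exception as e:
        raise PhyloError(f"malformed newick: {e}") from e
    return PhyloTree(newick=text.strip(), _tree=t)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=a.newick, schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=b.newick, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)
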