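"""Time-scaled binary genealogies.

A :class:`Genealogy` is the in-memory tree every stage of the pipeline
exchanges: coalescent simulators produce one, the phylogenetic likelihood
consumes one, and posterior tree samples are lists of them.  Nodes are
integers: tips ``0..n-1`` (contemporaneous, at time 0) and internal nodes
``n..2n-2``; node times increase into the past.  Times are either
mutation-scaled (substitutions/site) or calendar years, recorded in
``time_units``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

MUTATION_UNITS = "substitutions_per_site"
YEAR_UNITS = "years"


class Genealogy:
    """Rooted, binary, (near-)ultrametric genealogy.

    Parameters
    ----------
    parent
        Integer array of length ``2n-1``; ``parent[i]`` is the parent node of
        ``i`` and the root carries ``-1``.
    times
        Node times, length ``2n-1``; tips at (approximately) 0, every parent
        at least as old as its children.  Zero-length branches are legal
        (needed for degenerate star genealogies); negative ones are not.
    labels
        Tip labels, length ``n``, unique.
    """

    def __init__(
        self,
        parent: Sequence[int],
        times: Sequence[float],
        labels: Sequence[str],
        time_units: str = MUTATION_UNITS,
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.times = np.asarray(times, dtype=float)
        self.labels = list(labels)
        self.time_units = time_units
        if validate:
            self._validate()

    # -- construction / structure -------------------------------------------------

    def _validate(self) -> None:
        n_nodes = self.parent.size
        if n_nodes != self.times.size:
            raise ValueError("parent and times length mismatch")
        if n_nodes % 2 == 0 or n_nodes < 3:
            raise ValueError("a binary genealogy needs an odd node count >= 3")
        n = (n_nodes + 1) // 2
        if len(self.labels) != n:
            raise ValueError(f"expected {n} tip labels, got {len(self.labels)}")
        if len(set(self.labels)) != n:
            raise ValueError("tip labels must be unique")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("exactly one root required")
        child_counts = np.bincount(self.parent[self.parent >= 0], minlength=n_nodes)
        if np.any(child_counts[:n] != 0) or np.any(child_counts[n:] != 2):
            raise ValueError("tree is not binary with tips 0..n-1")
        has_par = self.parent >= 0
        if np.any(self.times[self.parent[has_par]] < self.times[has_par] - 1e-12):
            raise ValueError("negative branch length: parent younger than child")

    @property
    def n_tips(self) -> int:
        return (self.parent.size + 1) // 2

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def postorder(self) -> list[int]:
        """Internal nodes ordered so every child precedes its parent."""
        children = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(children[v])
        order.reverse()
        return [v for v in order if v >= self.n_tips]

    def copy(self) -> "Genealogy":
        return Genealogy(
            self.parent.copy(), self.times.copy(), list(self.labels),
            self.time_units, validate=False,
        )

    # -- branch-length summaries ---------------------------------------------------

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry = 0)."""
        bl = np.zeros(self.n_nodes)
        has_par = self.parent >= 0
        bl[has_par] = self.times[self.parent[has_par]] - self.times[has_par]
        return np.maximum(bl, 0.0)

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def external_branch_length(self) -> float:
        return float(self.branch_lengths()[: self.n_tips].sum())

    # -- clades and MRCAs ----------------------------------------------------------

    def clade_tipsets(self) -> dict[int, frozenset[int]]:
        """Map internal node -> frozenset of descendant tip indices."""
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(self.n_tips)}
        children = self.children()
        for v in self.postorder():
            a, b = children[v]
            sets[v] = sets[a] | sets[b]
        return {v: s for v, s in sets.items() if v >= self.n_tips}

    def mrca(self, tips: Iterable[int | str]) -> int:
        idx = set()
        for t in tips:
            idx.add(self.labels.index(t) if isinstance(t, str) else int(t))
        if not idx:
            raise ValueError("empty taxon set")
        unknown = [i for i in idx if not 0 <= i < self.n_tips]
        if unknown:
            raise ValueError(f"unknown tips: {unknown}")
        target = frozenset(idx)
        best, best_size = self.root, self.n_tips + 1
        for v, s in self.clade_tipsets().items():
            if target <= s and len(s) < best_size:
                best, best_size = v, len(s)
        return best

    def is_monophyletic(self, tips: Iterable[int | str]) -> bool:
        idx = frozenset(
            self.labels.index(t) if isinstance(t, str) else int(t) for t in tips
        )
        if len(idx) == 1:
            return True
        return idx in set(self.clade_tipsets().values())

    # -- serialization -------------------------------------------------------------

    def newick(self, precision: int = 12) -> str:
        children = self.children()
        bl = self.branch_lengths()

        def fmt(v: int) -> str:
            if v < self.n_tips:
                core = self.labels[v]
            else:
                a, b = children[v]
                core = f"({fmt(a)},{fmt(b)})"
            if self.parent[v] < 0:
                return core
            return f"{core}:{bl[v]:.{precision}g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, text: str, time_units: str = MUTATION_UNITS) -> "Genealogy":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(tree, time_units=time_units)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, time_units: str = MUTATION_UNITS) -> "Genealogy":
        nodes = [nd for nd in tree.preorder_node_iter()]
        leaves = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        n = len(leaves)
        index = {id(nd): i for i, nd in enumerate(leaves)}
        index.update({id(nd): n + j for j, nd in enumerate(internals)})
        depth = {id(tree.seed_node): 0.0}
        for nd in nodes:
            if nd is not tree.seed_node:
                depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        height = max(depth[id(nd)] for nd in leaves)
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        times = np.zeros(2 * n - 1)
        labels = [""] * n
        for nd in nodes:
            i = index[id(nd)]
            times[i] = max(height - depth[id(nd)], 0.0)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon else f"tip{i}"
        tips_t = times[:n]
        if np.any(np.abs(tips_t) > 1e-6 * max(height, 1.0)):
            raise ValueError("tree is not ultrametric: tips not contemporaneous")
        times[:n] = 0.0
        return cls(parent, times, labels, time_units=time_units)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Genealogy n_tips={self.n_tips} tmrca={self.tmrca:.4g} units={self.time_units}>"


def write_nexus_trees(trees: Sequence[Genealogy], path) -> None:
    """Write a posterior tree sample as a minimal NEXUS trees block."""
    if not trees:
        raise ValueError("no trees to write")
    labels = trees[0].labels
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBegin taxa;\n")
        fh.write(f"\tDimensions ntax={len(labels)};\n\tTaxlabels\n")
        for lab in labels:
            fh.write(f"\t\t{lab}\n")
        fh.write("\t\t;\nEnd;\nBegin trees;\n")
        for k, g in enumerate(trees):
            fh.write(f"tree STATE_{k} = {g.newick()}\n")
        fh.write("End;\n")
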