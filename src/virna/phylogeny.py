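"""Distance-based protein phylogenetics: p-distances, neighbor joining,
bootstrap supports, newick serialization.

The alignment is an input (built elsewhere, e.g. with ClustalW or
MAFFT); distances are uncorrected p-distances with pairwise gap
deletion (a Poisson correction is available). Tree construction is the
Saitou–Nei neighbor-joining agglomeration with deterministic
tie-breaking: among equal-Q pairs the pair with the lowest node-creation
indices is joined. Negative branch lengths, which NJ can produce, are
clamped to zero with the deficit moved to the sibling branch so the
path length through the new node is preserved.

Bootstrap supports resample alignment columns with replacement; the
support of an internal branch of the full-data tree is the fraction of
replicate trees containing the same leaf bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import SeqIO

from virna.errors import ConfigError, DataError, FormatError, InputError

GAP = "-"


@dataclass(frozen=True)
class Msa:
    """Aligned amino-acid rows with unique taxon labels."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 3:
            raise InputError("alignment needs at least 3 taxa")
        if len(self.labels) != len(self.rows):
            raise InputError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("taxon labels are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise InputError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        """Bootstrap replicate: columns drawn with replacement."""
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        return Msa(
            labels=self.labels,
            rows=tuple("".join(row[c] for c in cols) for row in self.rows),
        )


def read_aligned_fasta(handle) -> Msa:
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise FormatError("no records in alignment file")
    return Msa(
        labels=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise InputError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise DataError("negative distances")

    def to_phylip(self) -> str:
        """PHYLIP square format."""
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(
                f"{lab[:10]:<10}" + "  ".join(f"{x:.6f}" for x in row)
            )
        return "\n".join(lines) + "\n"


def p_distance_matrix(msa: Msa, correction: str = "none") -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    d(i,j) = mismatches / compared columns over columns where neither
    row is a gap. ``correction="poisson"`` applies -ln(1-p).
    """
    if correction not in {"none", "poisson"}:
        raise ConfigError(f"unknown correction {correction!r}")
    n = msa.n_taxa
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise DataError(
                    f"taxa {msa.labels[i]!r} and {msa.labels[j]!r} share no "
                    "gap-free column"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / n_comp
            if correction == "poisson":
                if p >= 1.0:
                    raise DataError(
                        f"p-distance 1.0 between {msa.labels[i]!r} and "
                        f"{msa.labels[j]!r}: Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=msa.labels, values=d)


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogeny; ``length`` is the branch to the
    parent, ``support`` a bootstrap proportion in [0, 1]."""

    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root-equivalent node."""

    root: TreeNode

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each canonicalized as the side
        *not* containing the lexicographically first taxon."""
        all_taxa = self.taxa
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            side = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side if ref not in side else all_taxa - side)
            return side

        walk(self.root)
        return out

    def internal_edges(self) -> list[tuple[frozenset[str], TreeNode]]:
        all_taxa = self.taxa
        ref = min(all_taxa)
        out = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            side = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(side) <= len(all_taxa) - 2:
                out.append((side if ref not in side else all_taxa - side, node))
            return side

        walk(self.root)
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths through the tree."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                below = {node.label: 0.0}
            else:
                below = {}
                sides = [walk(c) for c in node.children]
                for a in range(len(sides)):
                    for b in range(a + 1, len(sides)):
                        for la, da in sides[a].items():
                            for lb, db in sides[b].items():
                                key = tuple(sorted((la, lb)))
                                dists[key] = da + db
                for s in sides:
                    below.update(s)
            if node.length is not None:
                below = {k: v + node.length for k, v in below.items()}
            return below

        walk(self.root)
        return dists


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking."""
    n = len(d.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=lab) for i, lab in enumerate(d.labels)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best, best_q = (i, j), q
        i, j = best
        dij = get(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, preserving the through-path li + lj
        if li < 0:
            lj += -li
            li = 0.0
        elif lj < 0:
            li += -lj
            lj = 0.0
        node_i, node_j = nodes.pop(i), nodes.pop(j)
        node_i.length, node_j.length = li, lj
        new = TreeNode(children=[node_i, node_j])
        nodes[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = (
                get(i, k) + get(j, k) - dij
            ) / 2
        active = [k for k in active if k not in (i, j)] + [next_id]
        active.sort()
        next_id += 1

    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2
    lb = (get(a, b) + get(b, c) - get(a, c)) / 2
    lc = (get(a, c) + get(b, c) - get(a, b)) / 2
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(idx)
        node.length = max(0.0, length)
        root.children.append(node)
    return PhyloTree(root=root)


def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "none",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement *n_reps* times; each internal
    branch's support is the fraction of replicate NJ trees containing
    the same leaf bipartition. The full-data topology itself does not
    depend on the seed.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    tree = neighbor_joining(p_distance_matrix(msa, correction=correction))
    counts: dict[frozenset[str], int] = {bp: 0 for bp, _ in tree.internal_edges()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = neighbor_joining(
            p_distance_matrix(msa.resample_columns(rng), correction=correction)
        )
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in tree.internal_edges():
        node.support = counts[bp] / n_reps
    return tree


_NEWICK_META = set("()[]:;,' \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; bootstrap supports become internal
    node labels."""
    if tree.root.is_leaf and tree.root.label is None:
        raise FormatError("cannot serialize an empty tree")

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            s = _quote(node.label or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.support is not None:
                s += _fmt(node.support)
        if node.length is not None:
            s += f":{_fmt(node.length)}"
        return s

    return render(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (internal node labels read as supports)."""
    import dendropy

    if not text.strip() or not text.strip().strip(";"):
        raise FormatError("empty newick string")
    dt = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            label=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length,
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.label = dnode.label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dt.seed_node)
    return PhyloTree(root=root)
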