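"""Neighbor-joining trees of CPR alleles with bootstrap support.

Allele phylogenies orient derived versus ancestral promoter haplotypes:
pairwise distances are computed under JC, K2P or a composite TN93 model
(base composition pooled across all pairs, per-pair substitution counts),
trees are built with Saitou-Nei neighbor joining with deterministic
tie-breaking, rooted on an outgroup pendant edge when one is supplied,
and clade support is assessed by resampling alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "composite_distance",
    "neighbor_joining",
    "bootstrap_support",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(np.diag(m)[~np.isnan(np.diag(m))], 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(m - m.T), initial=0.0) > 1e-9:
                raise ValueError("matrix must be symmetric")


def _pair_counts(a: str, b: str) -> tuple[int, int, int, int]:
    """(usable sites, transitions P1 purine, transitions P2 pyrimidine, transversions)."""
    n = p1 = p2 = q = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        n += 1
        if x == y:
            continue
        if {x, y} <= _PURINES:
            p1 += 1
        elif {x, y} <= _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    return n, p1, p2, q


def composite_distance(
    sequences: dict[str, str], submodel: str = "TN93"
) -> DistanceMatrix:
    """Pairwise evolutionary distances for equal-length aligned sequences.

    ``submodel``:
      * ``"JC"``  — Jukes-Cantor, d = -(3/4) ln(1 - 4p/3);
      * ``"K2P"`` — Kimura two-parameter from transition/transversion counts;
      * ``"TN93"`` (default) — composite Tamura-Nei: base frequencies are
        pooled over the whole data set (shared across pairs), while the
        transition/transversion proportions are per pair.

    Sites where either sequence has N are dropped pairwise.  A p-distance
    outside a model's domain (log of a non-positive value) yields NaN.
    """
    labels = list(sequences)
    seqs = {k: v.upper() for k, v in sequences.items()}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    # pooled base composition (the composite part of the model)
    counts = {b: 0 for b in "ACGT"}
    for s in seqs.values():
        for c in s:
            if c in counts:
                counts[c] += 1
    tot = sum(counts.values())
    g = {b: (counts[b] / tot if tot else 0.25) for b in "ACGT"}
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    m = len(labels)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            n, p1, p2, q = _pair_counts(seqs[labels[i]], seqs[labels[j]])
            if n == 0:
                d = float("nan")
            elif submodel == "JC":
                p = (p1 + p2 + q) / n
                arg = 1 - 4 * p / 3
                d = -0.75 * math.log(arg) if arg > 0 else float("nan")
            elif submodel == "K2P":
                P, Q = (p1 + p2) / n, q / n
                a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
                d = (
                    -0.5 * math.log(a1) - 0.25 * math.log(a2)
                    if a1 > 0 and a2 > 0
                    else float("nan")
                )
            elif submodel == "TN93":
                P1, P2, Q = p1 / n, p2 / n, q / n
                k1 = 2 * g["A"] * g["G"] / gR if gR > 0 else 0.0
                k2 = 2 * g["T"] * g["C"] / gY if gY > 0 else 0.0
                k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["T"] * g["C"] * gR / gY)
                w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 0.0
                w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 0.0
                w3 = 1 - Q / (2 * gR * gY)
                if w1 > 0 and w2 > 0 and w3 > 0:
                    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
                else:
                    d = float("nan")
            else:
                raise ValueError(f"unknown submodel {submodel!r}")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)


@dataclass
class _Node:
    name: str | None = None  # leaf name
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> frozenset[str]:
        if self.name is not None:
            return frozenset([self.name])
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Rooted representation of an (unrooted) NJ tree.

    ``supports`` maps canonical bipartitions (the leaf side not containing
    the lexicographically smallest taxon) to bootstrap percentages.
    """

    root: _Node
    labels: list[str]
    outgroup: str | None = None
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions of the unrooted tree, canonicalized."""
        all_leaves = frozenset(self.labels)
        anchor = min(self.labels)
        out: set[frozenset[str]] = set()

        def walk(node: _Node) -> None:
            for child, _ in node.children:
                side = child.leaves()
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(side)
                walk(child)

        walk(self.root)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def find(node: _Node, target: str, acc: float) -> float | None:
            if node.name == target:
                return acc
            for c, bl in node.children:
                r = find(c, target, acc + bl)
                if r is not None:
                    return r
            return None

        def lca_dist(node: _Node) -> float | None:
            la = find(node, a, 0.0)
            lb = find(node, b, 0.0)
            if la is None or lb is None:
                return None
            best = la + lb
            for c, _ in node.children:
                r = lca_dist(c)
                if r is not None:
                    best = min(best, r)
            return best

        r = lca_dist(self.root)
        if r is None:
            raise KeyError((a, b))
        return r

    def newick(self, support_min: float | None = None) -> str:
        """Newick string; bootstrap supports as internal node labels.

        With ``support_min``, only supports strictly above it are shown
        (e.g. 60 to annotate only well-supported nodes).
        """

        def fmt(node: _Node) -> str:
            if node.name is not None:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            lab = ""
            if node.support is not None and (
                support_min is None or node.support > support_min
            ):
                lab = f"{node.support:.0f}"
            return f"({inner}){lab}"

        return fmt(self.root) + ";"


def neighbor_joining(d: DistanceMatrix, outgroup: str | None = None) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The standard Q criterion selects the pair to join; exact ties are broken
    by lexicographic order of the joined clusters' smallest leaf names.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  With an ``outgroup`` the tree is rooted at the
    midpoint of the outgroup's pendant edge, otherwise at the final join.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    nodes: list[_Node] = [_Node(name=lab) for lab in labels]
    keys: list[str] = list(labels)  # smallest leaf per cluster, for tie-break
    D = d.matrix.astype(float).copy()
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")

    while len(nodes) > 2:
        r = len(nodes)
        R = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                qv = (r - 2) * D[i, j] - R[i] - R[j]
                key = (qv, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        if lj < 0:
            lj, li = 0.0, D[i, j]
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        newd = np.zeros(r - 1)
        rest = [k for k in range(r) if k not in (i, j)]
        for idx, k in enumerate(rest):
            newd[idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        Dn = np.zeros((r - 1, r - 1))
        Dn[:-1, :-1] = D[np.ix_(rest, rest)]
        Dn[-1, :-1] = newd[: r - 2]
        Dn[:-1, -1] = newd[: r - 2]
        nodes = [nodes[k] for k in rest] + [parent]
        keys = [keys[k] for k in rest] + [min(keys[i], keys[j])]
        D = Dn

    # final join: split the remaining edge evenly (path distances preserved)
    bl = max(D[0, 1], 0.0)
    root = _Node(children=[(nodes[0], bl / 2), (nodes[1], bl / 2)])
    tree = PhyloTree(root=root, labels=labels, outgroup=outgroup)
    if outgroup is not None:
        tree = _reroot_on_pendant(tree, outgroup)
    return tree


def _adjacency(tree: PhyloTree):
    """Edge list of the rooted tree as an undirected adjacency map."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    counter = [0]

    def nid() -> int:
        counter[0] += 1
        return counter[0]

    def walk(node: _Node, ident: int) -> None:
        if node.name is not None:
            names[ident] = node.name
        for c, bl in node.children:
            cid = nid()
            adj.setdefault(ident, []).append((cid, bl))
            adj.setdefault(cid, []).append((ident, bl))
            walk(c, cid)

    walk(tree.root, 0)
    # the root of an unrooted representation is a degree-2 node: splice it out
    if len(adj.get(0, [])) == 2:
        (a, la), (b, lb) = adj[0]
        adj[a] = [(x, l) for x, l in adj[a] if x != 0] + [(b, la + lb)]
        adj[b] = [(x, l) for x, l in adj[b] if x != 0] + [(a, la + lb)]
        del adj[0]
    return adj, names


def _reroot_on_pendant(tree: PhyloTree, outgroup: str) -> PhyloTree:
    adj, names = _adjacency(tree)
    leaf = next(i for i, nm in names.items() if nm == outgroup)
    (nbr, bl) = adj[leaf][0]

    def build(ident: int, parent: int) -> _Node:
        nm = names.get(ident)
        kids = [(k, l) for k, l in adj[ident] if k != parent]
        if nm is not None and not kids:
            return _Node(name=nm)
        node = _Node()
        node.children = [(build(k, ident), l) for k, l in kids]
        return node

    root = _Node(
        children=[(build(leaf, nbr), bl / 2), (build(nbr, leaf), bl / 2)]
    )
    return PhyloTree(root=root, labels=tree.labels, outgroup=outgroup)


def bootstrap_support(
    sequences: dict[str, str],
    reps: int = 1000,
    seed: int | None = None,
    submodel: str = "TN93",
    outgroup: str | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement ``reps`` times; each
    replicate is run through the same distance + NJ path, and each internal
    bipartition of the original tree is annotated with the percentage of
    replicates containing it.  Replicates whose distance matrix is undefined
    (saturated or empty resample) are skipped but still count in the
    denominator.
    """
    if not sequences:
        raise ValueError("empty alignment")
    tree = neighbor_joining(composite_distance(sequences, submodel), outgroup)
    labels = list(sequences)
    cols = np.array([list(sequences[k].upper()) for k in labels])
    L = cols.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(reps):
        idx = rng.integers(0, L, size=L)
        resampled = {lab: "".join(cols[i, idx]) for i, lab in enumerate(labels)}
        try:
            rep_tree = neighbor_joining(
                composite_distance(resampled, submodel), outgroup
            )
        except ValueError:
            continue
        found = rep_tree.bipartitions()
        for bp in counts:
            if bp in found:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / reps for bp, c in counts.items()}
    _annotate_supports(tree)
    return tree


def _annotate_supports(tree: PhyloTree) -> None:
    all_leaves = frozenset(tree.labels)
    anchor = min(tree.labels)

    def walk(node: _Node) -> None:
        for child, _ in node.children:
            side = child.leaves()
            canon = all_leaves - side if anchor in side else side
            if canon in tree.supports:
                child.support = tree.supports[canon]
            walk(child)

    walk(tree.root)
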