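"""Signature distances, UPGMA trees, OUD-resampling bootstrap and tree I/O.

Strain signatures are compared by plain Euclidean distance

    d(x, y) = sqrt( sum_z (OUD_x(z) - OUD_y(z))^2 )

over all 4^k k-mers z.  Trees are built with UPGMA (average linkage), which
yields a rooted ultrametric tree.  Bootstrap support is computed by
resampling signature components: each replicate draws 4^k k-mer indices with
replacement, applies the SAME index multiset to every strain's signature
(so replicate columns remain comparable), rebuilds the distance matrix and
UPGMA tree, and counts how often each reference bipartition reappears.

Trees are carried as dendropy trees wrapped in :class:`SupportTree`;
bipartitions are canonicalized by their smaller leaf block (ties broken
lexicographically) so rooted and unrooted views agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .signature import OUDSignature

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "euclidean_distance",
    "distance_matrix",
    "upgma",
    "bootstrap_support",
    "bipartitions",
    "rf_distance",
    "reroot",
    "write_newick",
    "read_newick",
    "cophenetic_matrix",
]

Bipartition = frozenset  # canonical smaller block of a split


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over ordered strain labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(repr(float(v)) for v in row)
                fh.write(f"{label:<10s} {cells}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


class SupportTree:
    """A rooted tree with optional per-bipartition bootstrap support.

    Wraps a :class:`dendropy.Tree`.  Supports are percentages in [0, 100]
    keyed by canonical bipartition (smaller leaf block).
    """

    def __init__(self, tree: dendropy.Tree, supports: dict[Bipartition, float] | None = None):
        self.tree = tree
        self.supports = dict(supports or {})

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths: dict[str, float] = {}
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol

    def clone(self) -> "SupportTree":
        return SupportTree(self.tree.clone(depth=1), dict(self.supports))

    def __repr__(self) -> str:
        return f"SupportTree({len(self.leaf_labels)} leaves)"


def euclidean_distance(x: OUDSignature, y: OUDSignature) -> float:
    """Euclidean distance between two OUD signatures of the same k."""
    if x.k != y.k:
        raise ValueError(f"signature k mismatch: {x.k} vs {y.k}")
    if x.null_model != y.null_model:
        raise ValueError("signatures computed under different null models")
    return float(np.linalg.norm(x.values - y.values))


def distance_matrix(sigs: Sequence[OUDSignature], labels: Sequence[str] | None = None) -> DistanceMatrix:
    """All pairwise Euclidean signature distances."""
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures")
    if labels is None:
        labels = [s.strain for s in sigs]
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strain labels")
    X = np.stack([s.values for s in sigs])
    d = _pairwise_euclidean(X)
    return DistanceMatrix(labels=labels, values=d)


def _pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d


def upgma(dm: DistanceMatrix) -> SupportTree:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Iteratively merges the pair of clusters at minimal average distance; the
    merged node sits at height d/2, so the result is ultrametric.  Among
    equal-minimum pairs the pair whose (smaller representative label, larger
    representative label) is lexicographically least is merged first, where a
    cluster's representative is its lexicographically smallest leaf label.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    tns = dendropy.TaxonNamespace(dm.labels)
    clusters: dict[int, dict] = {}
    for i, label in enumerate(dm.labels):
        node = dendropy.Node(taxon=tns.get_taxon(label))
        clusters[i] = {"node": node, "size": 1, "height": 0.0, "rep": label}
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.values[i, j])
    next_id = n
    while len(clusters) > 1:
        best_pair = None
        best_key = None
        for pair, d in dist.items():
            a, b = sorted(pair, key=lambda c: clusters[c]["rep"])
            key = (d, clusters[a]["rep"], clusters[b]["rep"])
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        a, b = best_pair
        d_ab = dist.pop(frozenset((a, b)))
        height = d_ab / 2.0
        parent = dendropy.Node()
        for c in (a, b):
            child = clusters[c]["node"]
            child.edge.length = height - clusters[c]["height"]
            parent.add_child(child)
        size = clusters[a]["size"] + clusters[b]["size"]
        rep = min(clusters[a]["rep"], clusters[b]["rep"])
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dnew = (clusters[a]["size"] * da + clusters[b]["size"] * db) / size
            dist[frozenset((next_id, other))] = dnew
        del clusters[a], clusters[b]
        clusters[next_id] = {"node": parent, "size": size, "height": height, "rep": rep}
        next_id += 1
    (root_info,) = clusters.values()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root_info["node"]
    tree.is_rooted = True
    return SupportTree(tree)


def _canonical(block: Iterable[str], all_labels: frozenset[str]) -> Bipartition:
    block = frozenset(block)
    other = all_labels - block
    if (len(block), tuple(sorted(block))) <= (len(other), tuple(sorted(other))):
        return block
    return other


def bipartitions(t: SupportTree) -> set[Bipartition]:
    """Non-trivial bipartitions of the unrooted view of the tree.

    One per internal edge; pendant-leaf and root-spanning trivial splits are
    excluded.  Each split is identified by its canonical (smaller) block.
    """
    all_labels = t.leaf_labels
    splits: set[Bipartition] = set()
    for node in t.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        block = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(block) < 2 or len(all_labels - block) < 2:
            continue
        splits.add(_canonical(block, all_labels))
    return splits


def rf_distance(t1: SupportTree, t2: SupportTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of bipartition sets|."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("trees have different leaf label sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    sigs: Sequence[OUDSignature],
    n_reps: int = 100,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> SupportTree:
    """UPGMA tree with bootstrap support from resampled OUD components.

    Each replicate draws 4^k signature indices with replacement — one index
    multiset shared by every strain — then rebuilds distances and the UPGMA
    tree.  A reference bipartition's support is the percentage of replicates
    whose tree contains it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = distance_matrix(sigs, labels=labels)
    ref = upgma(dm)
    ref_splits = bipartitions(ref)
    X = np.stack([s.values for s in sigs])
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    hits = {split: 0 for split in ref_splits}
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        Xb = X[:, idx]
        dm_b = DistanceMatrix(labels=dm.labels, values=_pairwise_euclidean(Xb))
        rep_splits = bipartitions(upgma(dm_b))
        for split in ref_splits & rep_splits:
            hits[split] += 1
    ref.supports = {s: 100.0 * c / n_reps for s, c in hits.items()}
    return ref


def reroot(t: SupportTree, outgroup_label: str) -> SupportTree:
    """Re-root on the pendant edge of the outgroup leaf.

    The unrooted topology — hence the bipartition set and any supports — is
    unchanged.
    """
    if outgroup_label not in t.leaf_labels:
        raise ValueError(f"unknown outgroup label {outgroup_label!r}")
    out = t.clone()
    leaf = next(
        lf for lf in out.tree.leaf_node_iter() if lf.taxon.label == outgroup_label
    )
    if leaf.parent_node is out.tree.seed_node and len(out.tree.seed_node.child_nodes()) == 2:
        return out  # already rooted on this pendant edge
    length = leaf.edge.length or 0.0
    out.tree.reroot_at_edge(
        leaf.edge, length1=length / 2.0, length2=length / 2.0,
        update_bipartitions=False,
    )
    return out


def _support_label(value: float) -> str:
    return str(int(round(value))) if abs(value - round(value)) < 1e-9 else repr(value)


def write_newick(t: SupportTree, path: str | Path | None = None, precision: int = 17) -> str:
    """Serialize to Newick, supports stored as internal node labels.

    Returns the Newick string; writes it to ``path`` when given.
    """
    all_labels = t.leaf_labels
    for node in t.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        block = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _canonical(block, all_labels)
        if key in t.supports:
            node.label = _support_label(t.supports[key])
    s = t.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def read_newick(source: str | Path) -> SupportTree:
    """Read a Newick tree; numeric internal node labels become supports."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("("):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    t = SupportTree(tree)
    all_labels = t.leaf_labels
    supports: dict[Bipartition, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        block = frozenset(lf.taxon.label for lf in node.leaf_iter())
        supports[_canonical(block, all_labels)] = value
    t.supports = supports
    return t


def cophenetic_matrix(t: SupportTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (the cophenetic distances of an
    ultrametric tree)."""
    labels = sorted(t.leaf_labels)
    pdm = t.tree.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=labels, values=d)
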