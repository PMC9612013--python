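"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap, monophyly.

The tree is reconstructed by classical neighbor joining (Q-criterion join
selection, Studier–Keppler branch lengths) from pairwise p-distances computed
with pairwise deletion of gaps and Ns; branch support comes from
column-resampling bootstrap replicates; rooting is by outgroup, and labelled
leaf sets can be tested for monophyly — a query scattered over k maximal
clades has ``min_clades = k``, with k = 1 exactly when the set is
monophyletic.

Dendropy trees are the interchange container; newick is the interchange
format, with integer-percent supports stored as internal node labels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import OutgroupError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ParameterError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ParameterError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ParameterError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ParameterError("distances must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def _encode(al) -> np.ndarray:
    M = al.matrix()
    code = np.full(M.shape, 255, dtype=np.uint8)
    for i, b in enumerate((b"A", b"C", b"G", b"T")):
        code[M == b] = i
    return code  # 255 = missing (gap or N)


def p_distance_matrix(al, mode: str = "all_columns", snv_columns=None) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gaps and N.

    ``mode="snv_only"`` restricts to SNV columns (classified on the fly when
    ``snv_columns`` is not supplied).  A pair with zero comparable columns is
    an error naming the pair.
    """
    if al.n_seqs < 2:
        raise ParameterError("need at least two sequences")
    code = _encode(al)
    if mode == "snv_only":
        if snv_columns is None:
            from .variants import classify_columns

            vt, _ = classify_columns(al)
            snv_columns = vt.positions()
        cols = np.asarray(sorted(snv_columns), dtype=int) - 1
        code = code[:, cols]
    elif mode != "all_columns":
        raise ParameterError(f"mode must be all_columns|snv_only, got {mode!r}")
    n = al.n_seqs
    D = np.zeros((n, n))
    valid_mask = code != 255
    for i in range(n):
        for j in range(i + 1, n):
            valid = valid_mask[i] & valid_mask[j]
            m = int(valid.sum())
            if m == 0:
                raise ParameterError(
                    f"no comparable columns between {al.ids[i]!r} and {al.ids[j]!r}"
                )
            D[i, j] = D[j, i] = int((code[i][valid] != code[j][valid]).sum()) / m
    return DistanceMatrix(list(al.ids), D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp(x: float, clamped: list[float]) -> float:
    if x < 0:
        clamped.append(-x)
        return 0.0
    return x


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    Joins minimise Q(i,j) = (r-2) d(i,j) - R(i) - R(j); ties go to the
    lexicographically smallest cluster label pair (a cluster is labelled by
    its smallest leaf label).  Branch lengths follow Studier–Keppler;
    negatives are clamped to zero and the total deficit logged.  The result
    is unrooted with a single degree-3 anchor node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    cluster_label = list(dm.labels)  # smallest leaf label per active cluster
    D = dm.values.copy()
    active = list(range(n))
    clamped: list[float] = []

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - R[i] - R[j]
                pair = tuple(sorted((cluster_label[i], cluster_label[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (len(active) - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li, clamped)
        nodes[j].edge.length = _clamp(lj, clamped)
        # distances to the new cluster
        new_index = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (i, j):
                continue
            D[new_index, kk] = D[kk, new_index] = 0.5 * (D[i, kk] + D[j, kk] - D[i, j])
        nodes.append(u)
        cluster_label.append(min(cluster_label[i], cluster_label[j]))
        active = [a for a in active if a not in (i, j)] + [new_index]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = _clamp(ln, clamped)
    tree.seed_node = center
    tree.is_rooted = False
    if clamped:
        logger.warning(
            "clamped %d negative NJ branch lengths (total deficit %.3g)",
            len(clamped),
            sum(clamped),
        )
    tree.clamped_deficit = sum(clamped)
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, rooting, monophyly
# ---------------------------------------------------------------------------

def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial leaf bipartitions, each normalised to the side not
    containing the lexicographically smallest leaf label."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds (symmetric bipartition) distance between unrooted trees."""
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    al,
    n_reps: int = 5000,
    seed: int = 0,
    mode: str = "all_columns",
) -> dendropy.Tree:
    """NJ tree with integer-percent bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; an internal edge's
    support is the percentage of replicate NJ trees containing the same leaf
    bipartition.  Reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    from .variants import Alignment

    base = nj_tree(p_distance_matrix(al, mode=mode))
    all_labels = frozenset(lf.taxon.label for lf in base.leaf_node_iter())
    ref = min(all_labels)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(base)}
    rng = np.random.default_rng(seed)
    ncol = al.length
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_al = Alignment(list(al.ids), ["".join(s[c] for c in cols) for s in al.seqs])
        try:
            rep_tree = nj_tree(p_distance_matrix(rep_al, mode=mode))
        except ParameterError:
            continue  # replicate with an incomparable pair contributes nothing
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    for node in base.preorder_node_iter():
        if node is base.seed_node or node.is_leaf():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_labels - side
        if side in counts:
            node.label = str(int(round(100 * counts[side] / n_reps)))
    return base


def root_tree(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup, at its midpoint.

    The outgroup must form a clade in the unrooted tree; otherwise an
    explicit error is raised rather than silently resolving.
    """
    og = frozenset(outgroup_labels)
    rooted = tree.clone(depth=1)
    all_labels = frozenset(lf.taxon.label for lf in rooted.leaf_node_iter())
    missing = og - all_labels
    if missing:
        raise OutgroupError(f"outgroup labels not in tree: {sorted(missing)}")
    target = None
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        ls = _leafset(node)
        if ls == og or ls == all_labels - og:
            target = node
            break
    if target is None:
        raise OutgroupError(f"outgroup {sorted(og)} does not form a clade in the unrooted tree")
    edge_len = target.edge.length or 0.0
    rooted.reroot_at_edge(target.edge, update_bipartitions=False)
    for child in rooted.seed_node.child_nodes():
        child.edge.length = edge_len / 2.0
    rooted.is_rooted = True
    return rooted


@dataclass(frozen=True)
class MonophylyReport:
    """Outcome of a monophyly query on a rooted tree."""

    query: frozenset
    is_monophyletic: bool
    min_clades: int

    def as_text(self) -> str:
        return (
            f"query\t{','.join(sorted(self.query))}\n"
            f"is_monophyletic\t{self.is_monophyletic}\n"
            f"min_clades\t{self.min_clades}\n"
        )


def clade_test(tree: dendropy.Tree, query_labels) -> MonophylyReport:
    """Test whether a leaf-label set forms a single clade of a rooted tree.

    ``min_clades`` is the number of maximal query-pure clades whose leaf
    union is exactly the query set — the minimum possible for a tree, and 1
    iff the set is monophyletic.
    """
    query = frozenset(query_labels)
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = query - all_labels
    if unknown:
        raise ParameterError(f"unknown leaf labels: {sorted(unknown)}")
    if not query:
        raise ParameterError("empty query set")
    pure: dict[int, bool] = {}
    min_clades = 0
    is_mono = False
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = node.taxon.label in query
        else:
            pure[id(node)] = all(pure[id(ch)] for ch in node.child_nodes())
        if pure[id(node)] and _leafset(node) == query:
            is_mono = True
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if pure[id(node)] and (parent is None or not pure[id(parent)]):
            min_clades += 1
    return MonophylyReport(query, is_mono, min_clades)


def read_tree(source) -> dendropy.Tree:
    """Newick from a path or literal string."""
    s = str(source)
    if s.strip().startswith("(") or s.strip().endswith(";"):
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
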