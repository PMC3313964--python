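"""Neighbor-joining tree construction, nonparametric bootstrap, rooting.

Trees are held as :class:`dendropy.Tree` objects wrapped in
:class:`SupportTree`.  The NJ implementation is the classic Saitou & Nei
agglomeration: at each step the pair minimising the rate-corrected Q
criterion is joined; ties are broken deterministically by the lowest
(row, col) index pair with active nodes kept in creation order (input leaf
order first, merged nodes appended).  Negative branch lengths are clamped to
zero with the deficit transferred to the sister edge so the joined pair's
path length is preserved; raw values are logged.

Bootstrap support resamples alignment columns with replacement, rebuilds the
K2P matrix and NJ tree per replicate, and counts each internal bipartition
of the original tree across replicates (support mapped onto the original
tree, not a consensus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .distances import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    encode_alignment,
    k2p_from_counts,
)
from .io_metadata import LocusAlignment

Bipartition = frozenset  # frozenset of leaf labels, normalized (see bipartitions)


@dataclass
class BootstrapConfig:
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("bootstrap replicate count must be >= 1")


@dataclass
class SupportTree:
    """A (possibly rooted) tree with branch lengths and bootstrap supports.

    ``bipartition_support`` maps normalized bipartitions (frozensets of leaf
    labels on the side away from the reference leaf) to percent support; it
    survives rerooting, after which node annotations are refreshed.
    """

    tree: dendropy.Tree
    rooted: str = "unrooted"  # unrooted | outgroup-rooted | midpoint-rooted
    bipartition_support: dict[Bipartition, float] = field(default_factory=dict)
    effective_B: int | None = None
    negative_length_log: list[tuple[str, float]] = field(default_factory=list)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def bipartitions(self) -> set[Bipartition]:
        return bipartitions(self.tree)

    def annotate_supports(self) -> None:
        """Write supports onto internal node labels for newick output."""
        if not self.bipartition_support:
            return
        labels = set(self.leaf_labels)
        ref = min(labels)
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            key = frozenset(labels - below) if ref in below else below
            if key in self.bipartition_support:
                sup = self.bipartition_support[key]
                node.label = f"{sup:g}"
                node.support = sup

    def write_newick(self, path=None) -> str:
        self.annotate_supports()
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".8f",
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Nontrivial bipartitions as normalized frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing the
    lexicographically smallest label is recorded, making the set comparable
    across rootings and leaf orders.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(labels)
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(below) > len(labels) - 2:
            continue
        out.add(frozenset(labels - below) if ref in below else below)
    return out


def read_newick(path_or_string: str, rooted: bool = True) -> SupportTree:
    """Read a newick tree, interpreting internal node labels as supports."""
    src = str(path_or_string)
    if "(" in src and ";" in src:
        tree = dendropy.Tree.get(data=src, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=src, schema="newick", preserve_underscores=True)
    st = SupportTree(tree, rooted="outgroup-rooted" if rooted else "unrooted")
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        try:
            sup = float(node.label)
        except ValueError:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = frozenset(labels - below) if ref in below else below
        st.bipartition_support[key] = sup
    return st


def neighbor_joining(matrix: DistanceMatrix) -> SupportTree:
    """Classic NJ on a fully defined distance matrix (undefined entries must
    be imputed first; see :meth:`DistanceMatrix.imputed`)."""
    n = matrix.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 leaves")
    D = matrix.values.copy()
    if np.isnan(D).any():
        D, _ = matrix.imputed()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(matrix.ids)
    nodes: list[dendropy.Node] = []
    for label in matrix.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    neg_log: list[tuple[str, float]] = []

    def clamp_pair(li: float, lj: float, dij: float, tag: str) -> tuple[float, float]:
        if li < 0:
            neg_log.append((tag, li))
            lj = lj + li
            li = 0.0
        if lj < 0:
            neg_log.append((tag, lj))
            li = li + lj
            li = max(li, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = Q[iu]
        i, j = np.unravel_index(int(np.argmin(flat)), flat.shape)
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj, dij, f"join_{m}")
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form resolution of the final three nodes around the seed node
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for name, l in (("final_a", la), ("final_b", lb), ("final_c", lc)):
        if l < 0:
            neg_log.append((name, l))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    seed = dendropy.Node()
    for node, l in ((a, la), (b, lb), (c, lc)):
        seed.add_child(node)
        node.edge.length = l
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=seed)
    tree.is_rooted = False
    return SupportTree(tree, negative_length_log=neg_log)


def _nj_from_encoded(enc: np.ndarray, ids: list[str], min_overlap: int):
    """K2P matrix + NJ from an encoded alignment; None if no pair is defined."""
    n = enc.shape[0]
    vals = np.full((n, n), np.nan)
    np.fill_diagonal(vals, 0.0)
    comparable = enc < 4
    any_defined = False
    for i in range(n):
        ai = enc[i]
        mi = comparable[i]
        for j in range(i + 1, n):
            mask = mi & comparable[j]
            m = int(mask.sum())
            if m < max(min_overlap, 1):
                continue
            aa = ai[mask]
            bb = enc[j][mask]
            diff = aa != bb
            ts = int((diff & ((aa >> 1) == (bb >> 1))).sum())
            tv = int(diff.sum()) - ts
            pc = k2p_from_counts(m, ts, tv)
            if pc.d is not None:
                vals[i, j] = vals[j, i] = pc.d
                any_defined = True
    if not any_defined:
        return None
    dm = DistanceMatrix(ids, vals)
    return neighbor_joining(dm)


def bootstrap_support(
    aln: LocusAlignment,
    cfg: BootstrapConfig,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SupportTree:
    """NJ tree of ``aln`` with column-resampling bootstrap supports.

    Replicates whose resampled matrix has no defined entry are discarded and
    the effective replicate count reported.  Fully reproducible from the
    config seed.
    """
    enc = encode_alignment(aln)
    ids = list(aln.rows)
    original = _nj_from_encoded(enc, ids, min_overlap)
    if original is None:
        raise ValueError("original alignment yields no defined distances")
    targets = original.bipartitions()
    counts: dict[Bipartition, int] = {bp: 0 for bp in targets}
    rng = np.random.default_rng(cfg.seed)
    effective = 0
    L = enc.shape[1]
    for _ in range(cfg.B):
        cols = rng.integers(0, L, size=L)
        rep = _nj_from_encoded(enc[:, cols], ids, min_overlap)
        if rep is None:
            continue
        effective += 1
        rep_bps = rep.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
    if effective == 0:
        raise ValueError("all bootstrap replicates were discarded")
    original.bipartition_support = {
        bp: 100.0 * c / effective for bp, c in counts.items()
    }
    original.effective_B = effective
    original.annotate_supports()
    return original


def root_at_outgroup(st: SupportTree, outgroup_id: str | None) -> SupportTree:
    """Root on the outgroup's pendant edge; midpoint rooting when absent.

    Supports are re-applied from the bipartition map after rerooting, so
    clade annotations remain attached to the same splits.
    """
    tree = st.tree.clone(depth=1)
    if outgroup_id is None:
        tree.reroot_at_midpoint(update_bipartitions=False)
        mode = "midpoint-rooted"
    else:
        leaf = None
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == outgroup_id:
                leaf = lf
                break
        if leaf is None:
            raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
        length = leaf.edge.length or 0.0
        tree.reroot_at_edge(
            leaf.edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
        mode = "outgroup-rooted"
    tree.is_rooted = True
    rooted = SupportTree(
        tree,
        rooted=mode,
        bipartition_support=dict(st.bipartition_support),
        effective_B=st.effective_B,
    )
    rooted.annotate_supports()
    return rooted
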