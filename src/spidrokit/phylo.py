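"""Alignment distances, neighbor joining, gene-tree/species-tree
reconciliation, phylogenetic independent contrasts, and regression.

Paralog variants of a silk gene family are clustered from pairwise
p-distances with neighbor joining; duplication events are inferred by
LCA (last-common-ancestor) reconciliation of a rooted gene tree against
a rooted species tree; and cross-species structure-property relationships
are tested both with ordinary least squares and with phylogenetic
independent contrasts, which standardise tip differences by Brownian
expected variances so that species values become exchangeable data
points.

Trees are ``dendropy.Tree`` objects throughout; newick is the on-disk
format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import statsmodels.api as sm
from Bio import Align

from .seqio import SequenceRecord

__all__ = [
    "PairwiseAlignment",
    "ReconciliationResult",
    "ContrastSet",
    "RegressionResult",
    "global_align",
    "alignment_identity",
    "p_distance",
    "cluster_divergence",
    "pairwise_distance_matrix",
    "neighbor_joining",
    "reconcile",
    "pic",
    "regress",
]


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences differ in length")


@dataclass(frozen=True)
class ReconciliationResult:
    duplication_nodes: frozenset
    n_duplications: int
    n_losses: int


@dataclass(frozen=True)
class ContrastSet:
    contrasts: list[tuple[float, float]]  # (raw contrast, expected variance)
    n_tips: int

    @property
    def standardized(self) -> np.ndarray:
        return np.array([c / np.sqrt(v) for c, v in self.contrasts])


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float | None
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def _seq_of(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps.

    ``gap_open`` is the score of the first gap position, ``gap_extend``
    of each further position.  The first optimal alignment in the
    aligner's deterministic enumeration order is returned.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(_seq_of(a), _seq_of(b))[0]
    return PairwiseAlignment(gapped_a=str(aln[0]), gapped_b=str(aln[1]), score=aln.score)


def alignment_identity(alignment: PairwiseAlignment) -> float:
    """Matching columns / alignment length (gaps count as mismatch)."""
    a, b = alignment.gapped_a, alignment.gapped_b
    return sum(x == y and x != "-" for x, y in zip(a, b)) / len(a)


def p_distance(alignment: PairwiseAlignment) -> float:
    """Differing sites / compared sites, gap-containing columns excluded."""
    compared = differing = 0
    for x, y in zip(alignment.gapped_a, alignment.gapped_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        raise ValueError("no gap-free columns to compare")
    return differing / compared


def cluster_divergence(
    records: Sequence[SequenceRecord], labels: Mapping[str, str]
) -> tuple[dict[str, float | None], float | None]:
    """Mean within-cluster and between-cluster p-distances.

    Returns (within: cluster -> mean or None for singletons,
    between: overall cross-cluster mean or None with < 2 clusters).
    """
    within: dict[str, list[float]] = {}
    between: list[float] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            d = p_distance(global_align(records[i], records[j]))
            ci, cj = labels[records[i].id], labels[records[j].id]
            if ci == cj:
                within.setdefault(ci, []).append(d)
            else:
                between.append(d)
    clusters = {labels[r.id] for r in records}
    within_means: dict[str, float | None] = {
        c: (sum(within[c]) / len(within[c]) if within.get(c) else None) for c in clusters
    }
    return within_means, (sum(between) / len(between) if between else None)


def pairwise_distance_matrix(
    records: Sequence[SequenceRecord],
) -> tuple[list[str], np.ndarray]:
    """All-vs-all p-distance matrix on global alignments."""
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(global_align(records[i], records[j]))
    return [r.id for r in records], dm


def neighbor_joining(
    labels: Sequence[str],
    distance_matrix: np.ndarray,
    midpoint_root: bool = False,
) -> dendropy.Tree:
    """Classic neighbor joining (Saitou-Nei with the standard Q criterion).

    Ties in Q are broken by the lowest index pair.  The result is
    unrooted (trifurcating at the seed node) unless ``midpoint_root``.
    """
    dm = np.asarray(distance_matrix, dtype=float)
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dm) != 0) or np.any(dm < 0):
        raise ValueError("distance matrix must have zero diagonal and no negatives")
    if n < 2:
        raise ValueError("need at least two taxa")

    taxon_ns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxon_ns.get_taxon(lab))
        nodes.append(nd)
    d = dm.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin scans row-major
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0] + 1)
        for fk in range(m):
            k = active[fk]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    root = dendropy.Node()
    if len(active) == 3:
        # closed form: l_i = (d_ij + d_ik - d_jk) / 2 around the center
        i, j, k = active
        for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
            root.add_child(nodes[a])
            nodes[a].edge.length = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    else:
        i, j = active
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        nodes[i].edge.length = nodes[j].edge.length = d[i, j] / 2.0
    tree.seed_node = root
    tree.is_rooted = False
    if midpoint_root:
        tree.is_rooted = True
        tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def _check_binary_rooted(tree: dendropy.Tree, name: str) -> None:
    for nd in tree.preorder_node_iter():
        nch = len(nd.child_nodes())
        if nch not in (0, 2):
            raise ValueError(f"{name}: node {nd} is not binary (has {nch} children)")


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_species: Mapping[str, str],
) -> ReconciliationResult:
    """LCA reconciliation of a rooted binary gene tree with a rooted
    binary species tree.

    Each gene node g maps to M(g), the LCA in the species tree of the
    species of g's leaves.  g is a duplication iff M(g) equals M(c) for
    one of its children c.  Losses are counted along the embedding: for
    each gene edge (g, c) the species path from M(g) to M(c) implies
    len(path) - 1 losses under a speciation at g and len(path) losses
    under a duplication, which yields zero on congruent trees.
    """
    _check_binary_rooted(gene_tree, "gene tree")
    _check_binary_rooted(species_tree, "species tree")

    sp_parent: dict = {}
    sp_depth: dict = {}
    sp_by_label: dict = {}
    for nd in species_tree.preorder_node_iter():
        sp_depth[nd] = 0 if nd.parent_node is None else sp_depth[nd.parent_node] + 1
        sp_parent[nd] = nd.parent_node
        if nd.is_leaf():
            sp_by_label[nd.taxon.label] = nd

    def sp_lca(a, b):
        while sp_depth[a] > sp_depth[b]:
            a = sp_parent[a]
        while sp_depth[b] > sp_depth[a]:
            b = sp_parent[b]
        while a is not b:
            a, b = sp_parent[a], sp_parent[b]
        return a

    mapping: dict = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in leaf_species:
                raise ValueError(f"gene leaf {label!r} has no species mapping")
            sp = leaf_species[label]
            if sp not in sp_by_label:
                raise ValueError(f"species {sp!r} not a leaf of the species tree")
            mapping[nd] = sp_by_label[sp]
        else:
            c1, c2 = nd.child_nodes()
            mapping[nd] = sp_lca(mapping[c1], mapping[c2])

    duplications = set()
    losses = 0
    for nd in gene_tree.preorder_internal_node_iter():
        children = nd.child_nodes()
        is_dup = any(mapping[c] is mapping[nd] for c in children)
        if is_dup:
            duplications.add(nd)
        for c in children:
            path = sp_depth[mapping[c]] - sp_depth[mapping[nd]]
            losses += path if is_dup else max(path - 1, 0)
    return ReconciliationResult(
        duplication_nodes=frozenset(duplications),
        n_duplications=len(duplications),
        n_losses=losses,
    )


def pic(tree: dendropy.Tree, traits: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    At each internal node with pruned children (x_i, v_i), (x_j, v_j):
    contrast = x_i - x_j with expected variance v_i + v_j; the ancestral
    value is the variance-weighted mean and the parent branch is
    lengthened by v_i * v_j / (v_i + v_j).  Requires a rooted binary
    tree and a trait value for every leaf.
    """
    _check_binary_rooted(tree, "tree")
    work = tree.clone(depth=1)
    n_tips = 0
    contrasts: list[tuple[float, float]] = []
    value: dict = {}
    variance: dict = {}
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            n_tips += 1
            label = nd.taxon.label
            if label not in traits:
                raise ValueError(f"missing trait value for leaf {label!r}")
            value[nd] = float(traits[label])
            variance[nd] = nd.edge.length or 0.0
        else:
            c1, c2 = nd.child_nodes()
            v1, v2 = variance[c1], variance[c2]
            if v1 + v2 <= 0:
                raise ValueError("zero summed branch variance at a contrast")
            contrasts.append((value[c1] - value[c2], v1 + v2))
            value[nd] = (v2 * value[c1] + v1 * value[c2]) / (v1 + v2)
            variance[nd] = (nd.edge.length or 0.0) + v1 * v2 / (v1 + v2)
    return ContrastSet(contrasts=contrasts, n_tips=n_tips)


def regress(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> RegressionResult:
    """Ordinary least squares of y on x.

    Adjusted R-squared is 1-(1-R²)(n-1)/(n-2) with an intercept and
    1-(1-R²)·n/(n-1) through the origin; the p-value is the slope
    t-test.  Contrast regressions must go through the origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need >= 3 paired observations")
    design = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    if through_origin:
        slope, intercept = fit.params[0], None
        r2 = float(fit.rsquared)  # uncentered
        adj = 1 - (1 - r2) * n / (n - 1)
        p = float(fit.pvalues[0])
    else:
        intercept, slope = fit.params
        r2 = float(fit.rsquared)
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        p = float(fit.pvalues[1])
    return RegressionResult(
        slope=float(slope),
        intercept=None if intercept is None else float(intercept),
        r_squared=r2,
        adjusted_r_squared=adj,
        p_value=p,
        n=n,
    )
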