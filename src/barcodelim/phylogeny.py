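"""Distance-based phylogenetics: Kimura 2-parameter distances with pairwise
deletion, Neighbor-Joining, nonparametric bootstrap, outgroup rooting and
monophyly testing.

The K2P distance distinguishes transitions (A<->G, C<->T; proportion P)
from transversions (proportion Q):

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Columns where either sequence of a pair carries a gap, ``?`` or an IUPAC
ambiguity code are removed for that pair (pairwise deletion); ambiguity
codes are treated as missing data here, as distance software commonly does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment_io import Alignment
from .errors import (
    ContractViolation,
    RootingError,
    SaturationError,
    UndefinedDistanceError,
)

__all__ = [
    "DistanceMatrix",
    "k2p_distance",
    "k2p_from_counts",
    "distance_matrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "root_with_outgroup",
    "is_monophyletic",
    "locus_concordance",
]

logger = logging.getLogger(__name__)

_NUC = frozenset("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with per-pair effective sites."""

    labels: list[str]
    d: np.ndarray
    n_sites: np.ndarray = field(default=None)  # columns surviving deletion

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])


def k2p_from_counts(n: int, transitions: int, transversions: int) -> float:
    """Evaluate the K2P formula from raw counts over n compared sites."""
    if n == 0:
        raise UndefinedDistanceError("no sites survive pairwise deletion")
    P = transitions / n
    Q = transversions / n
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (P={P:.4f}, Q={Q:.4f}): divergence beyond "
            "the model's valid range"
        )
    return -0.5 * math.log(a * math.sqrt(b))


def _pair_counts(row_i: str, row_j: str) -> tuple[int, int, int]:
    n = ts = tv = 0
    for x, y in zip(row_i, row_j):
        if x not in _NUC or y not in _NUC:
            continue
        n += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(row_i: str, row_j: str, labels: tuple[str, str] | None = None) -> float:
    """K2P distance between two aligned character rows, with pairwise
    deletion of columns carrying gaps, ``?`` or ambiguity codes."""
    if len(row_i) != len(row_j):
        raise ContractViolation("rows must have equal length")
    n, ts, tv = _pair_counts(row_i, row_j)
    try:
        return k2p_from_counts(n, ts, tv)
    except (UndefinedDistanceError, SaturationError) as exc:
        if labels:
            raise type(exc)(f"pair ({labels[0]}, {labels[1]}): {exc}") from None
        raise


def _encode(alignment: Alignment) -> np.ndarray:
    """Integer-encode rows (A=0, G=1, C=2, T=3 so that code // 2 gives the
    purine/pyrimidine class); everything non-nucleotide -> -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate("AGCT"):
        lut[ord(ch)] = i
    mat = np.frombuffer(
        "".join(alignment.sequences).encode(), dtype=np.uint8
    ).reshape(alignment.n_strains, alignment.n_sites)
    return lut[mat]


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise K2P distances for an alignment."""
    if alignment.n_strains < 2:
        raise ContractViolation("need at least 2 strains")
    enc = _encode(alignment)
    m = alignment.n_strains
    d = np.zeros((m, m))
    n_sites = np.zeros((m, m), dtype=int)
    # purine/pyrimidine class: transitions stay within a class
    cls = enc // 2
    for i in range(m):
        n_sites[i, i] = int(np.sum(enc[i] >= 0))
        for j in range(i + 1, m):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            n = int(ok.sum())
            diff = ok & (enc[i] != enc[j])
            ts = int(np.sum(diff & (cls[i] == cls[j])))
            tv = int(diff.sum()) - ts
            try:
                dij = k2p_from_counts(n, ts, tv)
            except (UndefinedDistanceError, SaturationError) as exc:
                raise type(exc)(
                    f"pair ({alignment.strains[i]}, {alignment.strains[j]}): {exc}"
                ) from None
            d[i, j] = d[j, i] = dij
            n_sites[i, j] = n_sites[j, i] = n
    return DistanceMatrix(list(alignment.strains), d, n_sites)


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-Joining (Saitou & Nei) on a distance matrix.

    Ties in the Q-criterion are broken by the lexicographically smallest
    label pair (each cluster is represented by its smallest leaf label), so
    the result is deterministic.  Negative branch-length estimates are
    clamped to zero with the deficit transferred to the sister branch.
    Returns an unrooted tree with a basal trifurcation.
    """
    labels = matrix.labels
    m = len(labels)
    if m < 3:
        raise ContractViolation("NJ requires at least 3 labels")
    if not np.allclose(matrix.d, matrix.d.T, atol=1e-9):
        raise ContractViolation("distance matrix is not symmetric")

    taxon_ns = dendropy.TaxonNamespace(labels)
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(lab)
        nodes[lab] = node

    # active clusters keyed by representative (smallest member) label
    D: dict[frozenset[str], float] = {}
    active = sorted(labels)
    for i in range(m):
        for j in range(i + 1, m):
            D[frozenset((labels[i], labels[j]))] = float(matrix.d[i, j])

    def dist(a: str, b: str) -> float:
        return D[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_q = math.inf
        best_pair: tuple[str, str] | None = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                pair = (a, b) if a < b else (b, a)
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and (best_pair is None or pair < best_pair)
                ):
                    best_q = q
                    best_pair = pair
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
            la = max(la, 0.0)
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            D[frozenset((rep, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted(set(active) - {a, b} | {rep})
        nodes[rep] = parent

    # final trifurcation
    a, b, c = active
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    center = dendropy.Node()
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].edge.length = ln
        center.add_child(nodes[lab])

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an (un)rooted tree, each canonicalized to
    the side NOT containing the lexicographically smallest leaf label."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    result: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            result.add(side)
    return result


def bootstrap_support(
    alignment: Alignment, B: int = 1000, seed: int = 0
) -> tuple[dendropy.Tree, int]:
    """NJ tree on the full data with bootstrap support percentages.

    Columns are resampled with replacement ``B`` times; support of each
    internal edge of the full-data tree is the percentage of replicate
    trees containing the same bipartition.  Replicates in which any
    pairwise distance is undefined are redrawn (the count of redraws is
    returned and logged).  Supports are stored as internal-node labels.
    """
    if B < 1:
        raise ContractViolation("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = nj_tree(distance_matrix(alignment))
    target = bipartitions(base)
    counts = {bp: 0 for bp in target}
    L = alignment.n_sites
    redraws = 0
    done = 0
    while done < B:
        idx = rng.integers(0, L, size=L)
        seqs = ["".join(seq[i] for i in idx) for seq in alignment.sequences]
        rep = Alignment(
            alignment.locus, list(alignment.strains), seqs,
            ref_offset=alignment.ref_offset, ref_name=alignment.ref_name,
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep))
        except (UndefinedDistanceError, SaturationError):
            redraws += 1
            if redraws > 100 * B:
                raise
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1
    if redraws:
        logger.info("bootstrap: %d replicates redrawn", redraws)

    leaves = sorted(lf.taxon.label for lf in base.leaf_node_iter())
    ref, all_set = leaves[0], frozenset(leaves)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node is base.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side in counts and (node.edge.length or 0.0) > 0.0:
            node.label = str(int(round(100.0 * counts[side] / B)))
        else:
            # zero-length edges are unresolved; deterministic tie-breaking
            # would otherwise give them spurious full support
            node.label = "0"
    return base, redraws


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_strains: set[str]
) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup from the rest.

    The outgroup must be a single leaf or form one side of an existing
    bipartition; the root is placed at the midpoint of that edge.
    """
    tree = tree.clone(depth=1)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    outgroup = set(outgroup_strains)
    if not outgroup or not outgroup <= leaves:
        raise ContractViolation(
            f"outgroup strains not all in tree: {sorted(outgroup - leaves)}"
        )
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == outgroup or side == leaves - outgroup:
            target = node
            break
    if target is None:
        raise RootingError(
            f"outgroup {sorted(outgroup)} is not separated by a single edge"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(
        target.edge,
        length1=length / 2.0,
        length2=length / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def is_monophyletic(rooted_tree: dendropy.Tree, strain_set: set[str]) -> bool:
    """True iff some node's descendant-leaf set equals ``strain_set``.

    Singletons are always monophyletic.
    """
    strain_set = set(strain_set)
    if not strain_set:
        raise ContractViolation("strain set must be nonempty")
    leaves = {lf.taxon.label for lf in rooted_tree.leaf_node_iter()}
    unknown = strain_set - leaves
    if unknown:
        raise ContractViolation(f"strains not in tree: {sorted(unknown)}")
    if len(strain_set) == 1:
        return True
    for node in rooted_tree.preorder_node_iter():
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == strain_set:
            return True
        if len(side) < len(strain_set):
            continue
    return False


def locus_concordance(
    per_locus_trees: list[dendropy.Tree], clade_of_interest: set[str]
) -> float:
    """Fraction of rooted per-locus trees containing the given clade.

    A simple split-concordance summary (not a Bayesian concordance factor).
    """
    if not per_locus_trees:
        raise ContractViolation("need at least one tree")
    hits = sum(
        1 for t in per_locus_trees if is_monophyletic(t, clade_of_interest)
    )
    return hits / len(per_locus_trees)
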