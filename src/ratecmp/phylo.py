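"""Tree building and likelihood machinery.

Neighbor-joining (Saitou–Nei) with deterministic tie-breaking, bootstrap
bipartition supports, maximum-likelihood branch lengths on a fixed topology
under the K80 (Kimura two-parameter) substitution model via Felsenstein's
pruning algorithm, and sampling of well-supported orthologous clades from
gene-family trees.

Trees are :class:`dendropy.Tree` objects throughout; internal node labels
carry bootstrap supports (percentages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignio import CodonAlignment
from .distances import DistanceMatrix

__all__ = [
    "nj_tree",
    "bootstrap_support",
    "ml_branch_lengths",
    "sample_clades",
    "CladeSample",
    "read_newick",
    "write_newick",
    "tip_path_length",
    "k80_pmatrix",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal node labels are kept (supports)."""
    src = Path(source)
    if src.exists():
        return dendropy.Tree.get(path=str(src), schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Write Newick with branch lengths and internal-node support labels."""
    s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(s)
    return s


def tip_path_length(tree: dendropy.Tree, tip_a: str, tip_b: str) -> float:
    """Sum of branch lengths on the path between two named tips."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(tip_a)
    tb = tree.taxon_namespace.get_taxon(tip_b)
    return pdm.distance(ta, tb)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined; ties
    go to the lowest (row, column) index pair.  Negative estimated branch
    lengths are clamped to zero with the deficit transferred to the sister
    branch.  The returned tree is unrooted (trifurcating seed node) for
    four or more taxa.
    """
    if dm.any_undefined:
        raise ValueError("distance matrix contains undefined entries")
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        taxon = tns.new_taxon(label=lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    D = dm.values.copy()
    active = list(range(n0))
    # matrix grows as new internal nodes are appended
    size = 2 * n0
    big = np.zeros((size, size))
    big[:n0, :n0] = D
    nxt = n0
    all_nodes = list(nodes)

    while len(active) > 3:
        m = len(active)
        sub = big[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) on ties: argmin of flattened array scans row-major
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vj += vi
            vi = 0.0
        if vj < 0.0:
            vi += vj
            vj = 0.0
        ni, nj = all_nodes[active[i]], all_nodes[active[j]]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = vi
        nj.edge.length = vj
        all_nodes.append(parent)
        # distances from the new node
        du = 0.5 * (big[active, active[i]] + big[active, active[j]] - dij)
        big[nxt, active] = du
        big[active, nxt] = du
        big[nxt, nxt] = 0.0
        active[i] = nxt  # new node takes the smaller slot, order stable
        del active[j]
        nxt += 1

    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    a, b, c = active
    dab, dac, dbc = big[a, b], big[a, c], big[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for node, length in zip((a, b, c), (la, lb, lc)):
        child = all_nodes[node]
        root.add_child(child)
        child.edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def encode_alignment(aln: CodonAlignment) -> tuple[list[str], np.ndarray]:
    """Record ids and an (n_records, length) int8 code matrix (-1 = other)."""
    labels = [rid for rid, _, _ in aln.records]
    arr = np.full((aln.n_records, len(aln)), -1, dtype=np.int8)
    for k, (_, _, seq) in enumerate(aln.records):
        for j, ch in enumerate(seq):
            arr[k, j] = _CODE.get(ch, -1)
    return labels, arr


def k2p_matrix_from_codes(labels: Sequence[str], codes: np.ndarray) -> DistanceMatrix:
    """Vectorized K2P distance matrix from an integer-coded alignment."""
    n = codes.shape[0]
    vals = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            nn = int(ok.sum())
            if nn == 0:
                raise ValueError("no comparable sites")
            diff = ok & (a != b)
            ts = int((diff & (_TS_PARTNER[np.clip(a, 0, 3)] == b)).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / nn, tv / nn
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                vals[i, j] = vals[j, i] = np.nan
                sat[i, j] = sat[j, i] = True
            else:
                vals[i, j] = vals[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceMatrix(list(labels), vals, sat)


def bootstrap_support(
    aln: CodonAlignment, n_reps: int, seed: int, metric: str = "d"
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Nucleotide columns are resampled with replacement per replicate; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicates whose NJ tree contains it.  Replicates whose
    distance matrix has a saturated entry are discarded (counted in
    ``tree.n_discarded_reps``).  Deterministic given *seed*.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if metric != "d":
        raise ValueError("only the K2P metric 'd' is supported for bootstrapping")
    labels, codes = encode_alignment(aln)
    L = codes.shape[1]
    full = nj_tree(k2p_matrix_from_codes(labels, codes))
    full_bips = _label_bipartitions(full)
    counts = {key: 0 for key in full_bips}
    rng = np.random.default_rng(seed)
    discarded = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        dm = k2p_matrix_from_codes(labels, codes[:, cols])
        if dm.any_undefined:
            discarded += 1
            continue
        rep = nj_tree(dm)
        rep_bips = set(_label_bipartitions(rep))
        used += 1
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    denom = max(used, 1)
    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        key = _node_bipartition_key(node, set(labels))
        if key in counts:
            support = 100.0 * counts[key] / denom
            node.label = f"{support:g}"
            node.support = support
    full.n_discarded_reps = discarded
    return full


def _node_bipartition_key(node: dendropy.Node, all_labels: set[str]) -> frozenset:
    side = frozenset(lf.taxon.label for lf in node.leaf_iter())
    other = frozenset(all_labels - side)
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def _label_bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions keyed by the canonical smaller label set."""
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(all_labels - side) < 2:
            continue
        out[_node_bipartition_key(node, all_labels)] = node
    return out


# ---------------------------------------------------------------------------
# ML branch lengths (K80 pruning)


def k80_pmatrix(d: float, kappa: float) -> np.ndarray:
    """K80 transition-probability matrix for branch length *d* (subs/site).

    State order A, C, G, T; *kappa* is the transition/transversion rate
    ratio alpha/beta.
    """
    if d <= 0:
        return np.eye(4)
    b = d / (kappa + 2.0)
    a = kappa * b
    e1 = math.exp(-4.0 * b)
    e2 = math.exp(-2.0 * (a + b))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    M = np.full((4, 4), p_tv)
    for i in range(4):
        M[i, i] = p_same
        M[i, _TS_PARTNER[i]] = p_ts
    return M


class _PruningLikelihood:
    """Site-pattern log-likelihood for a fixed topology under K80."""

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree):
        labels, codes = encode_alignment(aln)
        keep = np.all(codes >= 0, axis=0)
        codes = codes[:, keep]
        if codes.shape[1] == 0:
            raise ValueError("no fully resolved columns for likelihood")
        # compress to unique site patterns
        patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
        self.counts = counts.astype(float)
        self.tree = tree
        self.postorder = list(tree.postorder_node_iter())
        tip_index = {lab: k for k, lab in enumerate(labels)}
        self.tip_partials: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if node.is_leaf():
                lab = node.taxon.label
                if lab not in tip_index:
                    raise ValueError(f"topology tip {lab!r} not in alignment")
                states = patterns[:, tip_index[lab]]
                part = np.zeros((len(counts), 4))
                part[np.arange(len(counts)), states] = 1.0
                self.tip_partials[id(node)] = part

    def log_likelihood(self, kappa: float) -> float:
        partials: dict[int, np.ndarray] = {}
        for node in self.postorder:
            if node.is_leaf():
                p = self.tip_partials[id(node)]
            else:
                p = np.ones((len(self.counts), 4))
                for child in node.child_nodes():
                    M = k80_pmatrix(child.edge.length or 0.0, kappa)
                    p = p * (partials[id(child)] @ M.T)
            partials[id(node)] = p
        root = partials[id(self.postorder[-1])]
        site_l = 0.25 * root.sum(axis=1)
        site_l = np.maximum(site_l, 1e-300)
        return float(np.dot(self.counts, np.log(site_l)))


def ml_branch_lengths(
    aln: CodonAlignment,
    topology: dendropy.Tree,
    kappa: float | str = 2.0,
    tol: float = 1e-8,
    max_sweeps: int = 50,
    max_branch: float = 20.0,
) -> dendropy.Tree:
    """Maximum-likelihood branch lengths on a fixed topology under K80.

    Coordinate sweeps optimize one branch at a time (bounded Brent,
    lengths >= 0); convergence when the log-likelihood improves by less
    than *tol* between sweeps.  ``kappa="estimate"`` profiles the
    transition/transversion ratio alongside the lengths.  The returned
    clone of *topology* carries ``log_likelihood``, ``kappa`` and
    ``converged`` attributes.  A basal bifurcation is collapsed first, so
    for three or more taxa every optimized edge is identifiable; with
    exactly two taxa only the tip-to-tip total is identifiable and it is
    split evenly between the two terminal edges.
    """
    tree = topology.clone(depth=1)
    n_tips = len(tree.leaf_nodes())
    if n_tips >= 3:
        tree.collapse_basal_bifurcation()
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < 0:
            edge.length = 0.05
    lik = _PruningLikelihood(aln, tree)

    two_taxon = n_tips == 2
    edges = [
        nd.edge
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
    ]

    kap = 2.0 if kappa == "estimate" else float(kappa)

    if two_taxon:
        e1, e2 = edges

        def nll_total(t: float, k: float) -> float:
            e1.length = t / 2.0
            e2.length = t / 2.0
            return -lik.log_likelihood(k)

        prev = -nll_total(e1.length + e2.length, kap)
        converged = False
        for _ in range(max_sweeps):
            res = minimize_scalar(
                lambda t: nll_total(t, kap), bounds=(0.0, max_branch), method="bounded",
                options={"xatol": 1e-12},
            )
            nll_total(res.x, kap)
            if kappa == "estimate":
                rk = minimize_scalar(
                    lambda lk: nll_total(e1.length + e2.length, math.exp(lk)),
                    bounds=(math.log(0.02), math.log(100.0)),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                kap = math.exp(rk.x)
            cur = lik.log_likelihood(kap)
            if abs(cur - prev) < tol:
                converged = True
                break
            prev = cur
    else:
        prev = lik.log_likelihood(kap)
        converged = False
        for _ in range(max_sweeps):
            for edge in edges:
                def nll(x: float, e=edge) -> float:
                    e.length = x
                    return -lik.log_likelihood(kap)

                res = minimize_scalar(
                    nll, bounds=(0.0, max_branch), method="bounded",
                    options={"xatol": 1e-10},
                )
                edge.length = float(res.x)
            if kappa == "estimate":
                def nll_k(logk: float) -> float:
                    return -lik.log_likelihood(math.exp(logk))

                rk = minimize_scalar(
                    nll_k, bounds=(math.log(0.02), math.log(100.0)),
                    method="bounded", options={"xatol": 1e-10},
                )
                kap = math.exp(rk.x)
            cur = lik.log_likelihood(kap)
            if cur - prev < tol:
                converged = True
                break
            prev = cur

    tree.log_likelihood = lik.log_likelihood(kap)
    tree.kappa = kap
    tree.converged = converged
    return tree


# ---------------------------------------------------------------------------
# Clade sampling


@dataclass
class CladeSample:
    """A well-supported orthologous clade with its outgroup proxy.

    ``member_tips`` are the tip labels inside the clade; ``outgroup_tips``
    the nearest neighboring homologs outside it (sister-group tips by
    default, widened by ``radius``).
    """

    member_tips: list[str]
    species_coverage: set[str]
    support: float
    outgroup_tips: list[str]


def _tip_species(label: str) -> str:
    return label.rpartition("|")[2] if "|" in label else label


def sample_clades(
    gene_tree: dendropy.Tree,
    required_species: Iterable[str],
    support_min: float = 50.0,
    radius: int = 1,
) -> list[CladeSample]:
    """Maximal monophyletic clades covering *required_species*.

    A clade qualifies when its subtending edge support is strictly greater
    than *support_min* and its tip species set covers the required species.
    Only maximal qualifying clades are returned (no qualifying ancestor).
    Outgroup tips are collected from sister groups, walking up *radius*
    ancestors.
    """
    required = set(required_species)
    for lf in gene_tree.leaf_node_iter():
        if lf.taxon is None or not lf.taxon.label:
            raise ValueError("tree has unlabeled tips")

    def support_of(node: dendropy.Node) -> float | None:
        lab = node.label
        if lab is None and getattr(node, "taxon", None) is not None and node.taxon:
            lab = node.taxon.label
        try:
            return float(lab)
        except (TypeError, ValueError):
            return None

    def qualifies(node: dendropy.Node) -> bool:
        if node.is_leaf() or node.parent_node is None:
            return False
        sup = support_of(node)
        if sup is None or not (sup > support_min):
            return False
        species = {_tip_species(lf.taxon.label) for lf in node.leaf_iter()}
        return species >= required

    samples: list[CladeSample] = []
    for node in gene_tree.preorder_node_iter():
        if not qualifies(node):
            continue
        anc = node.parent_node
        has_qualifying_ancestor = False
        while anc is not None:
            if qualifies(anc):
                has_qualifying_ancestor = True
                break
            anc = anc.parent_node
        if has_qualifying_ancestor:
            continue
        members = [lf.taxon.label for lf in node.leaf_iter()]
        member_set = set(members)
        outgroup: list[str] = []
        cur = node
        for _ in range(radius):
            parent = cur.parent_node
            if parent is None:
                break
            for sib in parent.child_nodes():
                if sib is cur:
                    continue
                outgroup.extend(
                    lf.taxon.label
                    for lf in sib.leaf_iter()
                    if lf.taxon.label not in member_set
                )
            cur = parent
        samples.append(
            CladeSample(
                member_tips=members,
                species_coverage={_tip_species(t) for t in members},
                support=support_of(node),
                outgroup_tips=outgroup,
            )
        )
    return samples
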