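"""Subgroup classification: sequence similarity graph + Markov clustering,
neighbor-joining phylogeny of intact NB domains with bootstrap support, and
the reconciliation of the two into subgroup labels.

The classification integrates three sources of evidence:

1. all-by-all local (Smith--Waterman) protein similarity, thresholded and
   clustered with MCL (inflation 1.5);
2. a neighbor-joining tree of the intact NB domains (JTT distances,
   bootstrap supports; branches below 50% support collapsed);
3. best-hit assignment of leftover singletons/partial genes against the
   already-labeled set.

Clusters whose members fall under the same supported clade of the tree are
merged into one subgroup (the tree arbitrates when similarity clustering
oversplits); genes absent from both go to ``none-grouping``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord, RunConfig

logger = logging.getLogger(__name__)

NONE_GROUP = "none-grouping"

# ---------------------------------------------------------------------------
# Pairwise local alignment
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    match_frac_a: float
    match_frac_b: float
    start_a: int = 0  # 0-based start of the local alignment in sequence a
    start_b: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings of unequal length")

    @property
    def identity(self) -> float:
        """Fraction of aligned columns with identical residues."""
        if not self.aligned_a:
            return 0.0
        same = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )
        return same / len(self.aligned_a)


def _make_aligner(matrix=None, gap_open: float = -11.0, gap_extend: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(a: ProteinRecord | str, b: ProteinRecord | str,
                matrix=None, gap_open: float = -11.0,
                gap_extend: float = -1.0) -> PairwiseAlignment:
    """Optimal Smith--Waterman local alignment under affine gap costs.

    Ties are broken deterministically (the aligner's first reported optimum,
    which is the earliest-starting path).  Sequences with no positively
    scoring alignment return an empty alignment with score 0.
    """
    id_a, seq_a = (a.id, a.sequence) if isinstance(a, ProteinRecord) else ("a", a)
    id_b, seq_b = (b.id, b.sequence) if isinstance(b, ProteinRecord) else ("b", b)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return PairwiseAlignment(id_a, id_b, "", "", 0.0, 0.0, 0.0)
    aln = next(iter(aligner.align(seq_a, seq_b)))
    ga, gb = str(aln[0]), str(aln[1])
    cov_a = sum(1 for c in ga if c != "-") / len(seq_a)
    cov_b = sum(1 for c in gb if c != "-") / len(seq_b)
    return PairwiseAlignment(id_a, id_b, ga, gb, float(score), cov_a, cov_b,
                             int(aln.coordinates[0][0]), int(aln.coordinates[1][0]))


def self_score(seq: str, matrix=None) -> float:
    m = matrix if matrix is not None else _BLOSUM62
    alpha = m.alphabet
    return float(sum(m[alpha.index(c), alpha.index(c)] for c in seq if c in alpha))


# ---------------------------------------------------------------------------
# Similarity graph and Markov clustering
# ---------------------------------------------------------------------------

def build_similarity_graph(proteins: list[ProteinRecord],
                           config: RunConfig) -> nx.Graph:
    """All-by-all local-alignment similarity graph.

    An edge is kept iff the SW score normalized by the self-score of the
    shorter sequence reaches ``config.sim_evalue_like_cutoff`` (the score
    threshold standing in for a BLAST E-value cutoff) *and* the alignment
    covers at least ``config.min_match_frac`` of both sequences.  Edge weight
    is the normalized score (1.0 for identical sequences).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to build a similarity graph")
    graph = nx.Graph()
    graph.add_nodes_from(p.id for p in proteins)
    selfs = {p.id: self_score(p.sequence) for p in proteins}
    for i, pa in enumerate(proteins):
        for pb in proteins[i + 1:]:
            aln = local_align(pa, pb)
            if aln.score <= 0:
                continue
            shorter = pa.id if len(pa) <= len(pb) else pb.id
            weight = aln.score / max(selfs[shorter], 1e-9)
            if weight >= config.sim_evalue_like_cutoff and \
                    min(aln.match_frac_a, aln.match_frac_b) >= config.min_match_frac:
                graph.add_edge(pa.id, pb.id, weight=min(weight, 1.0))
    return graph


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5,
                tol: float = 1e-6, max_iter: int = 200) -> list[set[str]]:
    """Markov clustering of a weighted similarity graph.

    Column-normalizes the weight matrix with unit self-loops, then iterates
    expansion (matrix squaring) and inflation (elementwise power followed by
    renormalization) until the matrix changes by less than ``tol`` or
    ``max_iter`` rounds.  Clusters are the attractor components; singletons
    are allowed and disconnected components are never merged.
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        M[M < 1e-12] = 0.0
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; returning current partition",
                       max_iter)

    # attractors: rows with mass on the diagonal; cluster = attractor row support
    comp = nx.Graph()
    comp.add_nodes_from(range(n))
    for i in range(n):
        if M[i, i] > 1e-6:
            for j in np.nonzero(M[i] > 1e-6)[0]:
                comp.add_edge(i, int(j))
    clusters = [
        {nodes[i] for i in cc} for cc in nx.connected_components(comp)
    ]
    clusters.sort(key=lambda s: (-len(s), min(s)))
    return clusters


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    """An (implicitly rooted representation of an) unrooted tree with branch
    lengths and optional bootstrap supports on internal nodes."""

    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the smaller side
        (ties broken lexicographically)."""
        all_leaves = self.leaf_names()
        out = set()
        for node in self.internal_nodes():
            side = node.leaf_names()
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(_canonical_side(side, other))
        return out

    def collapse_zero_branches(self, eps: float = 1e-12) -> None:
        """Collapse internal branches of (near-)zero length — arbitrary
        resolutions of unresolvable splits (e.g. identical sequences)."""

        def walk(node: TreeNode) -> None:
            new_children: list[TreeNode] = []
            for child in node.children:
                walk(child)
                if not child.is_leaf and child.length <= eps:
                    new_children.extend(child.children)
                else:
                    new_children.append(child)
            node.children = new_children

        walk(self.root)

    def collapse_below(self, min_support: float) -> None:
        """Collapse internal branches whose support is below ``min_support``
        (children are re-attached to the grandparent)."""

        def walk(node: TreeNode) -> None:
            new_children: list[TreeNode] = []
            for child in node.children:
                walk(child)
                if (not child.is_leaf and child.support is not None
                        and child.support < min_support):
                    new_children.extend(child.children)
                else:
                    new_children.append(child)
            node.children = new_children

        walk(self.root)

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = "" if node.support is None else f"{node.support:.2f}"
            return f"({inner}){sup}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _canonical_side(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return a if min(a) < min(b) else b


# ---------------------------------------------------------------------------
# JTT protein distances
# ---------------------------------------------------------------------------

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Empirical JTT amino-acid exchangeabilities (column-major lower triangle in
# the ARNDCQEGHILKMFPSTWYV order) and equilibrium frequencies.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11, 298,
    45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20, 17, 528,
    34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70, 16, 10, 49, 767,
    130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5, 59, 69, 17, 23,
    7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53,
    51, 18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6,
    6, 27, 14, 5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8,
    573, 11, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52,
    24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92,
    12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
_JTT_FREQ = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])


def _jtt_matrices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """JTT rate-matrix eigendecomposition, cached.  Returns
    ``(eigvals, left, right)`` such that ``P(t) = left @ diag(exp(l t)) @ right``."""
    S = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for j in range(19):
        for i in range(j + 1, 20):
            v = float(next(it))
            S[i, j] = S[j, i] = v
    pi = _JTT_FREQ / _JTT_FREQ.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -np.sum(pi * np.diag(Q))  # 1 expected substitution per site per unit t
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    B = (B + B.T) / 2.0
    eigvals, vecs = np.linalg.eigh(B)
    left = vecs / sq[:, None]
    right = (vecs * sq[:, None]).T
    return eigvals, left, right


_JTT_CACHE = _jtt_matrices()

# sanity: the lower triangle above must hold exactly 190 exchangeabilities
assert len(_JTT_LOWER) == 190


def _jtt_logP(t_grid: np.ndarray) -> np.ndarray:
    """log transition matrices for every t on the grid, flattened to
    shape (len(grid), 400)."""
    eigvals, left, right = _JTT_CACHE
    out = np.empty((len(t_grid), 400))
    for k, t in enumerate(t_grid):
        P = (left * np.exp(eigvals * t)) @ right
        np.clip(P, 1e-300, None, out=P)
        out[k] = np.log(P).ravel()
    return out


_T_GRID = np.exp(np.linspace(np.log(1e-4), np.log(8.0), 220))
_LOGP_GRID = _jtt_logP(_T_GRID)

MIN_SHARED_COLUMNS = 50


def encode_alignment(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode a gapped protein alignment as an integer matrix (gap/X = -1)."""
    ids = list(alignment)
    L = len(next(iter(alignment.values())))
    enc = np.full((len(ids), L), -1, dtype=np.int16)
    for r, gid in enumerate(ids):
        row = alignment[gid]
        if len(row) != len(next(iter(alignment.values()))):
            raise ValueError("ragged alignment")
        for c, ch in enumerate(row):
            enc[r, c] = _AA_INDEX.get(ch, -1)
    return ids, enc


def protein_distance_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray, set[tuple[str, str]]]:
    """Pairwise ML distances under the JTT model from a multiple alignment.

    Gaps (and X) are pairwise-deleted.  Each pairwise distance maximizes the
    likelihood of the observed residue pairs over branch length ``t`` on a
    log-spaced grid with quadratic refinement around the optimum — accurate
    to well below the stochastic error of any realistic alignment.

    Returns ``(ids, D, unreliable)`` where *unreliable* holds id pairs with
    fewer than 50 shared (ungapped) columns.
    """
    ids, enc = encode_alignment(alignment)
    n = len(ids)
    D = np.zeros((n, n))
    unreliable: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            mask = (enc[i] >= 0) & (enc[j] >= 0)
            shared = int(mask.sum())
            if shared == 0:
                D[i, j] = D[j, i] = np.nan
                unreliable.add((ids[i], ids[j]))
                continue
            if shared < MIN_SHARED_COLUMNS:
                unreliable.add((ids[i], ids[j]))
            flat = enc[i][mask].astype(np.int64) * 20 + enc[j][mask]
            counts = np.bincount(flat, minlength=400).astype(float)
            ll = _LOGP_GRID @ counts
            k = int(np.argmax(ll))
            t = _T_GRID[k]
            if 0 < k < len(_T_GRID) - 1:
                # quadratic refinement in log t
                x0, x1, x2 = np.log(_T_GRID[k - 1: k + 2])
                y0, y1, y2 = ll[k - 1: k + 2]
                denom = (y0 - 2 * y1 + y2)
                if denom < 0:
                    x = x1 - 0.5 * (x2 - x0) * (y2 - y0) / (2 * denom)
                    t = float(np.exp(np.clip(x, x0, x2)))
            if k == 0 and np.all(enc[i][mask] == enc[j][mask]):
                t = 0.0
            D[i, j] = D[j, i] = t
    return ids, D, unreliable


# ---------------------------------------------------------------------------
# Neighbor joining and UPGMA
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, ids: list[str]) -> Tree:
    """Saitou--Nei neighbor joining with deterministic tie-breaking (lowest
    index pair) and negative branch lengths clamped to zero, the deficit
    moved to the sister branch.

    With fewer than 3 taxa the trivial/star tree is returned.
    """
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    nodes = [TreeNode(name=i) for i in ids]
    if n == 1:
        return Tree(root=nodes[0])
    if n == 2:
        root = TreeNode()
        nodes[0].length = nodes[1].length = float(D[0, 1]) / 2.0
        root.children = nodes
        return Tree(root=root)

    D = D.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.children = [nodes[i], nodes[j]]
        # reuse slot i for the new node
        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_d
        D[active, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = float(max(length, 0.0))
        root.children.append(node)
    return Tree(root=root)


def upgma_tree(D: np.ndarray, ids: list[str]) -> Tree:
    """UPGMA (average-linkage, ultrametric) tree; used for comparison with
    NJ on ultrametric inputs and for family dendrograms."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(ids)
    if n == 1:
        return Tree(root=TreeNode(name=ids[0]))
    Z = linkage(squareform(D, checks=False), method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=ids[i]), 0.0) for i in range(n)
    }
    for k, (a, b, height, _cnt) in enumerate(Z):
        na, ha = nodes[int(a)]
        nb, hb = nodes[int(b)]
        na.length = float(height / 2.0 - ha)
        nb.length = float(height / 2.0 - hb)
        parent = TreeNode(children=[na, nb])
        nodes[n + k] = (parent, height / 2.0)
    root = nodes[n + len(Z) - 1][0]
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Progressive multiple alignment of NB domains
# ---------------------------------------------------------------------------

_PROFILE_ALPHA = AA_ORDER + "-"
_PM = np.full((21, 21), -4.0)
for _i, _a in enumerate(AA_ORDER):
    for _j, _b in enumerate(AA_ORDER):
        _PM[_i, _j] = _BLOSUM62[_BLOSUM62.alphabet.index(_a), _BLOSUM62.alphabet.index(_b)]
_PM[20, 20] = 0.0  # gap against gap
_GAP_COLUMN = -8.0


def _to_profile(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for row in rows:
        for c, ch in enumerate(row):
            prof[c, _AA_INDEX.get(ch, 20) if ch != "-" else 20] += 1.0
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (linear gap penalty); returns the two
    input blocks re-gapped to a common length."""
    pa, pb = _to_profile(rows_a), _to_profile(rows_b)
    La, Lb = len(pa), len(pb)
    S = pa @ _PM @ pb.T
    F = np.zeros((La + 1, Lb + 1))
    F[1:, 0] = _GAP_COLUMN * np.arange(1, La + 1)
    F[0, 1:] = _GAP_COLUMN * np.arange(1, Lb + 1)
    ptr = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, La + 1):
        diag = F[i - 1, :-1] + S[i - 1]
        up = F[i - 1, 1:] + _GAP_COLUMN
        row = F[i]
        prev_ptr = ptr[i]
        for j in range(1, Lb + 1):
            best = diag[j - 1]
            move = 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            left = row[j - 1] + _GAP_COLUMN
            if left > best:
                best, move = left, 2
            row[j] = best
            prev_ptr[j] = move
    # traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = La, Lb
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i -= 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            j -= 1
    return (["".join(reversed(x)) for x in out_a],
            ["".join(reversed(x)) for x in out_b])


def progressive_msa(records: list[ProteinRecord]) -> dict[str, str]:
    """Progressive multiple alignment along a neighbor-joining guide tree of
    pairwise local-alignment distances.

    Profiles are merged in the NJ join order; adequate for the conserved NB
    domains this package aligns (it is not a general-purpose MSA).
    """
    if not records:
        return {}
    if len(records) == 1:
        return {records[0].id: records[0].sequence}
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(records[i], records[j])
            ident = aln.identity if aln.aligned_a else 0.0
            cover = min(aln.match_frac_a, aln.match_frac_b)
            D[i, j] = D[j, i] = 1.0 - ident * cover

    # merge profiles following the NJ agglomeration schedule
    blocks: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].sequence]) for i in range(n)
    }
    Dw = D.copy()
    active = list(range(n))
    while len(active) > 1:
        m = len(active)
        if m > 2:
            sub = Dw[np.ix_(active, active)]
            r = sub.sum(axis=1)
            q = (m - 2) * sub - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            flat = int(np.argmin(q))
            ai, aj = divmod(flat, m)
        else:
            ai, aj = 0, 1
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        ids_a, rows_a = blocks[i]
        ids_b, rows_b = blocks[j]
        new_a, new_b = _align_profiles(rows_a, rows_b)
        blocks[i] = (ids_a + ids_b, new_a + new_b)
        new_d = 0.5 * (Dw[i, active] + Dw[j, active])
        Dw[i, active] = new_d
        Dw[active, i] = new_d
        Dw[i, i] = 0.0
        active.remove(j)
        del blocks[j]
    ids, rows = blocks[active[0]]
    return dict(zip(ids, rows))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_tree(alignment: dict[str, str], reps: int, seed: int,
                   config: RunConfig | None = None) -> Tree:
    """Neighbor-joining tree with bootstrap supports.

    Columns are resampled with replacement per replicate (independent RNG
    streams derived from ``(seed, replicate)`` so runs are reproducible and
    order-independent); the support of each internal branch of the original
    tree is the fraction of replicates reproducing its bipartition.
    Branches below ``config.collapse_support`` are collapsed.
    """
    config = config or RunConfig()
    ids, enc = encode_alignment(alignment)
    L = enc.shape[1]
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    base_ids, D, _ = protein_distance_matrix(alignment)
    tree = neighbor_joining(np.nan_to_num(D, nan=np.nanmax(D[np.isfinite(D)]) if np.isfinite(D).any() else 1.0), base_ids)
    tree.collapse_zero_branches()
    target = {node: node.leaf_names() for node in tree.internal_nodes()}
    all_leaves = tree.leaf_names()
    counts = {node: 0 for node in target}
    for rep in range(reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        sub = {gid: "".join(alignment[gid][c] for c in cols) for gid in ids}
        rids, Dr, _ = protein_distance_matrix(sub)
        Dr = np.nan_to_num(Dr, nan=8.0)
        rep_tree = neighbor_joining(Dr, rids)
        rep_biparts = rep_tree.bipartitions()
        for node, side in target.items():
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                counts[node] += 1  # trivial partitions are always present
                continue
            if _canonical_side(side, other) in rep_biparts:
                counts[node] += 1
    for node in target:
        node.support = counts[node] / reps if reps else None
    tree.collapse_below(config.collapse_support)
    return tree


# ---------------------------------------------------------------------------
# Subgroup assignment
# ---------------------------------------------------------------------------

@dataclass
class SubgroupAssignment:
    """gene id -> subgroup label, with per-gene provenance
    ({'cluster', 'tree', 'best-hit', 'none'})."""

    labels: dict[str, str]
    provenance: dict[str, str]

    def genes_in(self, subgroup: str) -> list[str]:
        return sorted(g for g, s in self.labels.items() if s == subgroup)

    @property
    def subgroups(self) -> list[str]:
        return sorted(set(self.labels.values()) - {NONE_GROUP})


def _supported_envelope(tree: Tree, leaves: frozenset[str],
                        min_support: float) -> frozenset[str] | None:
    """Smallest clade with bootstrap support >= ``min_support`` containing all
    of ``leaves``; None if only the (unsupported) root does."""
    best: frozenset[str] | None = None

    def walk(node: TreeNode) -> frozenset[str]:
        nonlocal best
        if node.is_leaf:
            return frozenset([node.name])
        names = frozenset()
        for c in node.children:
            names |= walk(c)
        if leaves <= names and node.support is not None and node.support >= min_support:
            if best is None or len(names) < len(best):
                best = names
        return names

    walk(tree.root)
    return best


def assign_subgroups(clusters: list[set[str]], tree: Tree,
                     full_type: dict[str, bool], config: RunConfig,
                     proteins: dict[str, ProteinRecord] | None = None,
                     reference_labels: dict[str, str] | None = None) -> SubgroupAssignment:
    """Integrate similarity clusters with the NB-domain phylogeny.

    1.  Each non-singleton cluster is anchored to the smallest tree clade with
        bootstrap support at or above ``config.subgroup_support`` that contains
        all of its full-type members (its *supported envelope*).
    2.  Clusters sharing the same supported envelope are the same phylogenetic
        subgroup and are merged under one label.
    3.  Remaining genes (singletons and genes absent from the tree) are
        assigned by best local-alignment hit against already-labeled genes,
        subject to the similarity/coverage thresholds; unresolvable genes get
        ``none-grouping``.

    Labels are ``G1..Gk`` by decreasing subgroup size unless
    ``reference_labels`` pins names (majority label of references present).
    """
    tree_leaves = tree.leaf_names()

    group_of_cluster: dict[int, int] = {}
    envelopes: dict[int, frozenset[str] | None] = {}
    for ci, cluster in enumerate(clusters):
        members_in_tree = frozenset(cluster) & tree_leaves
        if len(cluster) < 2 or not members_in_tree:
            continue
        envelopes[ci] = _supported_envelope(tree, members_in_tree, config.subgroup_support)

    env_to_group: dict[frozenset[str], int] = {}
    next_group = 0
    for ci in sorted(envelopes):
        env = envelopes[ci]
        if env is not None and env in env_to_group:
            group_of_cluster[ci] = env_to_group[env]
            continue
        group_of_cluster[ci] = next_group
        if env is not None:
            env_to_group[env] = next_group
        next_group += 1

    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    members_by_group: dict[int, set[str]] = {}
    for ci, gi in group_of_cluster.items():
        members_by_group.setdefault(gi, set()).update(clusters[ci])
    for gi, members in members_by_group.items():
        for g in members:
            labels[g] = f"__g{gi}"
            provenance[g] = "tree" if envelopes.get(_cluster_of(clusters, g)) else "cluster"

    # leftovers: singletons / unclustered / off-tree genes
    leftovers = sorted(
        {g for c in clusters for g in c} - set(labels)
    )
    labeled_ids = sorted(labels)
    for g in leftovers:
        best_label, best_weight = None, 0.0
        if proteins and g in proteins and labeled_ids:
            gseq = proteins[g]
            gself = self_score(gseq.sequence)
            for other in labeled_ids:
                if other not in proteins:
                    continue
                aln = local_align(gseq, proteins[other])
                shorter_self = min(gself, self_score(proteins[other].sequence))
                w = aln.score / max(shorter_self, 1e-9)
                if w > best_weight and w >= config.sim_evalue_like_cutoff and \
                        min(aln.match_frac_a, aln.match_frac_b) >= config.min_match_frac:
                    best_weight, best_label = w, labels[other]
        if best_label is not None:
            labels[g] = best_label
            provenance[g] = "best-hit"
        else:
            labels[g] = NONE_GROUP
            provenance[g] = "none"

    # final naming: references pin labels, otherwise G1..Gk by size
    final_name: dict[str, str] = {NONE_GROUP: NONE_GROUP}
    groups = sorted(
        {l for l in labels.values() if l != NONE_GROUP},
        key=lambda l: (-sum(1 for v in labels.values() if v == l), l),
    )
    used: set[str] = set()
    for l in groups:
        name = None
        if reference_labels:
            refs = [reference_labels[g] for g, v in labels.items()
                    if v == l and g in reference_labels]
            if refs:
                vals, cnts = np.unique(refs, return_counts=True)
                cand = str(vals[np.argmax(cnts)])
                if cand not in used:
                    name = cand
        if name is None:
            k = 1
            while f"G{k}" in used:
                k += 1
            name = f"G{k}"
        used.add(name)
        final_name[l] = name
    labels = {g: final_name[l] for g, l in labels.items()}
    return SubgroupAssignment(labels=labels, provenance=provenance)


def _cluster_of(clusters: list[set[str]], gene: str) -> int | None:
    for ci, c in enumerate(clusters):
        if gene in c:
            return ci
    return None


def backfill_nb_lineage(assignment: SubgroupAssignment, calls: dict) -> dict:
    """Resolve the TIR-vs-CC lineage of genes lacking N-terminal evidence from
    their subgroup: a subgroup whose members are majority-TIR confers the
    ``tir`` lineage, otherwise ``cc``.  Genes in ``none-grouping`` keep their
    lineage as-is.  Returns updated ArchitectureCall mapping (labels are
    recomputed from the decision table)."""
    from .motif_scan import relabel_with_lineage

    tir_frac: dict[str, float] = {}
    for sg in assignment.subgroups:
        members = assignment.genes_in(sg)
        with_call = [g for g in members if g in calls]
        if not with_call:
            continue
        tir_frac[sg] = sum(1 for g in with_call if calls[g].tir_present) / len(with_call)
    updated = dict(calls)
    for gene, sg in assignment.labels.items():
        if sg == NONE_GROUP or gene not in calls:
            continue
        lineage = "tir" if tir_frac.get(sg, 0.0) > 0.5 else "cc"
        updated[gene] = relabel_with_lineage(calls[gene], lineage)
    return updated
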