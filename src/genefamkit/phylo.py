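"""Distance phylogenetics: pairwise identity, progressive alignment,
Poisson-corrected distances, neighbor joining and bootstrap support.

Pairwise global alignment is Needleman–Wunsch with affine gaps through
Biopython's PairwiseAligner (BLOSUM62, gap open 10 / extend 0.5 by
default).  The multiple aligner is a deliberately simple progressive
aligner — UPGMA guide tree on identity distances, profile–profile
dynamic programming — adequate for the conserved families this toolkit
targets; externally produced alignments can be supplied instead.

Neighbor joining follows Saitou & Nei with the Q-criterion, ties broken
by the lexicographically smallest joined pair, and negative branch
lengths clamped to zero with the deficit moved to the sibling edge so
the pair's total is preserved.  Supports come from column-resampling
bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode

GAP = "-"


# ---------------------------------------------------------------------------
# pairwise alignment


def _make_aligner(matrix: str | None, gap_open: float, gap_extend: float,
                  match: float | None, mismatch: float | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix or "BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str | None = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    match: float | None = None,
    mismatch: float | None = None,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns the two gapped rows and the percent identity, defined as
    100 x (identical columns) / (alignment columns), gap columns counted
    in the denominator.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, match, mismatch)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return row_a, row_b, 100.0 * matches / len(row_a)


def percent_identity(a: str, b: str, **kwargs) -> float:
    return global_align(a, b, **kwargs)[2]


def filter_by_identity(
    sequences: dict[str, str], threshold: float = 50.0, **align_kwargs
) -> dict[str, str]:
    """Retain sequences whose best identity to any other input sequence
    reaches the threshold.  A singleton input is retained as-is."""
    names = list(sequences)
    if len(names) <= 1:
        return dict(sequences)
    best = {n: 0.0 for n in names}
    for x, y in itertools.combinations(names, 2):
        ident = percent_identity(sequences[x], sequences[y], **align_kwargs)
        best[x] = max(best[x], ident)
        best[y] = max(best[y], ident)
    return {n: sequences[n] for n in names if best[n] >= threshold}


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, name: str) -> str:
        return self.rows[self.names.index(name)].replace(GAP, "")

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def take_columns(self, idx) -> "Msa":
        return Msa(list(self.names), ["".join(r[i] for i in idx) for r in self.rows])


_SUBS = substitution_matrices.load("BLOSUM62")


def _col_score(col_a: str, col_b: str, gap_res: float = -4.0) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            if x == GAP and y == GAP:
                continue
            elif x == GAP or y == GAP:
                total += gap_res
            else:
                total += _SUBS[x, y]
    return total / (len(col_a) * len(col_b))


def _align_profiles(a: list[str], b: list[str], gap_col: float = -8.0) -> tuple[list[str], list[str]]:
    """Needleman–Wunsch on profile columns, linear gap cost per column.

    Traceback prefers diagonal, then a-gap-consuming, then b-gap-consuming
    moves, which makes the merge deterministic.
    """
    cols_a = ["".join(r[i] for r in a) for i in range(len(a[0]))]
    cols_b = ["".join(r[i] for r in b) for i in range(len(b[0]))]
    n, m = len(cols_a), len(cols_b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = np.arange(1, n + 1) * gap_col
    score[0, 1:] = np.arange(1, m + 1) * gap_col
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    pair = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            pair[i, j] = _col_score(cols_a[i], cols_b[j])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + pair[i - 1, j - 1]
            up = score[i - 1, j] + gap_col
            left = score[i, j - 1] + gap_col
            best = max(diag, up, left)
            score[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
        elif move == 1 and i > 0:
            out_a.append(cols_a[i - 1])
            out_b.append(GAP * len(a))
            i -= 1
        else:
            out_a.append(GAP * len(a))
            out_b.append(cols_b[j - 1])
            j -= 1
    out_a.reverse()
    out_b.reverse()
    rows_a = ["".join(c[k] for c in out_a) for k in range(len(a))]
    rows_b = ["".join(c[k] for c in out_b) for k in range(len(b))]
    return rows_a, rows_b


def progressive_align(sequences: dict[str, str]) -> Msa:
    """Progressive multiple alignment (UPGMA guide tree on identity
    distances, profile merges by dynamic programming)."""
    names = list(sequences)
    if not names:
        raise ValueError("no sequences to align")
    if len(names) == 1:
        return Msa(names, [sequences[names[0]]])
    n = len(names)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = 1.0 - percent_identity(sequences[names[i]], sequences[names[j]]) / 100.0
        dist[i, j] = dist[j, i] = d
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [sequences[names[i]]]) for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(tree):
        la, ra = clusters.pop(int(left)), clusters.pop(int(right))
        rows_a, rows_b = _align_profiles(la[1], ra[1])
        clusters[n + step] = (la[0] + ra[0], rows_a + rows_b)
    merged_names, merged_rows = clusters.popitem()[1]
    order = {name: i for i, name in enumerate(merged_names)}
    return Msa(names, [merged_rows[order[name]] for name in names])


# ---------------------------------------------------------------------------
# distances


def poisson_distance(msa: Msa, on_saturation: str = "error") -> DistanceMatrix:
    """Poisson-corrected amino-acid distances, d = -ln(1 - p), with
    pairwise deletion of gapped columns.

    p >= 1 (every comparable column differs) or zero comparable columns is
    a saturation failure; ``on_saturation='cap'`` instead caps p just
    below 1, which the bootstrap uses to keep resampled replicates total.
    """
    if len(msa) < 2:
        raise ValueError("need at least two aligned sequences")
    n = len(msa)
    mat = np.zeros((n, n))
    bad: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        ri, rj = msa.rows[i], msa.rows[j]
        compared = mismatch = 0
        for x, y in zip(ri, rj):
            if x == GAP or y == GAP:
                continue
            compared += 1
            if x != y:
                mismatch += 1
        if compared == 0:
            p = 1.0
        else:
            p = mismatch / compared
        if p >= 1.0:
            if on_saturation == "cap":
                p = 1.0 - 1e-9
            else:
                bad.append((msa.names[i], msa.names[j]))
                continue
        mat[i, j] = mat[j, i] = -np.log(1.0 - p)
    if bad:
        raise ValueError(f"saturated or incomparable pairs: {bad}")
    return DistanceMatrix(mat, ids=msa.names)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimising Q(i,j) = (n-2)d(i,j) - r_i - r_j;
    ties go to the lexicographically smallest (i, j).  The final three
    lineages are resolved by the closed-form star formulas, so the root of
    the returned tree is the unrooted tree's trifurcation.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d: dict[str, dict[str, float]] = {
        a: {b: float(dm[a, b]) for b in ids if b != a} for a in ids
    }
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in ids}
    active = sorted(ids)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best_q = None
        best_pair = None
        for a, b in itertools.combinations(active, 2):  # active is sorted
            q = (n - 2) * d[a][b] - r[a] - r[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        # clamp negatives, moving the deficit to the sibling edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_name = f"__nj{counter}"
        counter += 1
        parent = TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        nodes[new_name] = parent
        d[new_name] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_name][c] = dc
            d[c][new_name] = dc
        active = sorted([c for c in active if c not in (a, b)] + [new_name])
    x, y, z = active
    lx = max(0.0, (d[x][y] + d[x][z] - d[y][z]) / 2.0)
    ly = max(0.0, (d[x][y] + d[y][z] - d[x][z]) / 2.0)
    lz = max(0.0, (d[x][z] + d[y][z] - d[x][y]) / 2.0)
    root = TreeNode(name=None)
    for name, length in ((x, lx), (y, ly), (z, lz)):
        nodes[name].length = length
        root.append(nodes[name])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised as
    the smaller side (ties broken lexicographically)."""
    tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        if (len(side), tuple(sorted(side))) <= (len(other), tuple(sorted(other))):
            splits.add(side)
        else:
            splits.add(other)
    return splits


def bootstrap_support(
    msa: Msa, replicates: int = 1000, seed: int | None = None
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from the full alignment plus bootstrap supports (percent of
    column-resampled replicates containing each original bipartition).

    With ``replicates=0`` the tree is returned with no supports.  Internal
    nodes of the returned tree carry their support as the node name, the
    convention Newick viewers expect for bootstrap labels.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    tree = neighbor_joining(poisson_distance(msa))
    if replicates == 0:
        return tree, {}
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(tree)}
    ncol = msa.n_columns
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = msa.take_columns(idx)
        rep_tree = neighbor_joining(poisson_distance(rep, on_saturation="cap"))
        rep_splits = bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        key = side if side in supports else other
        if key in supports:
            node.name = f"{supports[key]:.0f}"
    return tree, supports


def to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
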