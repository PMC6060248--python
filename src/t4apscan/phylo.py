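"""Distance-based phylogenetics: progressive alignment, corrected distances,
neighbor joining with bootstrap supports, and monophyly tests.

Trees are built by Saitou–Nei neighbor joining on Poisson-corrected protein
distances (or JC69 for nucleotide data). For an additive distance matrix NJ
recovers the generating tree exactly — path lengths on the tree reproduce the
input — which the tests exploit as an oracle. Column-bootstrap supports are
attached to internal edges, and monophyly of a taxon subset is decided by
whether some edge's bipartition isolates exactly that subset.

The multiple aligner is a deterministic progressive scheme: a UPGMA guide
tree on pairwise global-alignment p-distances, with profile–profile
Needleman–Wunsch merges (affine gaps, BLOSUM62 expected column scores) from
the leaves to the root. For two sequences it reduces to the optimal pairwise
global alignment.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from scipy.cluster.hierarchy import linkage, to_tree
from skbio import TreeNode

from .homology import GAP_EXTEND, GAP_OPEN, _BLOSUM62, global_align

_AA = "ACDEFGHIKLMNPQRSTVWYX-"
_AA_INDEX = {c: i for i, c in enumerate(_AA)}
# BLOSUM62 extended with zero-scoring gap and X rows for profile scoring
_B62EXT = np.zeros((len(_AA), len(_AA)))
for _i, _a in enumerate(_AA[:-2]):
    for _j, _b in enumerate(_AA[:-2]):
        _B62EXT[_i, _j] = _BLOSUM62[_a, _b]


class SaturationError(ValueError):
    """Distance correction undefined: too many observed differences."""


@dataclass
class MultipleAlignment:
    labels: list[str]
    rows: list[str]
    alphabet: str = "protein"  # or "nucleotide"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxa labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice_columns(self, start: int, stop: int | None = None) -> "MultipleAlignment":
        """Restrict to a column range, e.g. the conserved N-terminal window
        used for pilin phylogenies."""
        return MultipleAlignment(
            list(self.labels), [r[start:stop] for r in self.rows], self.alphabet
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.labels, self.rows):
                fh.write(f">{lab}\n{row}\n")

    @classmethod
    def from_fasta(cls, path, alphabet: str = "protein") -> "MultipleAlignment":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq))
        return cls(labels, rows, alphabet)


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue-frequency matrix (L x |alphabet|)."""
    L = len(rows[0])
    freq = np.zeros((L, len(_AA)))
    for row in rows:
        for j, c in enumerate(row):
            freq[j, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1
    return freq / len(rows)


def _profile_nw(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap Needleman–Wunsch between two profiles; returns the two row
    groups padded with '-' to the merged length."""
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    S = fa @ _B62EXT @ fb.T  # expected column-pair score

    NEG = -1e18
    go, ge = -(GAP_OPEN + GAP_EXTEND), -GAP_EXTEND
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (A advances)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = go + ge * (j - 1)
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            # match state
            best, arg = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, arg = Yi1[j - 1], 2
            Mi[j] = best + Si[j - 1]
            ptrM[i, j] = arg
            # gap in B
            best, arg = Mi1[j] + go, 0
            if Xi1[j] + ge > best:
                best, arg = Xi1[j] + ge, 1
            if Yi1[j] + go > best:
                best, arg = Yi1[j] + go, 2
            Xi[j] = best
            ptrX[i, j] = arg
            # gap in A
            best, arg = Mi[j - 1] + go, 0
            if Xi[j - 1] + go > best:
                best, arg = Xi[j - 1] + go, 1
            if Yi[j - 1] + ge > best:
                best, arg = Yi[j - 1] + ge, 2
            Yi[j] = best
            ptrY[i, j] = arg

    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append("X")
            state = int(ptrX[i, j])
            i -= 1
        else:
            ops.append("Y")
            state = int(ptrY[i, j])
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_align(
    sequences: Sequence[str],
    labels: Sequence[str] | None = None,
    alphabet: str = "protein",
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Deterministic for a fixed input order. Two sequences reduce to the
    optimal pairwise global alignment under BLOSUM62 / affine 11+1 gaps.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("progressive_align requires >=2 sequences")
    if any(not s for s in sequences):
        raise ValueError("empty sequence")
    labels = list(labels) if labels is not None else [f"seq{i}" for i in range(n)]

    if n == 2:
        _, a, b = global_align(sequences[0], sequences[1])
        return MultipleAlignment(labels, [a, b], alphabet)

    # guide tree from pairwise global-alignment p-distances
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, a, b = global_align(sequences[i], sequences[j])
            diff = cols = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                cols += 1
                diff += x != y
            dmat[i, j] = dmat[j, i] = diff / cols if cols else 1.0
    condensed = dmat[np.triu_indices(n, k=1)]
    guide = to_tree(linkage(condensed, method="average"))

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [sequences[node.id]]
        ids_l, rows_l = merge(node.left)
        ids_r, rows_r = merge(node.right)
        out_l, out_r = _profile_nw(rows_l, rows_r)
        return ids_l + ids_r, out_l + out_r

    ids, rows = merge(guide)
    order = np.argsort(ids)
    return MultipleAlignment(
        [labels[ids[k]] for k in order], [rows[k] for k in order], alphabet
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def distance_matrix(
    alignment: MultipleAlignment,
    correction: str = "poisson",
    saturation: str = "error",
) -> np.ndarray:
    """Pairwise distances over ungapped shared columns.

    correction: 'p' (raw proportion), 'poisson' (protein, d = -ln(1-p)), or
    'jc69' (nucleotide, d = -(3/4) ln(1 - 4p/3)). Saturated pairs (p >= 1,
    or >= 3/4 for jc69) raise :class:`SaturationError` naming the pair, or
    are capped at 10 substitutions/site with ``saturation='cap'`` (used by
    the bootstrap, where resampling can transiently saturate a pair).
    """
    if correction not in {"p", "poisson", "jc69"}:
        raise ValueError(f"unknown correction {correction!r}")
    n = alignment.n_taxa
    rows = alignment.rows
    enc = np.array(
        [[_AA_INDEX.get(c, _AA_INDEX["X"]) for c in row] for row in rows], dtype=np.int16
    )
    gap = _AA_INDEX["-"]
    D = np.zeros((n, n))
    CAP = 10.0
    for i in range(n):
        for j in range(i + 1, n):
            shared = (enc[i] != gap) & (enc[j] != gap)
            cols = int(shared.sum())
            if cols == 0:
                raise SaturationError(
                    f"no shared ungapped columns between "
                    f"{alignment.labels[i]} and {alignment.labels[j]}"
                )
            p = float((enc[i][shared] != enc[j][shared]).sum()) / cols
            if correction == "p":
                d = p
            elif correction == "poisson":
                if p >= 1.0:
                    if saturation == "cap":
                        d = CAP
                    else:
                        raise SaturationError(
                            f"saturated pair {alignment.labels[i]} / "
                            f"{alignment.labels[j]}: p = {p:.3f}"
                        )
                else:
                    d = -math.log(1.0 - p)
            else:  # jc69
                if p >= 0.75:
                    if saturation == "cap":
                        d = CAP
                    else:
                        raise SaturationError(
                            f"saturated pair {alignment.labels[i]} / "
                            f"{alignment.labels[j]}: p = {p:.3f} >= 3/4"
                        )
                else:
                    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Returns an unrooted tree represented with a trifurcating root. Q-matrix
    ties are broken by the smallest (i, j) index pair over the current node
    ordering, making the output deterministic. Negative branch-length
    estimates are clamped to zero (cannot occur for additive input).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires >=3 taxa")
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix/labels shape mismatch")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    if (matrix < -1e-12).any():
        raise ValueError("distance matrix must be nonnegative")

    nodes = [TreeNode(name=lab) for lab in labels]
    D = matrix.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-9))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        parent.extend([a, b])
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal 3-node star: three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        max(0.5 * (d01 + d02 - d12), 0.0),
        max(0.5 * (d01 + d12 - d02), 0.0),
        max(0.5 * (d02 + d12 - d01), 0.0),
    ]
    root = TreeNode()
    for node, ln in zip(nodes, lens):
        node.length = float(ln)
        root.append(node)
    return root


def tree_path_distances(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix (additivity check)."""
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = tree.find(labels[i])
            d = a.distance(tree.find(labels[j]))
            out[i, j] = out[j, i] = float(d)
    return out


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Nontrivial bipartitions of an unrooted tree, each normalized to the
    side not containing the lexicographically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = set(leaves)
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out[frozenset(side)] = node
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    alignment: MultipleAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "poisson",
) -> TreeNode:
    """NJ tree on the full alignment with column-bootstrap edge supports.

    Columns are resampled with replacement; the support of an internal edge
    is the percentage of replicate NJ trees containing its bipartition. All
    replicate column draws come from one seeded stream (replicate r consumes
    draws r*L .. r*L+L-1), so results do not depend on evaluation order.
    """
    if alignment.n_taxa < 4:
        raise ValueError("bootstrap needs >=4 taxa")
    L = alignment.n_columns
    D = distance_matrix(alignment, correction)
    base = neighbor_joining(D, alignment.labels)
    base_bips = bipartitions(base)
    counts = {bip: 0 for bip in base_bips}

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, L, size=(n_replicates, L))
    for r in range(n_replicates):
        cols = draws[r]
        rows = ["".join(row[c] for c in cols) for row in alignment.rows]
        rep = MultipleAlignment(list(alignment.labels), rows, alignment.alphabet)
        try:
            Dr = distance_matrix(rep, correction, saturation="cap")
        except SaturationError:
            continue
        rep_bips = set(bipartitions(neighbor_joining(Dr, rep.labels)))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1

    for bip, node in base_bips.items():
        node.name = str(round(100.0 * counts[bip] / n_replicates))
    return base


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonophylyVerdict:
    taxon_subset: frozenset[str]
    is_monophyletic: bool
    support_pct: float | None = None


def test_monophyly(tree: TreeNode, taxon_subset: Iterable[str]) -> MonophylyVerdict:
    """True iff some edge's bipartition isolates exactly the subset; the
    verdict carries that edge's bootstrap support when annotated. Singletons
    and the full leaf set are trivially monophyletic."""
    subset = frozenset(taxon_subset)
    if not subset:
        raise ValueError("empty taxon subset")
    leaves = {t.name for t in tree.tips()}
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(subset) in (1, len(leaves) - 1, len(leaves)):
        # isolated by a pendant edge (or the whole tree): trivially true
        return MonophylyVerdict(subset, True, None)
    ref = sorted(leaves)[0]
    target = subset if ref not in subset else frozenset(leaves - subset)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        norm = frozenset(side) if ref not in side else frozenset(leaves - side)
        if norm == target:
            support = None
            if node.name is not None and str(node.name).strip():
                try:
                    support = float(node.name)
                except ValueError:
                    support = None
            return MonophylyVerdict(subset, True, support)
    return MonophylyVerdict(subset, False, None)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
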