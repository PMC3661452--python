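"""Distance-based phylogenetics for germline V segments.

The family analysis follows the classical workflow: progressive multiple
alignment, pairwise identity with gap-excluded columns, neighbor-joining
(Saitou-Nei) with bootstrap support from column resampling, outgroup
rooting, and single-linkage partitioning of the V repertoire into
families on an identity threshold.

Trees are :class:`skbio.TreeNode` objects, so they serialize to newick
and interoperate with the wider ecosystem; the neighbor-joining
agglomeration itself is implemented here with a deterministic
lexicographic tie-break so results are reproducible to the byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import TreeNode

_GAP = ord("-")


# ---------------------------------------------------------------------------
# alignments and identity


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    def __len__(self):
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), np.uint8).reshape(
            len(self.rows), -1)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two aligned rows, excluding gap columns.

    Columns where either row has a gap are removed from the denominator;
    an alignment with no comparable columns has no defined identity.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    A = np.frombuffer(a.upper().encode(), np.uint8)
    B = np.frombuffer(b.upper().encode(), np.uint8)
    valid = (A != _GAP) & (B != _GAP)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no gap-free columns to compare")
    return 100.0 * float((A[valid] == B[valid]).sum()) / n


def identity_matrix(aln: Alignment, *, columns=None) -> np.ndarray:
    """All-pairs percent identity (gap-excluded); 100 on the diagonal.

    Pairs without comparable columns get identity 0 (maximal distance)
    rather than an error — needed for bootstrap resamples.
    """
    M = aln.matrix()
    if columns is not None:
        M = M[:, columns]
    n = len(aln)
    out = np.full((n, n), 100.0)
    nongap = M != _GAP
    for i in range(n):
        for j in range(i + 1, n):
            valid = nongap[i] & nongap[j]
            c = int(valid.sum())
            ident = 100.0 * float((M[i, valid] == M[j, valid]).sum()) / c \
                if c else 0.0
            out[i, j] = out[j, i] = ident
    return out


# ---------------------------------------------------------------------------
# progressive multiple alignment


_ALPHA = "ACGT-"
_SCORE = np.full((5, 5), -1.0)
np.fill_diagonal(_SCORE, 1.0)
_SCORE[4, :] = _SCORE[:, 4] = -1.0
_SCORE[4, 4] = 0.0
_GAP_COST = 3.0   # stiff: gaps only where they repair several mismatches


def _profile(rows: np.ndarray) -> np.ndarray:
    """Column frequency profile over A,C,G,T,- (other symbols -> N-like
    uniform over the four bases)."""
    L = rows.shape[1]
    freq = np.zeros((L, 5))
    for k, ch in enumerate(_ALPHA):
        freq[:, k] = (rows == ord(ch)).mean(axis=0)
    other = 1.0 - freq.sum(axis=1)
    freq[:, :4] += other[:, None] / 4.0
    return freq


def _align_profiles(ra: np.ndarray, rb: np.ndarray):
    """Global profile-profile alignment; returns gapped row matrices."""
    fa, fb = _profile(ra), _profile(rb)
    S = np.einsum("ik,kl,jl->ij", fa, _SCORE, fb)
    La, Lb = S.shape
    H = np.empty((La + 1, Lb + 1))
    H[0] = -_GAP_COST * np.arange(Lb + 1)
    for i in range(1, La + 1):
        # best of diagonal/up moves per column, then propagate left moves
        # as a running max with linear gap decay (avoids an inner loop)
        tmp = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] - _GAP_COST)
        H[i, 0] = H[i - 1, 0] - _GAP_COST
        decay = _GAP_COST * np.arange(Lb + 1)
        cand = np.concatenate(([H[i, 0]], tmp)) + decay
        H[i] = np.maximum.accumulate(cand) - decay
    # traceback
    i, j = La, Lb
    path = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
            path.append("M"); i -= 1; j -= 1
        elif i > 0 and abs(H[i, j] - (H[i - 1, j] - _GAP_COST)) < eps:
            path.append("U"); i -= 1
        else:
            path.append("L"); j -= 1
    path.reverse()
    L = len(path)
    out_a = np.full((ra.shape[0], L), _GAP, np.uint8)
    out_b = np.full((rb.shape[0], L), _GAP, np.uint8)
    ia = ib = 0
    for col, op in enumerate(path):
        if op in "MU":
            out_a[:, col] = ra[:, ia]; ia += 1
        if op in "ML":
            out_b[:, col] = rb[:, ib]; ib += 1
    return out_a, out_b


def progressive_msa(seqs: list[tuple[str, str]]) -> Alignment:
    """Guide-tree progressive multiple alignment.

    Pairwise edit distances build a neighbor-joining guide tree; profiles
    are merged bottom-up with a sum-of-pairs profile aligner (match +1,
    mismatch -1, linear gap cost).  De-gapping any output row recovers
    the corresponding input sequence.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    labels = [l for l, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    data = {l: s.upper() for l, s in seqs}

    def as_rows(label):
        return ([label],
                np.frombuffer(data[label].encode(), np.uint8)[None, :].copy())

    if len(seqs) == 2:
        (la, ra), (lb, rb) = as_rows(labels[0]), as_rows(labels[1])
        A, B = _align_profiles(ra, rb)
        rows = np.vstack([A, B])
        return Alignment(la + lb, ["".join(map(chr, r)) for r in rows])

    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ed = edlib.align(data[labels[i]], data[labels[j]],
                             mode="NW")["editDistance"]
            d[i, j] = d[j, i] = ed / max(len(data[labels[i]]),
                                         len(data[labels[j]]))
    guide = nj_tree(DistanceMatrix(labels, d))

    def merge(node):
        if node.is_tip():
            return as_rows(node.name)
        parts = [merge(ch) for ch in node.children]
        cur_labels, cur_rows = parts[0]
        for nxt_labels, nxt_rows in parts[1:]:
            A, B = _align_profiles(cur_rows, nxt_rows)
            cur_rows = np.vstack([A, B])
            cur_labels = cur_labels + nxt_labels
        return cur_labels, cur_rows

    out_labels, rows = merge(guide)
    aln = Alignment(out_labels, ["".join(map(chr, r)) for r in rows])
    order = [aln.labels.index(l) for l in labels]
    return Alignment(labels, [aln.rows[k] for k in order])


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")


def distances_from_alignment(aln: Alignment, *, columns=None) -> DistanceMatrix:
    """Distance = 1 - identity/100 with pairwise gap exclusion."""
    return DistanceMatrix(list(aln.labels),
                          1.0 - identity_matrix(aln, columns=columns) / 100.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Ties in the Q criterion resolve to the lexicographically smallest
    pair of cluster representatives (the minimal leaf label in each
    cluster).  Negative branch lengths are clamped to zero and counted
    in ``tree.negative_branches``.  The returned tree is unrooted
    (trifurcating root).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {}
    nodes = {}
    reps = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = TreeNode(name=lab)
        reps[i] = lab
    for i in range(n):
        for j in range(n):
            d[(i, j)] = float(dm.d[i, j])
    active = sorted(nodes, key=lambda k: reps[k])
    clamped = 0
    next_id = n

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[(i, j)] - R[i] - R[j]
                pair = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair < best[1]):
                    best = (q, pair, i, j)
        _, _, i, j = best
        li = d[(i, j)] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[(i, j)] - li
        if li < 0:
            clamped += 1; li = 0.0
        if lj < 0:
            clamped += 1; lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        u = next_id; next_id += 1
        nodes[u] = parent
        reps[u] = min(reps[i], reps[j])
        for k in active:
            if k in (i, j):
                continue
            d[(u, k)] = d[(k, u)] = (d[(i, k)] + d[(j, k)] - d[(i, j)]) / 2
        d[(u, u)] = 0.0
        active = sorted((k for k in active if k not in (i, j)),
                        key=lambda k: reps[k]) + [u]
        active.sort(key=lambda k: reps[k])

    a, b, c = sorted(active, key=lambda k: reps[k])
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        if ln < 0:
            clamped += 1; ln = 0.0
        node.length = ln
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.negative_branches = clamped
    return root


# ---------------------------------------------------------------------------
# bootstrap and rooting


def _bipartitions(tree: TreeNode):
    """Canonical non-trivial bipartitions (internal edges) of a tree."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        comp = all_tips - side
        canon = min((side, comp), key=lambda s: (len(s), tuple(sorted(s))))
        out.append((node, canon))
    return out


def bootstrap_support(aln: Alignment, replicates: int, seed: int) -> TreeNode:
    """NJ tree with bootstrap support from column resampling.

    Columns are resampled with replacement per replicate; the support of
    each internal edge is the percentage of replicate trees containing
    the same bipartition.  Fully seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if len(aln) < 3:
        raise ValueError("bootstrap needs at least 3 sequences")
    tree = nj_tree(distances_from_alignment(aln))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(distances_from_alignment(aln, columns=cols))
        for _, canon in _bipartitions(rep):
            counts[canon] = counts.get(canon, 0) + 1
    for node, canon in _bipartitions(tree):
        # skbio's newick writer emits `support` as the internal node label
        node.support = 100.0 * counts.get(canon, 0) / replicates
    return tree


def root_at_outgroup(tree: TreeNode, outgroup) -> TreeNode:
    """Root on the edge separating the outgroup from the ingroup."""
    outgroup = frozenset(outgroup)
    tips = {t.name for t in tree.tips()}
    missing = outgroup - tips
    if missing:
        raise ValueError(f"outgroup labels absent from tree: {sorted(missing)}")
    if not outgroup or outgroup == tips:
        raise ValueError("outgroup must be a proper non-empty tip subset")
    target = None
    for node in tree.postorder(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        if side == outgroup or side == tips - outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            "outgroup is not monophyletic in the unrooted tree: "
            f"{sorted(outgroup)}")
    rooted = tree.root_at(target, above=True, branch_attrs=["support"])
    return rooted


# ---------------------------------------------------------------------------
# family partitioning


@dataclass
class FamilyPartition:
    assignments: dict[str, int]
    families: list[list[str]]
    min_within: dict[int, float]
    max_between: float

    @property
    def n_families(self) -> int:
        return len(self.families)


def partition_families(labels, identity: np.ndarray,
                       threshold: float = 75.0) -> FamilyPartition:
    """Single-linkage families at an identity threshold.

    Two segments join the same family when connected by a chain of
    pairwise identities at or above ``threshold``.  Family ids are
    assigned 1..k in order of each family's lexicographically smallest
    member, so the partition is invariant to input order.
    """
    labels = list(labels)
    n = len(labels)
    identity = np.asarray(identity, float)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if identity[i, j] >= threshold:
                parent[find(i)] = find(j)

    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(labels[i])
    families = sorted((sorted(m) for m in comps.values()), key=lambda m: m[0])
    assignments = {}
    min_within = {}
    for fid, members in enumerate(families, start=1):
        for m in members:
            assignments[m] = fid
        idx = [labels.index(m) for m in members]
        if len(idx) > 1:
            sub = identity[np.ix_(idx, idx)]
            min_within[fid] = float(sub[~np.eye(len(idx), dtype=bool)].min())
        else:
            min_within[fid] = 100.0
    max_between = float("nan")
    if len(families) > 1:
        best = -np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if assignments[labels[i]] != assignments[labels[j]]:
                    best = max(best, identity[i, j])
        max_between = float(best)
    return FamilyPartition(assignments, families, min_within, max_between)
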