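"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree-building stage mirrors the classic protein-family workflow:
pairwise p-distances with pairwise gap deletion (optionally Poisson
corrected), a Saitou-Nei neighbor-joining tree, and nonparametric bootstrap
supports obtained by resampling alignment columns and counting how often
each internal split of the full-data tree recurs. All tie-breaks are
lexicographic so results are identical across platforms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tree import Tree, TreeNode
from .sequence_io import AlignedSet

MIN_COMPARABLE = 10
_GAP_CODE = ord("-")
_X_CODE = ord("X")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")


def _encode(aligned: AlignedSet) -> np.ndarray:
    return np.array(
        [np.frombuffer(row.encode("ascii"), dtype=np.uint8) for _, row in aligned.records]
    )


def _pdist_from_array(
    arr: np.ndarray, labels: list[str], correction: str = "p"
) -> DistanceMatrix:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        a = arr[i]
        for j in range(i + 1, n):
            b = arr[j]
            comparable = (a != _GAP_CODE) & (b != _GAP_CODE)
            n_comp = int(comparable.sum())
            if n_comp < MIN_COMPARABLE:
                raise ValueError(
                    f"fewer than {MIN_COMPARABLE} comparable columns between "
                    f"'{labels[i]}' and '{labels[j]}' ({n_comp})"
                )
            mismatch = comparable & (
                (a != b) | (a == _X_CODE) | (b == _X_CODE)
            )
            p = mismatch.sum() / n_comp
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for pair "
                        f"('{labels[i]}', '{labels[j]}')"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels, d)


def p_distance(aligned: AlignedSet, correction: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    p-distance is the mismatch fraction over columns where neither row has a
    gap; 'X' mismatches everything, including another 'X'. With
    ``correction="poisson"`` the multiple-hit correction -ln(1-p) is applied.
    Any pair sharing fewer than 10 comparable columns is an error.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction '{correction}'")
    if len(aligned.records) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    return _pdist_from_array(_encode(aligned), aligned.ids(), correction)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (m-2) d(i,j) - r_i - r_j.
    Negative pendant branch lengths are clamped to zero with the deficit
    moved to the sister branch, preserving the joined pair's path distance.
    Ties in Q are broken by the lexicographically smallest pair of subtree
    labels (each subtree labeled by its smallest leaf). For two taxa the
    single distance is split equally between the pendant edges.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if n == 2:
        half = dm.d[0, 1] / 2.0
        return Tree(
            TreeNode(
                children=[
                    TreeNode(name=dm.labels[0], length=half),
                    TreeNode(name=dm.labels[1], length=half),
                ]
            )
        )

    nodes = [TreeNode(name=lab) for lab in dm.labels]
    minlab = list(dm.labels)
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best_key = None
        best_ab = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    la, lb = minlab[active[a]], minlab[active[b]]
                    key = (min(la, lb), max(la, lb))
                    if best_key is None or key < best_key:
                        best_key, best_ab = key, (a, b)
        a, b = best_ab
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = TreeNode(children=[ni, nj_])
        # distances from the new node to every other active node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = new
        minlab[i] = min(minlab[i], minlab[j])
        active.remove(j)

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max(0.0, (dij + dik - djk) / 2.0)
    lj = max(0.0, (dij + djk - dik) / 2.0)
    lk = max(0.0, (dik + djk - dij) / 2.0)
    for idx, length in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = length
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root)


def bootstrap_supports(
    aligned: AlignedSet,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "p",
) -> Tree:
    """NJ tree of the full alignment with bootstrap supports on its splits.

    Alignment columns are resampled with replacement (same length), the NJ
    tree rebuilt per replicate, and each internal split of the full-data
    tree scored by the percentage of replicates containing it (rounded to
    the nearest integer). A replicate that leaves some pair with too few
    comparable columns is redrawn, up to 10 times. Deterministic for a
    fixed seed and invariant to the row order of the alignment.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    full_dm = p_distance(aligned, correction)
    tree = nj_tree(full_dm)
    splits = tree.splits()
    if not splits:
        return tree
    counts = {key: 0 for key in splits}
    arr = _encode(aligned)
    labels = aligned.ids()
    n_cols = arr.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        for attempt in range(10):
            cols = rng.integers(0, n_cols, size=n_cols)
            try:
                rep_dm = _pdist_from_array(arr[:, cols], labels, correction)
            except ValueError:
                continue
            break
        else:
            raise ValueError(
                "bootstrap replicate repeatedly violated the minimum "
                "comparable-columns rule"
            )
        rep_splits = nj_tree(rep_dm).splits()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = int(round(100.0 * counts[key] / n_reps))
    return tree
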