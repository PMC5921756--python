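"""Distance-based phylogeny.

Pipeline: pairwise-deletion p-distances over an aligned protein matrix,
Poisson correction d = -ln(1 - p), Saitou-Nei neighbor-joining, and
column-resampling bootstrap whose bipartition frequencies are mapped
back onto the full-data tree. Ties in the NJ Q-matrix are broken by the
lowest taxon-index pair so runs are deterministic; negative NJ branch
lengths are clamped to zero with the deficit moved to the sister edge.

Gap handling is pairwise deletion: a column contributes to a pair's
distance only when both rows are ungapped there. (Complete deletion,
the common alternative, discards signal on truncated family members;
both behaviours are available through ``gap_mode``.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from famkit.errors import FamkitError, SaturationError

log = logging.getLogger("famkit.phylo")

GAP = "-"


@dataclass
class Alignment:
    """A rectangular multiple alignment (gap symbol permitted)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise FamkitError("taxa/rows length mismatch")
        if len(self.taxa) < 2:
            raise FamkitError("an alignment requires at least 2 taxa")
        ncol = len(self.rows[0])
        if ncol == 0 or any(len(r) != ncol for r in self.rows):
            raise FamkitError("all alignment rows must share one nonzero length")
        if len(set(self.taxa)) != len(self.taxa):
            raise FamkitError("duplicate taxon labels")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(len(self.rows), self.n_columns)

    def subsample_columns(self, idx: np.ndarray) -> "Alignment":
        arr = self.to_array()[:, idx]
        return Alignment(
            taxa=list(self.taxa),
            rows=[row.tobytes().decode("ascii") for row in arr],
        )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise FamkitError("distance matrix shape does not match taxa")
        if not np.allclose(np.diag(self.d), 0.0):
            raise FamkitError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.allclose(
            np.where(finite, self.d, 0.0), np.where(finite.T, self.d.T, 0.0)
        ):
            raise FamkitError("distance matrix must be symmetric")
        if np.any(self.d[finite] < 0):
            raise FamkitError("distances must be nonnegative")


def p_distance(alignment: Alignment, taxon_a: str, taxon_b: str) -> float:
    """Proportion of differing residues over pairwise-ungapped columns."""
    ia, ib = alignment.taxa.index(taxon_a), alignment.taxa.index(taxon_b)
    a = np.frombuffer(alignment.rows[ia].upper().encode(), dtype="S1")
    b = np.frombuffer(alignment.rows[ib].upper().encode(), dtype="S1")
    mask = (a != GAP.encode()) & (b != GAP.encode())
    comparable = int(mask.sum())
    if comparable == 0:
        raise FamkitError(f"{taxon_a}/{taxon_b}: no comparable (pairwise ungapped) columns")
    return float(((a != b) & mask).sum()) / comparable


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p).

    Monotone increasing and >= p on [0, 1); p >= 1 is saturated and
    maps to +inf (flagged with a warning, never fabricated).
    """
    if p < 0:
        raise FamkitError(f"proportion must be >= 0, got {p}")
    if p >= 1:
        log.warning("saturated p-distance (p = %s): distance set to inf", p)
        return math.inf
    return -math.log1p(-p)


def distance_matrix(alignment: Alignment, correction: str = "poisson") -> DistanceMatrix:
    """All-pairs distance matrix ('poisson' or raw 'p')."""
    arr = np.char.upper(alignment.to_array())
    n = len(alignment.taxa)
    gap = GAP.encode()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (arr[i] != gap) & (arr[j] != gap)
            comparable = int(mask.sum())
            if comparable == 0:
                raise FamkitError(
                    f"{alignment.taxa[i]}/{alignment.taxa[j]}: no comparable columns"
                )
            p = float(((arr[i] != arr[j]) & mask).sum()) / comparable
            d[i, j] = d[j, i] = poisson_correct(p) if correction == "poisson" else p
    return DistanceMatrix(taxa=list(alignment.taxa), d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SupportedTree:
    """An unrooted tree (trifurcating root node) with optional
    per-internal-edge bootstrap percentages."""

    root: TreeNode
    taxa: list[str]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map canonical leaf-set bipartitions to the internal node
        subtending the corresponding edge. Trivial (single-leaf) splits
        are excluded."""
        full = frozenset(self.taxa)
        anchor = sorted(self.taxa)[0]
        out: dict[frozenset, TreeNode] = {}

        def visit(node: TreeNode) -> None:
            for child, _ in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaves())
                    if 1 < len(side) < len(full) - 1:
                        key = side if anchor not in side else full - side
                        out[key] = child
                    visit(child)

        visit(self.root)
        return out

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name  # type: ignore[return-value]
            inner = ",".join(
                f"{fmt(c)}:{length:.{decimals}f}" for c, length in node.children
            )
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def cherries(self) -> list[tuple[tuple[str, str], TreeNode]]:
        """Two-leaf clades with the internal node carrying the edge
        (and its support) that subtends them."""
        out: list[tuple[tuple[str, str], TreeNode]] = []

        def visit(node: TreeNode) -> None:
            if not node.is_leaf:
                kids = [c for c, _ in node.children]
                if len(kids) == 2 and all(k.is_leaf for k in kids):
                    out.append(((kids[0].name, kids[1].name), node))  # type: ignore[arg-type]
                for k in kids:
                    visit(k)

        visit(self.root)
        # Unrooted special case: two leaf children hanging off the
        # trifurcating root form a cherry subtended by the third edge.
        root_kids = [c for c, _ in self.root.children]
        if len(root_kids) == 3:
            leaf_kids = [k for k in root_kids if k.is_leaf]
            inner_kids = [k for k in root_kids if not k.is_leaf]
            if len(leaf_kids) == 2 and len(inner_kids) == 1:
                out.append(((leaf_kids[0].name, leaf_kids[1].name), inner_kids[0]))
        return out


def nj_tree(matrix: DistanceMatrix) -> SupportedTree:
    """Neighbor-joining (Saitou-Nei) agglomeration.

    On an additive matrix the generating topology is recovered exactly.
    Requires >= 3 taxa and finite distances.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise FamkitError("neighbor-joining requires at least 3 taxa")
    if not np.all(np.isfinite(matrix.d)):
        raise SaturationError(
            "distance matrix contains infinite entries; resolve saturation "
            "(e.g. remove saturated pairs) before tree building"
        )
    nodes = [TreeNode(name=t) for t in matrix.taxa]
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: lowest (i, j) index pair
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for ak in active:
            if ak in (i, j):
                continue
            d[k_new, ak] = d[ak, k_new] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [k_new]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return SupportedTree(root=root, taxa=list(matrix.taxa))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def bootstrap_supports(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    correction: str = "poisson",
) -> SupportedTree:
    """Column-resampling bootstrap.

    Each replicate resamples alignment columns with replacement and
    re-runs the full pipeline (p-distance -> correction -> NJ); the
    support of each internal edge of the full-data tree is the
    percentage of successful replicates containing its bipartition.
    Replicates with an incomparable pair or a saturated distance are
    skipped and counted (``tree.n_skipped``). Reproducible given seed.
    """
    if replicates < 1:
        raise FamkitError("replicates must be >= 1")
    tree = nj_tree(distance_matrix(alignment, correction=correction))
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    skipped = 0
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = alignment.subsample_columns(idx)
        try:
            rep_tree = nj_tree(distance_matrix(rep, correction=correction))
        except (FamkitError, SaturationError):
            skipped += 1
            continue
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    valid = replicates - skipped
    if valid == 0:
        raise FamkitError("all bootstrap replicates failed")
    for bp, node in tree.bipartitions().items():
        node.support = 100.0 * counts[bp] / valid
    tree.n_skipped = skipped  # type: ignore[attr-defined]
    if skipped:
        log.warning("bootstrap: %d of %d replicates skipped", skipped, replicates)
    return tree


def sister_pairs(tree: SupportedTree, threshold: float = 65.0) -> list[tuple[str, str]]:
    """Cherries whose subtending edge support strictly exceeds the
    threshold (percent)."""
    pairs = []
    for (a, b), node in tree.cherries():
        if node.support is not None and node.support > threshold:
            pairs.append(tuple(sorted((a, b))))
    return sorted(set(pairs))


@dataclass
class GroupContrast:
    mean_a: float
    mean_b: float
    t_statistic: float | None
    p_value: float | None
    n_a: int
    n_b: int


def exon_group_contrast(records, membership: dict[str, str]) -> GroupContrast:
    """Welch two-sided t test of exon counts between two labelled groups.

    ``membership`` maps gene name -> group label; exactly two labels are
    expected. A group with fewer than 2 members yields means only.
    """
    groups: dict[str, list[int]] = {}
    for r in records:
        if r.name in membership:
            groups.setdefault(membership[r.name], []).append(r.exon_count)
    if len(groups) != 2:
        raise FamkitError(f"expected exactly 2 groups, got {sorted(groups)}")
    (la, xa), (lb, xb) = sorted(groups.items())
    if not xa or not xb:
        raise FamkitError("both groups must be nonempty")
    mean_a, mean_b = float(np.mean(xa)), float(np.mean(xb))
    if min(len(xa), len(xb)) < 2:
        return GroupContrast(mean_a, mean_b, None, None, len(xa), len(xb))
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    if np.isnan(t):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return GroupContrast(mean_a, mean_b, float(t), float(p), len(xa), len(xb))
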