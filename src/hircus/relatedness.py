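"""Kinship (pi-hat), IBS distances, and neighbor-joining trees.

All three rest on the pairwise mismatch rate of pseudohaploid calls: the
fraction of jointly called panel sites where two samples carry different
alleles.  Kinship follows the mismatch-halving logic of allele-sharing
estimators for low-coverage data: two unrelated samples from one
population mismatch at a baseline rate m_bar; a pair sharing a fraction
pi of their genome identical-by-descent mismatches at m_bar (1 - pi/2),
so pi_hat = 2 (1 - m / m_bar), clamped to [0, 1].  Expected values are 0
for unrelated, 0.5 for parent-offspring or full siblings, and 1 for self
(or identical twins / duplicate libraries).

The IBS distance (1 - identity-by-state = mismatch rate) feeds
Saitou-Nei neighbor joining; topology uncertainty is assessed by
resampling 5-Mb genomic blocks with replacement and recording, for each
internal edge of the point-estimate tree, the fraction of replicates
whose tree contains the same bipartition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fstats import assign_blocks
from .genotypes import MISSING, PseudohaploidMatrix

__all__ = [
    "KinshipEstimate",
    "DistanceMatrix",
    "TreeNode",
    "TreeWithSupport",
    "pairwise_mismatch",
    "kinship_pihat",
    "ibs_distance",
    "neighbor_joining",
    "bootstrap_tree",
]

DEFAULT_BLOCK_BP = 5_000_000
DEFAULT_BOOTSTRAPS = 50


@dataclass
class KinshipEstimate:
    pair: tuple[str, str]
    mismatch_rate: float
    baseline: float
    pi_hat: float
    n_overlapping_sites: int


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise 1-IBS values with overlap counts."""

    labels: tuple[str, ...]
    values: np.ndarray
    overlaps: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape must be (n, n)")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v


class TreeNode:
    """Node of an (un)rooted phylogeny; root of an NJ tree is a trifurcation."""

    __slots__ = ("name", "children", "support")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, include_support: bool = False) -> str:
        return self._newick(include_support) + ";"

    def _newick(self, include_support: bool) -> str:
        if self.is_leaf:
            return self.name
        parts = ",".join(
            f"{child._newick(include_support)}:{length:.6g}"
            for child, length in self.children
        )
        label = ""
        if include_support and self.support is not None:
            label = f"{self.support:.2f}"
        return f"({parts}){label}"


@dataclass
class TreeWithSupport:
    """Unrooted tree with optional per-bipartition bootstrap supports."""

    root: TreeNode
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    n_replicates: int = 0

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the leaf set of one side."""
        return tree_bipartitions(self.root)

    def newick(self) -> str:
        return self.root.newick(include_support=bool(self.supports))


def tree_bipartitions(root: TreeNode) -> set[frozenset[str]]:
    """Unrooted split encoding: side not containing the lexicographically
    first leaf, restricted to non-trivial splits (2 <= |side| <= n-2)."""
    all_leaves = frozenset(root.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            side = walk(child)
            canon = all_leaves - side if anchor in side else side
            if 2 <= len(canon) <= len(all_leaves) - 2:
                splits.add(canon)
            below |= side
        return below

    walk(root)
    return splits


def _pair_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mismatch counts, overlap counts) over all sample pairs, vectorized."""
    observed = calls != MISSING
    n = calls.shape[0]
    mism = np.zeros((n, n), dtype=np.int64)
    over = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = observed[i] & observed[i + 1 :]
        diff = both & (calls[i] != calls[i + 1 :])
        over[i, i + 1 :] = both.sum(axis=1)
        mism[i, i + 1 :] = diff.sum(axis=1)
    mism += mism.T
    over += over.T
    return mism, over


def pairwise_mismatch(matrix: PseudohaploidMatrix) -> pd.DataFrame:
    """Mismatch rate per unordered sample pair.

    m = differing calls / jointly non-missing panel sites.  Pairs with no
    overlap are flagged unusable (m = NaN).
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples")
    mism, over = _pair_stats(matrix.calls)
    rows = []
    for i, j in itertools.combinations(range(len(matrix.samples)), 2):
        n_ov = int(over[i, j])
        rows.append(
            {
                "a": matrix.samples[i],
                "b": matrix.samples[j],
                "mismatch": mism[i, j] / n_ov if n_ov else np.nan,
                "overlap": n_ov,
                "usable": n_ov > 0,
            }
        )
    return pd.DataFrame(rows)


def kinship_pihat(
    mismatch: pd.DataFrame,
    baseline_strategy: str = "median",
    designated_pairs: list[tuple[str, str]] | None = None,
) -> list[KinshipEstimate]:
    """Moment estimator of the IBD fraction pi per sample pair.

    The baseline m_bar is the median mismatch across pairs (robust to a
    few related pairs contaminating the presumed-unrelated set) or the
    mean over explicitly designated unrelated pairs.
    """
    usable = mismatch[mismatch["usable"]]
    if baseline_strategy == "median":
        if len(usable) < 3:
            raise ValueError("need >= 3 usable pairs for a median baseline")
        m_bar = float(usable["mismatch"].median())
    elif baseline_strategy == "designated_pairs":
        if not designated_pairs:
            raise ValueError("designated_pairs required for that baseline strategy")
        keys = {frozenset(p) for p in designated_pairs}
        sel = usable[
            [frozenset((a, b)) in keys for a, b in zip(usable["a"], usable["b"])]
        ]
        if sel.empty:
            raise ValueError("no designated pairs found in the mismatch table")
        m_bar = float(sel["mismatch"].mean())
    else:
        raise ValueError(f"unknown baseline strategy {baseline_strategy!r}")
    if m_bar == 0:
        raise ValueError("degenerate panel: baseline mismatch is zero")
    out = []
    for _, row in usable.iterrows():
        pi = float(np.clip(2.0 * (1.0 - row["mismatch"] / m_bar), 0.0, 1.0))
        out.append(
            KinshipEstimate(
                pair=(row["a"], row["b"]),
                mismatch_rate=float(row["mismatch"]),
                baseline=m_bar,
                pi_hat=pi,
                n_overlapping_sites=int(row["overlap"]),
            )
        )
    return out


def ibs_distance(matrix: PseudohaploidMatrix) -> DistanceMatrix:
    """Pairwise 1-IBS distances (mismatch rates) between samples."""
    mism, over = _pair_stats(matrix.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(over > 0, mism / np.maximum(over, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(matrix.samples), d, over)


def neighbor_joining(dist: DistanceMatrix) -> TreeWithSupport:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lowest (i, j) taxon-index pair for
    determinism.  Negative branch lengths are clamped to zero with the
    deficit transferred to the sibling edge, preserving path lengths.
    """
    d = np.asarray(dist.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN (unusable pair)")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name) for name in dist.labels]
    d = d.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> TreeNode:
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        parent.children = [(nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0))]
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        parent = join(i, j, li, lj)
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (sub[a, :] + sub[b, :] - sub[a, b])
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for c, k in enumerate(active):
            d[-1, k] = d[k, -1] = new_d[c]
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        root.children = [
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    elif len(active) == 2:
        i, j = active
        root.children = [(nodes[i], d[i, j] / 2), (nodes[j], d[i, j] / 2)]
    else:
        root = nodes[active[0]]
    return TreeWithSupport(root=root)


def bootstrap_tree(
    matrix: PseudohaploidMatrix,
    rng: np.random.Generator,
    n_reps: int = DEFAULT_BOOTSTRAPS,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> TreeWithSupport:
    """IBS neighbor-joining tree with genomic-block bootstrap supports.

    5-Mb blocks of panel sites are resampled with replacement to the
    original block count; IBS and NJ are recomputed per replicate, and
    each internal edge of the point-estimate tree receives the fraction
    of replicates containing the same (unrooted) bipartition.
    """
    chrom = matrix.panel.sites["chrom"].to_numpy()
    pos = matrix.panel.sites["pos"].to_numpy()
    blocks = assign_blocks(chrom, pos, block_bp)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError("need >= 2 genomic blocks to bootstrap")

    point = neighbor_joining(ibs_distance(matrix))
    target = point.bipartitions()
    counts = {split: 0 for split in target}

    observed = matrix.calls != MISSING
    n = matrix.calls.shape[0]
    # per-block pairwise mismatch/overlap counts, summed per replicate
    block_mism = np.zeros((uniq.size, n, n), dtype=np.int64)
    block_over = np.zeros((uniq.size, n, n), dtype=np.int64)
    for k, b in enumerate(uniq):
        cols = blocks == b
        sub = matrix.calls[:, cols]
        obs = observed[:, cols]
        for i in range(n):
            both = obs[i] & obs[i + 1 :]
            diff = both & (sub[i] != sub[i + 1 :])
            block_over[k, i, i + 1 :] = both.sum(axis=1)
            block_mism[k, i, i + 1 :] = diff.sum(axis=1)
        block_mism[k] += block_mism[k].T
        block_over[k] += block_over[k].T

    for _ in range(n_reps):
        pick = rng.integers(0, uniq.size, size=uniq.size)
        mism = block_mism[pick].sum(axis=0)
        over = block_over[pick].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dvals = np.where(over > 0, mism / np.maximum(over, 1), np.nan)
        np.fill_diagonal(dvals, 0.0)
        try:
            rep = neighbor_joining(
                DistanceMatrix(tuple(matrix.samples), dvals, over)
            )
        except ValueError:
            continue  # replicate lost all overlap for some pair
        rep_splits = rep.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    supports = {s: c / n_reps for s, c in counts.items()}
    _annotate_supports(point.root, supports)
    return TreeWithSupport(root=point.root, supports=supports, n_replicates=n_reps)


def _annotate_supports(root: TreeNode, supports: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(root.leaves())
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        canon = all_leaves - below if anchor in below else below
        if canon in supports:
            node.support = supports[canon]
        return below

    walk(root)
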