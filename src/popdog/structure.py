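"""Population-structure summaries: genotype PCA and neighbor-joining trees.

PCA uses GRM standardization — genotype dosages centered by 2p and scaled by
sqrt(2p(1−p)) per SNP, missing entries contributing 0 after centering — and
an eigendecomposition of the resulting individual × individual covariance.

Neighbor joining is the classic Saitou–Nei agglomeration on a 1 − IBS
distance matrix, exact on additive distances, with deterministic
lexicographic tie-breaking on the Q-criterion and standard negative-branch
clamping (deficit transferred to the sibling edge). Trees serialize to
Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diversity import DistanceMatrix
from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    individual_ids: list[str]
    populations: list[str]
    coordinates: np.ndarray      # individuals x components (PC scores)
    eigenvalues: np.ndarray      # non-increasing
    variance_fraction: np.ndarray


def pca(panel: GenotypePanel, n_components: int = 10) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Monomorphic SNPs are excluded; missing genotypes are mean-imputed (zero
    after centering). Components are ordered by decreasing eigenvalue of
    the genetic relationship matrix; coordinates are eigenvectors scaled by
    the square root of their eigenvalue.
    """
    if n_components > panel.n_individuals - 1:
        raise ValueError("n_components must be <= individuals - 1")
    p = panel.minor_allele_frequency()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    g = panel.genotypes[:, poly].astype(float)
    p = p[poly]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[panel.genotypes[:, poly] == MISSING] = 0.0
    grm = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(grm)
    order = np.argsort(eigval)[::-1][:n_components]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    total = np.trace(grm)
    return PcaResult(
        individual_ids=panel.individual_ids,
        populations=[ind.population for ind in panel.individuals],
        coordinates=eigvec * np.sqrt(eigval),
        eigenvalues=eigval,
        variance_fraction=eigval / total if total > 0 else eigval * np.nan,
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree stored with an arbitrary internal root."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.label)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt_label(label: str) -> str:
            if any(c in label for c in " ()[]:;,'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(node: TreeNode) -> str:
            if node.is_leaf():
                return fmt_label(node.label)
            inner = ",".join(
                f"{walk(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return walk(self.root) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise path-length distances between leaves."""
        labels = self.leaf_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.label: 0.0}
            sub: list[dict[str, float]] = []
            for child, length in node.children:
                d = below(child)
                sub.append({lab: v + length for lab, v in d.items()})
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for la, va in sub[a].items():
                        for lb, vb in sub[b].items():
                            dist[index[la], index[lb]] = va + vb
                            dist[index[lb], index[la]] = va + vb
            merged: dict[str, float] = {}
            for d in sub:
                merged.update(d)
            return merged

        below(self.root)
        return DistanceMatrix(labels, dist)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (r−2)d(i,j) − R_i − R_j is
    joined; ties are broken by the lexicographically smallest (sorted) label
    pair. Negative branch lengths are clamped to 0 with the deficit moved to
    the sibling branch. Exact on additive distances.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    d = {
        (a, b): float(dist.values[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }
    if any(v < 0 for v in d.values()):
        raise ValueError("negative distances not allowed")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in labels}
    active = list(labels)
    join_count = 0

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb, la = lb + la, 0.0
            logger.debug("negative branch clamped")
        if lb < 0:
            la, lb = la + lb, 0.0
            logger.debug("negative branch clamped")
        return la, max(lb, 0.0)

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * d[(a, b)] - row_sum[a] - row_sum[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best is None or key < best)
                ):
                    best, best_q = key, q
        a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = clamp(la, lb)
        new_label = f"__internal_{join_count}"
        join_count += 1
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
            d[(new_label, c)] = d[(c, new_label)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b, c = active
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return PhyloTree(root=root)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def unrooted_splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, for topology comparison."""
    all_leaves = frozenset(tree.leaf_labels())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(walk(child) for child, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = min(below, all_leaves - below, key=lambda s: sorted(s))
            splits.add(side)
        return below

    for child, _ in tree.root.children:
        walk(child)
    return splits
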