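"""Population structure: GRM + PCA, identity-by-state distances, and a
neighbor-joining tree with Newick export.

The genomic relationship matrix follows the GCTA definition
G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)); the GRM is
eigen-decomposed for PCA.  The 1−IBS distance matrix feeds the
neighbor-joining tree only, mirroring the usual GCTA/PLINK/PHYLIP
toolchain split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .panel import MISSING, GenotypePanel


# ---------------------------------------------------------------------------
# GRM + PCA
# ---------------------------------------------------------------------------

def compute_grm(panel: GenotypePanel) -> np.ndarray:
    """GCTA-style genomic relationship matrix.

    Missing dosages are mean-imputed per site; monomorphic sites
    (p in {0, 1}) are excluded with a warning.
    """
    X = panel.genotypes.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=1) / 2.0
    poly = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    n_dropped = int((~poly).sum())
    if n_dropped:
        warnings.warn(f"compute_grm: excluded {n_dropped} monomorphic sites")
    X, p = X[poly], p[poly]
    # mean imputation == centring missing entries at zero
    Z = (X - 2.0 * p[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    Z = np.nan_to_num(Z, nan=0.0)
    m = Z.shape[0]
    if m == 0:
        raise ValueError("no polymorphic sites for GRM")
    return Z.T @ Z / m


@dataclass
class PCAResult:
    """Top-k eigenpairs of the GRM.

    ``pve`` normalises each eigenvalue by the sum of all positive
    eigenvalues (percent); ``pve_topk`` renormalises over the retained
    components only, matching the common practice of reporting the first
    few PCs as shares of the variance they jointly explain.
    """

    coordinates: np.ndarray  # samples x k, eigvec * sqrt(eigval)
    eigenvalues: np.ndarray
    pve: np.ndarray
    pve_topk: np.ndarray = field(default=None)  # type: ignore[assignment]
    eigenvectors: np.ndarray = field(default=None)  # type: ignore[assignment]


def pca(grm: np.ndarray, k: int) -> PCAResult:
    """Top-k principal components of a (symmetric) GRM."""
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    if grm.shape != (n, n) or not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be square symmetric")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    w, v = scipy.linalg.eigh(grm)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos_sum = np.sum(np.maximum(w, 0.0))
    pve_all = w / pos_sum * 100.0
    wk, vk = w[:k], v[:, :k]
    coords = vk * np.sqrt(np.maximum(wk, 0.0))[None, :]
    topk_sum = np.sum(np.maximum(wk, 0.0))
    return PCAResult(
        coordinates=coords,
        eigenvalues=wk,
        pve=pve_all[:k],
        pve_topk=wk / topk_sum * 100.0,
        eigenvectors=vk,
    )


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0.0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def ibs_distance(panel: GenotypePanel) -> DistanceMatrix:
    """1 − average identity-by-state over jointly called sites.

    Per site a pair shares 0, 1 or 2 alleles (IBS = 2 − |dosage
    difference|); the distance is one minus the mean of IBS/2.
    """
    X = panel.genotypes
    n = panel.n_samples
    called = X != MISSING
    D = np.zeros((n, n))
    for i in range(n):
        joint = called[:, i:i + 1] & called[:, i + 1:]
        diff = np.abs(X[:, i:i + 1].astype(np.int16)
                      - X[:, i + 1:].astype(np.int16))
        sim = np.where(joint, 2 - diff, 0).sum(axis=0)
        counts = joint.sum(axis=0)
        for off, (s, c) in enumerate(zip(sim, counts)):
            j = i + 1 + off
            if c == 0:
                raise ValueError(
                    f"samples {panel.samples[i]!r} and {panel.samples[j]!r} "
                    "share no jointly called site"
                )
            D[i, j] = D[j, i] = 1.0 - (s / 2.0) / c
    return DistanceMatrix(labels=list(panel.samples), matrix=D)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of an (unrooted-style) tree; children carry branch lengths."""

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.label)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (for additivity checks)."""
        labels = sorted(self.leaf_labels())
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            merged: dict[str, float] = {}
            groups: list[dict[str, float]] = []
            for child, blen in node.children:
                sub = {lab: d + blen for lab, d in below(child).items()}
                for done in groups:
                    for la, da in done.items():
                        for lb, db in sub.items():
                            i, j = index[la], index[lb]
                            D[i, j] = D[j, i] = da + db
                groups.append(sub)
                merged.update(sub)
            return merged

        below(self.root)
        return DistanceMatrix(labels=labels, matrix=D)

    def bipartitions(self) -> list[frozenset]:
        """Leaf sets under each internal edge (for monophyly checks)."""
        out: list[frozenset] = []

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            leaves: set[str] = set()
            for child, _ in node.children:
                sub = walk(child)
                out.append(sub)
                leaves |= sub
            return frozenset(leaves)

        walk(self.root)
        return out

    def is_monophyletic(self, labels) -> bool:
        """True when some edge splits exactly ``labels`` from the rest."""
        want = frozenset(labels)
        all_leaves = frozenset(self.leaf_labels())
        comp = all_leaves - want
        return any(b == want or b == comp for b in self.bipartitions())


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimising Q(i,j) = (r−2)·d(i,j) − R_i − R_j is joined at
    each step; ties pick the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister
    branch so path lengths through the join are preserved.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.matrix.astype(float).copy()
    nodes = [TreeNode(lab) for lab in dist.labels]
    tags = list(dist.labels)  # smallest leaf label per active cluster
    active = list(range(n))

    def join_lengths(dij: float, li: float, lj: float):
        if li < 0.0:
            lj, li = dij, 0.0
        elif lj < 0.0:
            li, lj = dij, 0.0
        return li, lj

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((tags[active[a]], tags[active[b]]))), a, b)
            for a, b in cand if a < b
        )
        _, ai, bj = best
        i, j = active[ai], active[bj]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[bj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = join_lengths(dij, li, lj)

        parent = TreeNode()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # distances from the new node to the remainder
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_row
        D[active, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        tags[i] = min(tags[i], tags[j])
        active.remove(j)

    # final three-way join (unrooted star centre)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set(" ()[]':;,")


def _fmt_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialise the tree as a Newick string with branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _fmt_label(node.label)
        inner = ",".join(f"{render(ch)}:{blen:.10g}"
                         for ch, blen in node.children)
        return f"({inner})"

    return render(tree.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (labels, branch lengths; no comments)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def read_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                ch = s[pos]
                if ch == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(ch)
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "():,;":
            pos += 1
        return s[start:pos]

    def read_clade() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, blen = read_clade()
                node.children.append((child, blen))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        label = read_label()
        if label:
            if node.children:
                pass  # internal labels ignored
            else:
                node.label = label
        blen = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            blen = float(s[start:pos])
        return node, blen

    root, _ = read_clade()
    return Tree(root=root)
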