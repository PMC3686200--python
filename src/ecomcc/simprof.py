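"""Group-average (UPGMA) hierarchical clustering with SIMPROF validation.

SIMPROF (similarity profile test) asks whether a set of samples with no
a-priori grouping contains multivariate structure: the observed sorted vector
of within-set pairwise dissimilarities is compared with its expectation under
independent within-taxon permutation, which destroys taxon associations while
preserving each taxon's abundance distribution.  Clusters are the maximal
subtrees of the UPGMA dendrogram whose profile test is non-significant.

UPGMA is implemented here rather than delegated so the tie-break is fully
deterministic: among equally close cluster pairs, the pair whose
lexicographically smallest member labels come first is merged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import spawn_seed
from .community import CommunityMatrix, DissimilarityMatrix, bray_curtis

__all__ = [
    "DendrogramNode",
    "Dendrogram",
    "SimprofResult",
    "upgma",
    "simprof_test",
    "significant_clusters",
]


@dataclass
class DendrogramNode:
    """A node of the merge tree: leaves carry a sample label, internal nodes
    the merge height (mean cross-pair dissimilarity) and two children."""

    height: float
    labels: tuple            # sorted sample labels beneath this node
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class Dendrogram:
    root: DendrogramNode
    sample_ids: list

    def __post_init__(self) -> None:
        # UPGMA monotonicity: heights non-decreasing from leaves to root
        def check(node: DendrogramNode) -> None:
            for child in (node.left, node.right):
                if child is not None and child.height > node.height + 1e-12:
                    raise ValueError("dendrogram heights decrease toward the root")
                if child is not None:
                    check(child)

        check(self.root)
        if set(self.root.labels) != set(map(str, self.sample_ids)):
            raise ValueError("dendrogram leaf set does not match sample set")

    def to_newick(self) -> str:
        """Newick string; branch lengths place each merge at its height."""

        def render(node: DendrogramNode, parent_height: float) -> str:
            length = max(0.0, parent_height - node.height)
            if node.is_leaf:
                return f"{node.labels[0]}:{length:.10g}"
            inner = ",".join(
                render(c, node.height) for c in (node.left, node.right)
            )
            return f"({inner}):{length:.10g}"

        return render(self.root, self.root.height) + ";"

    def nodes_topdown(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.left, node.right])
        return out


def upgma(D: DissimilarityMatrix) -> Dendrogram:
    """Group-average-fusion hierarchical clustering.

    Inter-cluster distance is the arithmetic mean of all cross-pair
    dissimilarities; ties broken by the lexicographically smallest member
    label so the output is deterministic.
    """
    n = D.n_samples
    if n < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    labels = [str(s) for s in D.sample_ids]
    nodes = [DendrogramNode(0.0, (lab,)) for lab in labels]
    sizes = [1] * n
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.values[i, j])
    active = list(range(n))
    next_id = n
    store = {i: nodes[i] for i in range(n)}

    def d_of(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                d = d_of(i, j)
                rep = tuple(sorted((store[i].labels[0], store[j].labels[0])))
                key = (d, rep)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        h = d_of(i, j)
        merged = DendrogramNode(
            height=h,
            labels=tuple(sorted(store[i].labels + store[j].labels)),
            left=store[i] if store[i].labels[0] < store[j].labels[0] else store[j],
            right=store[j] if store[i].labels[0] < store[j].labels[0] else store[i],
        )
        store[next_id] = merged
        si, sj = sizes[i], sizes[j]
        sizes.append(si + sj)
        for k in active:
            if k in (i, j):
                continue
            d_new = (si * d_of(i, k) + sj * d_of(j, k)) / (si + sj)
            dist[(k, next_id) if k < next_id else (next_id, k)] = d_new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    return Dendrogram(root=store[active[0]], sample_ids=labels)


@dataclass
class SimprofResult:
    """Outcome of one similarity-profile test."""

    labels: tuple            # sample labels tested
    pi: float                # observed profile departure statistic
    p_perm: float
    n_perm: int
    alpha: float
    tested: bool             # False for untestable subsets (< 3 samples)

    @property
    def significant(self) -> bool:
        """True when the profile shows structure at level alpha."""
        return self.tested and self.p_perm < self.alpha


def _profiles_from_permuted(X: np.ndarray, rng: np.random.Generator, n_perm: int) -> np.ndarray:
    """Sorted Bray-Curtis profiles of n_perm within-taxon permutations of X."""
    n, t = X.shape
    iu, ju = np.triu_indices(n, k=1)
    # chunk permutations so the (chunk, n_pairs, t) workspace stays small
    chunk = max(1, int(2e7 // max(1, iu.size * t)))
    out = np.empty((n_perm, iu.size))
    for start in range(0, n_perm, chunk):
        r = min(chunk, n_perm - start)
        # independent shuffle of every (replicate, taxon) column in one call
        Xp = rng.permuted(np.tile(X, (r, 1, 1)), axis=1)
        num = np.abs(Xp[:, iu, :] - Xp[:, ju, :]).sum(axis=2)
        den = Xp[:, iu, :].sum(axis=2) + Xp[:, ju, :].sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
        d.sort(axis=1)
        out[start:start + r] = d
    return out


def _observed_profile(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    num = np.abs(X[iu] - X[ju]).sum(axis=1)
    den = X[iu].sum(axis=1) + X[ju].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return np.sort(d)


def simprof_test(
    M: CommunityMatrix,
    subset=None,
    n_perm_mean: int = 1000,
    n_perm_test: int = 999,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> SimprofResult:
    """Similarity-profile permutation test on a (transformed) community matrix.

    The observed profile is the sorted vector of pairwise Bray-Curtis
    dissimilarities within ``subset``; the null shuffles each taxon's values
    independently across the subset's samples.  pi = sum_k |s_(k) - sbar_(k)|
    against a mean profile from ``n_perm_mean`` permutations; the p-value from
    ``n_perm_test`` further permutations.  The random stream is consumed in
    sorted-label order so reordering input rows/columns cannot change the
    result.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if subset is None:
        subset = M.sample_ids
    subset = sorted(str(s) for s in subset)
    missing = set(subset) - set(map(str, M.sample_ids))
    if missing:
        raise KeyError(f"unknown sample label(s): {sorted(missing)}")
    if len(subset) < 3:
        return SimprofResult(
            labels=tuple(subset), pi=0.0, p_perm=1.0, n_perm=0, alpha=alpha, tested=False
        )

    ab = M.abundance.copy()
    ab.index = ab.index.astype(str)
    X = ab.loc[subset, sorted(map(str, ab.columns))].to_numpy(dtype=float)
    obs = _observed_profile(X)

    key = zlib.crc32("|".join(subset).encode("utf-8"))
    rng = np.random.default_rng(spawn_seed(seed or 0, "simprof", key))
    mean_profile = _profiles_from_permuted(X, rng, n_perm_mean).mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).sum())
    null_profiles = _profiles_from_permuted(X, rng, n_perm_test)
    pi_null = np.abs(null_profiles - mean_profile[None, :]).sum(axis=1)
    tol = 1e-12 * (1.0 + pi_obs)
    p = (1 + int(np.count_nonzero(pi_null >= pi_obs - tol))) / (1 + n_perm_test)
    return SimprofResult(
        labels=tuple(subset), pi=pi_obs, p_perm=p, n_perm=n_perm_test, alpha=alpha, tested=True
    )


def significant_clusters(
    M: CommunityMatrix,
    D: DissimilarityMatrix | None = None,
    alpha: float = 0.05,
    n_perm_mean: int = 1000,
    n_perm_test: int = 999,
    seed: int | None = 0,
) -> pd.Series:
    """SIMPROF-validated flat clustering.

    Top-down traversal of the UPGMA tree: a node whose similarity profile is
    significant is split further; traversal stops at nodes without significant
    internal structure, whose sample sets become the output clusters.
    Returns a Series mapping sample label -> cluster id ("cluster-1", ...).
    """
    if D is None:
        D = bray_curtis(M)
    tree = upgma(D)
    clusters: list[tuple] = []

    def visit(node: DendrogramNode) -> None:
        res = simprof_test(
            M,
            subset=node.labels,
            n_perm_mean=n_perm_mean,
            n_perm_test=n_perm_test,
            alpha=alpha,
            seed=seed,
        )
        if res.significant and not node.is_leaf:
            visit(node.left)
            visit(node.right)
        else:
            clusters.append(node.labels)

    visit(tree.root)
    assignment = {}
    for k, labs in enumerate(sorted(clusters, key=lambda c: c[0]), start=1):
        for lab in labs:
            assignment[lab] = f"cluster-{k}"
    return pd.Series({str(s): assignment[str(s)] for s in M.sample_ids}, name="cluster")
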