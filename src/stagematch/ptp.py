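"""Maximum-likelihood Poisson tree process (PTP) species delimitation.

PTP works on a substitution-scaled (non-ultrametric) gene tree and models
branch lengths as draws from two exponential distributions: one for
between-species branches (speciation) and one for within-species branches
(coalescence), the former typically much longer. A delimitation is a
partition of the tips into species such that every species is a subtree;
equivalently, an antichain of "species root" nodes covering all tips.
Branches strictly inside a species subtree are within-class; all others
(including each species' stem) are between-class. The maximum-likelihood
partition is found either by exhaustive enumeration of antichain covers
(small trees) or by a seeded greedy hill-climb over split/merge moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .core import ClusterPartition, DataError, GeneTree

EXACT_TIP_LIMIT = 12


@dataclass
class _PtpIndex:
    """Array view of the tree used by both search strategies."""

    nodes: list                      # preorder; nodes[0] is the root
    parent: np.ndarray               # parent index, -1 for root
    children: list[list[int]]
    is_tip: np.ndarray
    length: np.ndarray               # edge length above each node (0 for root)
    sub_sum: np.ndarray              # sum of positive-length edges strictly below
    sub_cnt: np.ndarray              # count of positive-length edges strictly below
    tip_labels: list[str | None]
    n_zero_edges: int

    @classmethod
    def build(cls, gt: GeneTree) -> "_PtpIndex":
        if gt.n_tips < 2:
            raise DataError("PTP needs a tree with at least 2 tips")
        nodes = list(gt.tree.preorder_node_iter())
        idx = {n: i for i, n in enumerate(nodes)}
        N = len(nodes)
        parent = np.full(N, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(N)]
        is_tip = np.zeros(N, dtype=bool)
        length = np.zeros(N)
        labels: list[str | None] = [None] * N
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                parent[i] = idx[n.parent_node]
                children[parent[i]].append(i)
                length[i] = n.edge.length or 0.0
            if n.is_leaf():
                is_tip[i] = True
                labels[i] = n.taxon.label
        sub_sum = np.zeros(N)
        sub_cnt = np.zeros(N, dtype=int)
        for i in range(N - 1, -1, -1):
            for c in children[i]:
                own = (length[c], 1) if length[c] > 0 else (0.0, 0)
                sub_sum[i] += sub_sum[c] + own[0]
                sub_cnt[i] += sub_cnt[c] + own[1]
        n_zero = int(np.sum((length == 0.0) & (parent >= 0)))
        return cls(nodes, parent, children, is_tip, length, sub_sum, sub_cnt, labels, n_zero)

    @property
    def n_branches(self) -> int:
        # root edge excluded; zero-length branches excluded from the likelihood
        return int(self.sub_cnt[0])

    @property
    def total_length(self) -> float:
        return float(self.sub_sum[0])

    def tips_below(self, i: int) -> frozenset[str]:
        out = []
        stack = [i]
        while stack:
            j = stack.pop()
            if self.is_tip[j]:
                out.append(self.tip_labels[j])
            else:
                stack.extend(self.children[j])
        return frozenset(out)


def _exp_class_loglik(n: int, total: float) -> float:
    """Maximized log-likelihood of n exponential draws summing to `total`."""
    if n == 0:
        return 0.0
    return n * (np.log(n / total) - 1.0)


def _antichain_loglik(index: _PtpIndex, roots: frozenset[int]) -> tuple[float, float, float, bool]:
    """(logL, rate_within, rate_between, degenerate_flag) for an antichain."""
    n_w = int(sum(index.sub_cnt[r] for r in roots))
    s_w = float(sum(index.sub_sum[r] for r in roots))
    n_b = index.n_branches - n_w
    s_b = index.total_length - s_w
    logL = _exp_class_loglik(n_w, s_w) + _exp_class_loglik(n_b, s_b)
    rate_w = n_w / s_w if n_w else np.nan
    rate_b = n_b / s_b if n_b else np.nan
    return float(logL), rate_w, rate_b, (n_w == 0 or n_b == 0)


def _enumerate_antichains(index: _PtpIndex):
    """All antichain covers (every tip under exactly one species root)."""

    def rec(i: int):
        if index.is_tip[i]:
            return [frozenset([i])]
        combos = [frozenset([i])]
        parts = [rec(c) for c in index.children[i]]
        acc = [frozenset()]
        for p in parts:
            acc = [a | b for a in acc for b in p]
        combos.extend(acc)
        return combos

    return rec(0)


def count_antichain_covers(gt: GeneTree) -> int:
    """Number of candidate PTP partitions (antichain covers) of a tree."""
    index = _PtpIndex.build(gt)

    def g(i: int) -> int:
        if index.is_tip[i]:
            return 1
        prod = 1
        for c in index.children[i]:
            prod *= g(c)
        return 1 + prod

    return g(0)


# ---------------------------------------------------------------------------
# Public likelihood on an explicit partition


def ptp_loglik(gt: GeneTree, partition: ClusterPartition):
    """Two-class exponential log-likelihood of a given partition.

    Each cluster must be a subtree of the gene tree (the tips below the
    cluster's MRCA are exactly the cluster). Returns
    ``(logL, rate_within, rate_between)``; an empty class has an undefined
    (NaN) rate and contributes nothing — the model then collapses toward the
    single-class null.
    """
    index = _PtpIndex.build(gt)
    tip_idx = {lab: i for i, lab in enumerate(index.tip_labels) if lab is not None}
    roots = []
    for cluster in partition.clusters:
        tips = gt.tips_of_specimens(cluster)
        if gt.specimens_of(tips) != set(cluster):
            raise DataError("cluster does not align with haplotype tip membership")
        ids = [tip_idx[t] for t in tips]
        mrca = _mrca(index, ids)
        if index.tips_below(mrca) != frozenset(tips):
            raise DataError("cluster tips are not a connected subtree (not a clade)")
        roots.append(mrca)
    covered = frozenset().union(*(index.tips_below(r) for r in roots)) if roots else frozenset()
    all_tips = index.tips_below(0)
    if covered != all_tips:
        raise DataError("partition does not cover all tips of the tree")
    logL, rw, rb, _ = _antichain_loglik(index, frozenset(roots))
    return logL, rw, rb


def _mrca(index: _PtpIndex, ids: list[int]) -> int:
    paths = []
    for i in ids:
        path = []
        j = i
        while j >= 0:
            path.append(j)
            j = index.parent[j]
        paths.append(path[::-1])
    k = 0
    while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
        k += 1
    return paths[0][k - 1]


# ---------------------------------------------------------------------------
# Model / results


@dataclass
class PTPResults:
    """Fitted PTP delimitation."""

    partition: ClusterPartition
    cluster_tip_sets: list[frozenset]
    rate_within: float
    rate_between: float
    loglik: float
    null_loglik: float
    lrt_df: int
    lrt_pvalue: float
    method: str
    degenerate: bool          # one branch class empty (model collapsed to null)
    n_zero_length_excluded: int

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_tip_sets)

    def summary(self) -> str:
        lines = [
            f"Poisson tree process fit ({self.method})",
            "=" * 41,
            f"delimited clusters        {self.n_clusters:>12d}",
            f"rate within / between     {self.rate_within:>12.6g} / {self.rate_between:.6g}",
            f"logL (two-class model)    {self.loglik:>12.4f}",
            f"logL (one-class null)     {self.null_loglik:>12.4f}",
            f"LRT (df={self.lrt_df}) p-value        {self.lrt_pvalue:>12.4g}",
        ]
        if self.n_zero_length_excluded:
            lines.append(f"zero-length branches excluded: {self.n_zero_length_excluded}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "rate_within": self.rate_within,
            "rate_between": self.rate_between,
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "lrt_df": self.lrt_df,
            "lrt_pvalue": self.lrt_pvalue,
            "method": self.method,
        }


class PTP:
    """PTP delimitation model for a substitution-scaled gene tree.

    The root edge is ignored and any outgroup must be pruned beforehand.
    Zero-length branches are excluded from the likelihood (reported, not
    penalized).
    """

    def __init__(self, tree: GeneTree):
        self.tree = tree
        self._index = _PtpIndex.build(tree)

    def fit(self, method: str = "heuristic", seed: int = 0, n_restarts: int = 5,
            df: int = 3) -> PTPResults:
        if method == "exact":
            roots = self._fit_exact()
        elif method == "heuristic":
            roots = self._fit_heuristic(seed=seed, n_restarts=n_restarts)
        else:
            raise ValueError(f"unknown PTP search method {method!r}")
        return self._results(roots, method, df)

    # -- exact --------------------------------------------------------------

    def _fit_exact(self) -> frozenset[int]:
        if self.tree.n_tips > EXACT_TIP_LIMIT:
            raise DataError(
                f"exact PTP enumerates all partitions and is limited to "
                f"{EXACT_TIP_LIMIT} tips ({self.tree.n_tips} given); use the heuristic"
            )
        best, best_logL = None, -np.inf
        for roots in _enumerate_antichains(self._index):
            logL = _antichain_loglik(self._index, roots)[0]
            if logL > best_logL + 1e-12:
                best, best_logL = roots, logL
        return best

    # -- heuristic ----------------------------------------------------------

    def _fit_heuristic(self, seed: int, n_restarts: int) -> frozenset[int]:
        rng = np.random.default_rng(seed)
        index = self._index
        tips = frozenset(np.flatnonzero(index.is_tip).tolist())
        starts = [frozenset([0]), tips]
        for _ in range(max(0, n_restarts - len(starts))):
            starts.append(self._random_antichain(rng))
        best, best_logL = None, -np.inf
        for start in starts:
            roots, logL = self._hill_climb(start)
            if logL > best_logL + 1e-12:
                best, best_logL = roots, logL
        return best

    def _random_antichain(self, rng: np.random.Generator) -> frozenset[int]:
        index = self._index
        roots = []
        stack = [0]
        while stack:
            i = stack.pop()
            if index.is_tip[i] or rng.random() < 0.5:
                roots.append(i)
            else:
                stack.extend(index.children[i])
        return frozenset(roots)

    def _hill_climb(self, roots: frozenset[int]) -> tuple[frozenset[int], float]:
        index = self._index
        cur = roots
        cur_logL = _antichain_loglik(index, cur)[0]
        while True:
            best_move, best_logL = None, cur_logL
            # split moves: replace an internal species root by its children
            for r in cur:
                if not index.is_tip[r]:
                    cand = (cur - {r}) | frozenset(index.children[r])
                    logL = _antichain_loglik(index, cand)[0]
                    if logL > best_logL + 1e-12:
                        best_move, best_logL = cand, logL
            # merge moves: replace a full sibling set by its parent
            parents = {index.parent[r] for r in cur if index.parent[r] >= 0}
            for p in parents:
                if all(c in cur for c in index.children[p]):
                    cand = (cur - frozenset(index.children[p])) | {p}
                    logL = _antichain_loglik(index, cand)[0]
                    if logL > best_logL + 1e-12:
                        best_move, best_logL = cand, logL
            if best_move is None:
                return cur, cur_logL
            cur, cur_logL = best_move, best_logL

    # -- assembly -----------------------------------------------------------

    def _results(self, roots: frozenset[int], method: str, df: int) -> PTPResults:
        index = self._index
        logL, rate_w, rate_b, degenerate = _antichain_loglik(index, roots)
        null_logL = _exp_class_loglik(index.n_branches, index.total_length)
        lrt = max(0.0, 2.0 * (logL - null_logL))
        pvalue = float(chi2.sf(lrt, df)) if lrt > 0 else 1.0
        tip_sets = sorted((index.tips_below(r) for r in roots), key=lambda s: sorted(s))
        clusters = [frozenset(self.tree.specimens_of(ts)) for ts in tip_sets]
        return PTPResults(
            partition=ClusterPartition(gene=self.tree.gene, method="PTP", clusters=clusters),
            cluster_tip_sets=tip_sets,
            rate_within=float(rate_w),
            rate_between=float(rate_b),
            loglik=logL,
            null_loglik=float(null_logL),
            lrt_df=df,
            lrt_pvalue=pvalue,
            method=method,
            degenerate=degenerate,
            n_zero_length_excluded=index.n_zero_edges,
        )


def fit_ptp_exact(tree: GeneTree, df: int = 3) -> PTPResults:
    """Exhaustive-enumeration PTP fit (brute-force oracle, <= 12 tips)."""
    return PTP(tree).fit(method="exact", df=df)


def fit_ptp_heuristic(tree: GeneTree, seed: int = 0, n_restarts: int = 5,
                      df: int = 3) -> PTPResults:
    """Greedy hill-climbing PTP fit with seeded restarts (any tree size)."""
    return PTP(tree).fit(method="heuristic", seed=seed, n_restarts=n_restarts, df=df)
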