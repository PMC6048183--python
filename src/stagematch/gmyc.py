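"""Single-threshold GMYC species delimitation.

The generalized mixed Yule-coalescent model assumes an ultrametric gene tree
in which branching events older than an unknown threshold age arise from a
Yule (speciation) process and events younger than it from neutral
coalescence within the delimited species. Both processes are rate-scaled
branching processes: during an inter-event interval the speciation process
runs at rate ``lambda_div * k**p_div`` (``k`` = number of species lineages)
and species ``j``'s coalescent at ``lambda_coal * (n_j*(n_j-1))**p_coal``
(``n_j`` = lineages sampled within species ``j``). Exponents of 1 recover
the linear Yule process and the Kingman coalescent; fitted jointly they
absorb departures such as population growth or non-neutral diversification.

The likelihood is the superposition density of the ordered branching times:
each inter-event interval contributes the survival of every active process,
plus the total event rate of the interval for the branching event bounding
it rootward (coalescent-style bookkeeping: with exponents of 1 and a single
species this reduces exactly to the standard Kingman log-density).

The threshold is profiled by scanning one candidate per gap between
consecutive distinct node ages (midpoint convention) plus one candidate
older than the root (= the single-coalescent null). Within a candidate the
two rates have closed-form maxima, leaving a 2-D numeric search over the
exponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .core import ClusterPartition, DataError, GeneTree

_EPS_AGE = 1e-12  # separation imposed between simultaneous events (soft polytomies)
_P_LO, _P_HI = 0.0, 10.0
RATE_MAX = 1e8


class GmycWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Tree indexing


class _TreeIndex:
    """Age-sorted event structure of an ultrametric tree.

    Zero-length internal branches are collapsed to soft polytomies, which are
    then treated as simultaneous events separated by ``_EPS_AGE``.
    """

    def __init__(self, gt: GeneTree, ultrametric_tol: float = 1e-6):
        if gt.n_tips < 3:
            raise DataError("GMYC needs a tree with at least 3 tips")
        if not gt.is_ultrametric(tol=ultrametric_tol):
            raise DataError(f"GMYC input tree is not ultrametric (tol={ultrametric_tol})")
        self.gene_tree = gt
        tree = gt.tree.clone(depth=1)
        tree.collapse_unweighted_edges()  # zero-length internal edges -> polytomies
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        self.tree = tree

        ages = _node_ages(tree)
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        # sort oldest first; deterministic tie-break by preorder position
        order = {n: i for i, n in enumerate(tree.preorder_node_iter())}
        internal.sort(key=lambda n: (-ages[n], order[n]))
        # enforce strictly decreasing ages (simultaneous events _EPS_AGE apart)
        adj = []
        prev = np.inf
        for n in internal:
            a = min(ages[n], prev - _EPS_AGE)
            adj.append(a)
            prev = a
        self.events = internal                      # e_1 (root) .. e_E, oldest first
        self.ages = np.asarray(adj)                 # strictly decreasing
        self.rank = {n: i for i, n in enumerate(internal)}
        self.root_age = self.ages[0]
        self.n_events = len(internal)
        self._leafsets: dict = {}

    def leafset(self, node) -> frozenset:
        try:
            return self._leafsets[node]
        except KeyError:
            if node.is_leaf():
                s = frozenset([node.taxon.label])
            else:
                s = frozenset().union(*(self.leafset(c) for c in node.child_nodes()))
            self._leafsets[node] = s
            return s

    def candidate_thresholds(self) -> list[float]:
        """Midpoints between consecutive distinct event ages, plus one older
        than the root (the single-coalescent configuration)."""
        cands = [self.root_age * 1.05 + _EPS_AGE]
        distinct = self.ages[np.concatenate(([True], np.diff(self.ages) < -1e-9))]
        for hi, lo in zip(distinct[:-1], distinct[1:]):
            cands.append(0.5 * (hi + lo))
        return cands

    def cluster_roots(self, threshold_age: float) -> list:
        """Cluster-root nodes for a given threshold: the lineages crossing it."""
        d = int(np.sum(self.ages > threshold_age))
        if d == 0:
            return [self.tree.seed_node]
        div = set(self.events[:d])
        roots = []
        for node in self.events[:d]:
            for child in node.child_nodes():
                if child not in div:
                    roots.append(child)
        return roots

    def cluster_tip_sets(self, threshold_age: float) -> list[frozenset]:
        return [self.leafset(r) for r in self.cluster_roots(threshold_age)]


def _node_ages(tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    height = max(depths[l] for l in tree.leaf_node_iter())
    return {n: height - d for n, d in depths.items()}


# ---------------------------------------------------------------------------
# Interval table


@dataclass
class GmycInterval:
    """One inter-event interval of the mixed model."""

    duration: float
    n_div: int                      # diversification (between-species) lineages
    coal_counts: tuple[int, ...]    # per-cluster within-species lineage counts
    event: str | None               # process of the event at the rootward end
    event_term_count: int           # k (div) or n*(n-1) (coal) entering the event term


@dataclass
class GmycIntervalTable:
    """Interval decomposition of a tree for one threshold age.

    Carries both the human-readable interval records and the flat arrays the
    likelihood is evaluated from. Every branching event is attached to the
    interval it bounds rootward; ``ev_k`` holds that interval's
    between-species lineage count, and the (``ev_coal_idx``, ``coal_v``)
    pairs index each interval's per-cluster ``n*(n-1)`` values (shared by
    the event-rate and survival terms; ``coal_x`` is the interval length).
    """

    threshold_age: float
    n_div_events: int
    n_coal_events: int
    intervals: list[GmycInterval]
    ev_k: np.ndarray                # per event-interval between-species count
    ev_has_coal: np.ndarray         # bool: event is a within-species coalescence
    ev_coal_idx: np.ndarray         # event index for each coal_v entry
    coal_v: np.ndarray              # n_j*(n_j-1) values, flattened
    coal_x: np.ndarray              # interval duration for each coal_v entry
    div_surv_k: np.ndarray          # (k, x) pairs: diversification survival
    div_surv_x: np.ndarray


def gmyc_interval_table(tree: GeneTree, threshold_age: float) -> GmycIntervalTable:
    """Decompose an ultrametric tree into inter-event intervals under a
    threshold, classifying lineages as between- vs within-species."""
    index = _TreeIndex(tree)
    return _build_table(index, threshold_age)


def _build_table(index: _TreeIndex, T: float) -> GmycIntervalTable:
    ages = index.ages
    E = index.n_events
    d = int(np.sum(ages > T))
    bounds = np.concatenate((ages, [0.0]))

    # cluster assignment of sub-threshold events
    roots = index.cluster_roots(T)
    K = len(roots)
    cluster_of = {}
    for j, r in enumerate(roots):
        stack = [r]
        while stack:
            node = stack.pop()
            if not node.is_leaf():
                cluster_of[index.rank[node]] = j
                stack.extend(node.child_nodes())

    intervals: list[GmycInterval] = []
    ev_k = []
    ev_has_coal = []
    ev_coal_idx = []
    coal_v = []
    coal_x = []
    div_surv = []

    counts = np.ones(K, dtype=int)  # per-cluster lineage counts, top-down
    for m in range(1, E + 1):       # interval J_m: (a_m, a_{m+1}); event e_m rootward
        a_hi, a_lo = bounds[m - 1], bounds[m]
        if a_hi > T >= a_lo:
            # straddling interval: rootward part all-diversification, tipward
            # part has K singleton clusters (no coalescent mass yet)
            x_root, x_tip = a_hi - T, T - a_lo
            ev_k.append(m + 1)
            ev_has_coal.append(False)
            div_surv.append((m + 1, x_root))
            div_surv.append((K, x_tip))
            intervals.append(GmycInterval(x_root, m + 1, (), "diversification", m + 1))
            intervals.append(GmycInterval(x_tip, K, tuple(counts), None, 0))
            continue
        x = a_hi - a_lo
        if a_lo >= T:  # entirely rootward of the threshold
            ev_k.append(m + 1)
            ev_has_coal.append(False)
            div_surv.append((m + 1, x))
            intervals.append(GmycInterval(x, m + 1, (), "diversification", m + 1))
        else:          # entirely tipward: event e_m is a coalescence in its cluster
            j = cluster_of[m - 1]
            counts[j] += 1
            v = counts[j] * (counts[j] - 1)
            ev_k.append(K)
            ev_has_coal.append(True)
            div_surv.append((K, x))
            eidx = len(ev_k) - 1
            for c in counts:
                if c >= 2:
                    ev_coal_idx.append(eidx)
                    coal_v.append(c * (c - 1))
                    coal_x.append(x)
            intervals.append(GmycInterval(x, K, tuple(counts), "coalescent", v))

    return GmycIntervalTable(
        threshold_age=T,
        n_div_events=d,
        n_coal_events=E - d,
        intervals=intervals,
        ev_k=np.asarray(ev_k, dtype=float),
        ev_has_coal=np.asarray(ev_has_coal, dtype=bool),
        ev_coal_idx=np.asarray(ev_coal_idx, dtype=int),
        coal_v=np.asarray(coal_v, dtype=float),
        coal_x=np.asarray(coal_x, dtype=float),
        div_surv_k=np.asarray([p[0] for p in div_surv], dtype=float),
        div_surv_x=np.asarray([p[1] for p in div_surv], dtype=float),
    )


# ---------------------------------------------------------------------------
# Likelihood


def gmyc_loglik(
    table: GmycIntervalTable,
    lambda_div: float,
    p_div: float,
    lambda_coal: float,
    p_coal: float,
) -> float:
    """Mixed Yule-coalescent log-likelihood for one interval table.

    Each event contributes the log of the total branching rate of the
    interval it terminates (rootward); each interval contributes the
    survival of both processes. ``lambda_div = 0`` is permitted when the
    table contains no diversification events (the process then contributes
    nothing); a zero rate with events depending on it yields ``-inf``.
    """
    if lambda_div < 0 or lambda_coal < 0:
        raise ValueError("rates must be non-negative")
    n_ev = table.ev_k.size
    rates = lambda_div * table.ev_k**p_div
    if table.coal_v.size:
        vp = table.coal_v**p_coal
        rates = rates + lambda_coal * np.bincount(
            table.ev_coal_idx, weights=vp, minlength=n_ev
        )
        coal_surv = lambda_coal * float(np.dot(vp, table.coal_x))
    else:
        coal_surv = 0.0
    if np.any(rates <= 0):
        return -np.inf
    div_surv = lambda_div * float(np.dot(table.div_surv_k**p_div, table.div_surv_x))
    return float(np.sum(np.log(rates)) - div_surv - coal_surv)


def _fit_null_like(table: GmycIntervalTable):
    """Pure-coalescent fit (lambda_div = 0); only valid when the table has
    no diversification events. The rate has a closed-form profile."""
    n_ev = table.ev_k.size

    def prof(pc: float):
        vp = table.coal_v**pc
        B = float(np.dot(vp, table.coal_x))
        lam = min(n_ev / B, RATE_MAX)
        sums = np.bincount(table.ev_coal_idx, weights=vp, minlength=n_ev)
        return float(n_ev * np.log(lam) + np.sum(np.log(sums)) - lam * B), lam

    grid = np.linspace(_P_LO, _P_HI, 41)
    vals = [prof(pc)[0] for pc in grid]
    pc0 = float(grid[int(np.argmax(vals))])
    res = minimize(lambda p: -prof(float(np.clip(p[0], _P_LO, _P_HI)))[0], [pc0],
                   method="Nelder-Mead", options={"xatol": 1e-7, "fatol": 1e-11})
    pc_ = float(np.clip(res.x[0], _P_LO, _P_HI))
    logL, lam = prof(pc_)
    return logL, 0.0, 0.0, lam, pc_


def _maximize_candidate(table: GmycIntervalTable, rng: np.random.Generator,
                        n_starts: int = 3, thorough: bool = True):
    """Maximize the likelihood over all four parameters for one threshold.

    Rates are searched in log-space; initial rates come from the
    event-count / opportunity ratios of each process class. With
    ``thorough=False`` a cheaper single-start search is run (used for the
    first pass over all thresholds; the leading candidates are then
    re-optimized thoroughly).
    """
    if table.n_div_events == 0:
        return _fit_null_like(table)

    lo, hi = np.log(1e-10), np.log(RATE_MAX)

    def neg(theta):
        u, pd_, w, pc_ = theta
        if not (_P_LO <= pd_ <= _P_HI and _P_LO <= pc_ <= _P_HI and
                lo <= u <= hi and lo <= w <= hi):
            return 1e18
        ll = gmyc_loglik(table, np.exp(u), pd_, np.exp(w), pc_)
        return -ll if np.isfinite(ll) else 1e18

    def lam0(pd_, pc_):
        Sd = float(np.dot(table.div_surv_k**pd_, table.div_surv_x))
        ud = np.log(max(table.n_div_events / Sd, 1e-10))
        if table.coal_v.size:
            Sc = float(np.dot(table.coal_v**pc_, table.coal_x))
            uc = np.log(max(table.n_coal_events / Sc, 1e-10))
        else:
            uc = 0.0
        return ud, uc

    cands = []
    for pd0 in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
        for pc0 in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0):
            ud, uc = lam0(pd0, pc0)
            theta = (ud, pd0, uc, pc0)
            cands.append((neg(theta), theta))
    cands.sort(key=lambda t: t[0])
    if thorough:
        starts = [np.asarray(c[1]) for c in cands[:max(3, n_starts)]]
        for _ in range(max(0, n_starts - 2)):
            starts.append(np.asarray(cands[0][1]) + rng.normal(0.0, 0.3, size=4))
        options = {"xatol": 1e-7, "fatol": 1e-12, "maxiter": 1500}
    else:
        starts = [np.asarray(cands[0][1])]
        options = {"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300}

    best = None
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
    if thorough:
        # polish from the optimum found
        res = minimize(neg, best.x, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 800})
        if res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e18:
        return None
    u, pd_, w, pc_ = best.x
    pd_, pc_ = float(np.clip(pd_, _P_LO, _P_HI)), float(np.clip(pc_, _P_LO, _P_HI))
    lam_d, lam_c = float(np.exp(u)), float(np.exp(w))
    return -float(best.fun), lam_d, pd_, lam_c, pc_


# ---------------------------------------------------------------------------
# Model / results


@dataclass
class GMYCResults:
    """Fitted single-threshold GMYC model."""

    threshold_age: float
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    loglik: float
    null_loglik: float
    lrt_df: int
    lrt_pvalue: float
    partition: ClusterPartition
    cluster_tip_sets: list[frozenset]
    threshold_scan: pd.DataFrame = None

    @property
    def n_entities(self) -> int:
        return len(self.cluster_tip_sets)

    def summary(self) -> str:
        lines = [
            "Single-threshold GMYC fit",
            "=" * 41,
            f"delimited entities        {self.n_entities:>12d}",
            f"threshold age             {self.threshold_age:>12.6g}",
            f"lambda_div / p_div        {self.lambda_div:>12.6g} / {self.p_div:.4g}",
            f"lambda_coal / p_coal      {self.lambda_coal:>12.6g} / {self.p_coal:.4g}",
            f"logL (mixed model)        {self.loglik:>12.4f}",
            f"logL (coalescent null)    {self.null_loglik:>12.4f}",
            f"LRT (df={self.lrt_df}) p-value        {self.lrt_pvalue:>12.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_entities": self.n_entities,
            "threshold_age": self.threshold_age,
            "lambda_div": self.lambda_div,
            "p_div": self.p_div,
            "lambda_coal": self.lambda_coal,
            "p_coal": self.p_coal,
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "lrt_df": self.lrt_df,
            "lrt_pvalue": self.lrt_pvalue,
        }


class GMYC:
    """Single-threshold GMYC model for an ultrametric gene tree.

    Parameters
    ----------
    tree
        Ultrametric :class:`~stagematch.core.GeneTree` (a chronogram). The
        method is designed for haplotype trees: if the tree has one tip per
        specimen and no collapsed haplotypes, a warning is issued (identical
        sequences inflate the apparent coalescent rate).
    """

    def __init__(self, tree: GeneTree, ultrametric_tol: float = 1e-6):
        self.tree = tree
        self._index = _TreeIndex(tree, ultrametric_tol=ultrametric_tol)
        if not tree.tip_map_explicit:
            warnings.warn(
                "no haplotype membership supplied and tree tips map 1:1 to specimens; "
                "GMYC expects a haplotype tree (collapse identical sequences first)",
                GmycWarning,
                stacklevel=2,
            )

    def fit(self, df: int = 3, n_starts: int = 3, seed: int = 0) -> GMYCResults:
        """Scan all candidate thresholds, maximizing the likelihood at each.

        Ties between thresholds are broken toward the older one (fewer
        entities). ``df`` is the degrees of freedom of the chi-square LRT
        against the single-coalescent null (2 by default, 3 also in use in
        the literature).
        """
        rng = np.random.default_rng(seed)
        index = self._index

        # first pass: cheap optimization at every candidate threshold
        prelim = []
        for T in index.candidate_thresholds():
            table = _build_table(index, T)
            thorough = table.n_div_events == 0  # null candidate is cheap & exact
            out = _maximize_candidate(table, rng, n_starts=n_starts, thorough=thorough)
            if out is None:
                warnings.warn(f"optimization failed at threshold {T:.6g}; skipped",
                              GmycWarning, stacklevel=2)
                continue
            prelim.append((out[0], T, table, out))
        if not prelim:
            raise RuntimeError("GMYC optimization failed at every candidate threshold")
        null_entry = next((p for p in prelim if p[2].n_div_events == 0), None)
        null_loglik = null_entry[0] if null_entry else max(p[0] for p in prelim)

        # second pass: thorough re-optimization of the leading candidates
        top_k = len(prelim) if index.n_events <= 12 else 3
        refine = sorted(prelim, key=lambda p: -p[0])[:top_k]
        refined = {}
        for _, T, table, out in refine:
            if table.n_div_events == 0:
                refined[T] = (out[0], T, table, out)
                continue
            out2 = _maximize_candidate(table, rng, n_starts=n_starts, thorough=True)
            if out2 is not None and out2[0] >= out[0]:
                refined[T] = (out2[0], T, table, out2)
            else:
                refined[T] = (out[0], T, table, out)

        scan_rows = []
        best = None
        for logL0, T, table, out in prelim:
            logL0, T, table, out = refined.get(T, (logL0, T, table, out))
            scan_rows.append(
                {"threshold_age": T, "n_entities": table.n_div_events + 1, "loglik": out[0]}
            )
            # ties broken toward the older threshold (scanned oldest first)
            if best is None or out[0] > best[0] + 1e-9:
                best = (out[0], T, table, out)

        logL, T, table, out = best
        _, lam_d, pd_, lam_c, pc_ = out
        lrt = max(0.0, 2.0 * (logL - null_loglik))
        pvalue = float(chi2.sf(lrt, df)) if lrt > 0 else 1.0
        tip_sets = index.cluster_tip_sets(T)
        clusters = [
            frozenset(self.tree.specimens_of(ts)) for ts in tip_sets
        ]
        partition = ClusterPartition(gene=self.tree.gene, method="GMYC", clusters=clusters)
        return GMYCResults(
            threshold_age=T,
            lambda_div=lam_d,
            p_div=float(pd_),
            lambda_coal=lam_c,
            p_coal=float(pc_),
            loglik=logL,
            null_loglik=null_loglik,
            lrt_df=df,
            lrt_pvalue=pvalue,
            partition=partition,
            cluster_tip_sets=tip_sets,
            threshold_scan=pd.DataFrame(scan_rows),
        )


def fit_gmyc(tree: GeneTree, df: int = 3, n_starts: int = 3, seed: int = 0) -> GMYCResults:
    """Convenience wrapper: ``GMYC(tree).fit(...)``."""
    return GMYC(tree).fit(df=df, n_starts=n_starts, seed=seed)
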