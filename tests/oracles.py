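"""Independent reference implementations used as test oracles.

Everything here is written directly against the tree structure, without
reusing the package's interval tables, cluster bookkeeping or search code,
so that agreement between the two routes is informative.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# Kingman coalescent closed form


def kingman_loglik(node_ages: list[float], pair_rate: float) -> float:
    """Standard Kingman log-density of a single-population genealogy.

    ``node_ages``: coalescence times (any order); ``pair_rate``: rate at
    which any one pair of lineages coalesces. With k lineages the total rate
    is ``pair_rate * k * (k-1) / 2``... expressed here via k*(k-1) times
    pair_rate/2 to match the power-law parameterization with p = 1.
    """
    ages = sorted(node_ages, reverse=True)
    bounds = ages + [0.0]
    logp = 0.0
    for m in range(1, len(ages) + 1):
        k = m + 1
        rate = pair_rate * k * (k - 1) / 2.0
        logp += math.log(rate) - rate * (bounds[m - 1] - bounds[m])
    return logp


# ---------------------------------------------------------------------------
# GMYC: independent likelihood + grid/optimizer maximizer


def _ages(gt):
    ages = gt.node_ages()
    return ages


def gmyc_loglik_independent(gt, T, lam_d, p_d, lam_c, p_c) -> float:
    """Mixed Yule-coalescent superposition log-likelihood, recomputed from
    raw edges (no interval-table reuse)."""
    ages = _ages(gt)
    tree = gt.tree
    edges = [(ages[n.parent_node], ages[n], n)
             for n in tree.preorder_node_iter() if n.parent_node is not None]
    internal = sorted((ages[n] for n in tree.preorder_node_iter() if not n.is_leaf()),
                      reverse=True)

    # cluster assignment: ancestor edge crossing the threshold
    crossing = [n for (pa, ca, n) in edges if pa > T >= ca]
    if T > internal[0]:
        crossing = [tree.seed_node]
    cluster_of = {}
    for j, top in enumerate(crossing):
        stack = [top]
        while stack:
            m = stack.pop()
            cluster_of[id(m)] = j
            stack.extend(m.child_nodes())
    K = len(crossing)

    bounds = internal + [0.0]
    logL = 0.0
    for i in range(len(internal)):
        hi, lo = bounds[i], bounds[i + 1]
        for (phi, plo) in ((hi, max(lo, T)), (min(hi, T), lo)):
            if phi <= plo:
                continue
            mid = 0.5 * (phi + plo)
            spanning = [(pa, ca, n) for (pa, ca, n) in edges
                        if pa > mid > ca - 1e-9 and ca <= plo + 1e-7]
            if mid > T:
                ndiv = len(spanning)
                coal = 0.0
            else:
                ndiv = K
                counts: dict = {}
                for (_pa, _ca, n) in spanning:
                    j = cluster_of.get(id(n))
                    counts[j] = counts.get(j, 0) + 1
                coal = sum((c * (c - 1)) ** p_c for c in counts.values() if c >= 2)
            r = lam_d * ndiv**p_d + lam_c * coal
            logL -= r * (phi - plo)
            if abs(phi - hi) < 1e-15:  # event at the rootward end of the interval
                if r <= 0:
                    return -np.inf
                logL += math.log(r)
    return float(logL)


def gmyc_candidates_independent(gt) -> list[float]:
    ages = sorted((a for n, a in _ages(gt).items() if not n.is_leaf()), reverse=True)
    distinct = [ages[0]]
    for a in ages[1:]:
        if distinct[-1] - a > 1e-9:
            distinct.append(a)
    cands = [ages[0] * 1.05 + 1e-9]
    cands += [0.5 * (hi + lo) for hi, lo in zip(distinct[:-1], distinct[1:])]
    return cands


def _gmyc_arrays_independent(gt, T):
    """Independent interval decomposition (edge-walking, no reuse of the
    package's event-sorted table construction). Returns flat arrays from
    which the superposition log-likelihood is a few dot products."""
    ages = _ages(gt)
    tree = gt.tree
    edges = [(ages[n.parent_node], ages[n], n)
             for n in tree.preorder_node_iter() if n.parent_node is not None]
    internal = sorted((ages[n] for n in tree.preorder_node_iter() if not n.is_leaf()),
                      reverse=True)

    crossing = [n for (pa, ca, n) in edges if pa > T >= ca]
    if T > internal[0]:
        crossing = [tree.seed_node]
    cluster_of = {}
    for j, top in enumerate(crossing):
        stack = [top]
        while stack:
            m = stack.pop()
            cluster_of[id(m)] = j
            stack.extend(m.child_nodes())
    K = len(crossing)

    ev_k, ev_vals = [], []          # per event-interval: k and coal v-list
    surv_k, surv_kx = [], []        # diversification survival (k, x)
    surv_v, surv_vx = [], []        # coalescent survival (v, x)
    bounds = internal + [0.0]
    for i in range(len(internal)):
        hi, lo = bounds[i], bounds[i + 1]
        for (phi, plo) in ((hi, max(lo, T)), (min(hi, T), lo)):
            if phi <= plo:
                continue
            mid = 0.5 * (phi + plo)
            x = phi - plo
            spanning = [(pa, ca, n) for (pa, ca, n) in edges
                        if pa > mid > ca - 1e-9 and ca <= plo + 1e-7]
            if mid > T:
                k, vals = len(spanning), []
            else:
                k = K
                counts: dict = {}
                for (_pa, _ca, n) in spanning:
                    j = cluster_of.get(id(n))
                    counts[j] = counts.get(j, 0) + 1
                vals = [c * (c - 1) for c in counts.values() if c >= 2]
            surv_k.append(k)
            surv_kx.append(x)
            for v in vals:
                surv_v.append(v)
                surv_vx.append(x)
            if abs(phi - hi) < 1e-15:
                ev_k.append(k)
                ev_vals.append(vals)
    d = sum(1 for a in internal if a > T)
    return {
        "d": d,
        "ev_k": np.asarray(ev_k, dtype=float),
        "ev_vals": [np.asarray(v, dtype=float) for v in ev_vals],
        "surv_k": np.asarray(surv_k, dtype=float),
        "surv_kx": np.asarray(surv_kx, dtype=float),
        "surv_v": np.asarray(surv_v, dtype=float),
        "surv_vx": np.asarray(surv_vx, dtype=float),
    }


def _gmyc_arrays_loglik(arr, lam_d, p_d, lam_c, p_c) -> float:
    logL = 0.0
    for k, vals in zip(arr["ev_k"], arr["ev_vals"]):
        r = lam_d * k**p_d + lam_c * float(np.sum(vals**p_c))
        if r <= 0:
            return -np.inf
        logL += math.log(r)
    logL -= lam_d * float(np.dot(arr["surv_k"]**p_d, arr["surv_kx"]))
    if arr["surv_v"].size:
        logL -= lam_c * float(np.dot(arr["surv_v"]**p_c, arr["surv_vx"]))
    return logL


def gmyc_max_loglik_oracle(gt) -> float:
    """Grid search + heavy local refinement over every candidate threshold,
    on an independently computed interval decomposition."""
    p_grid = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
    best = -np.inf
    for T in gmyc_candidates_independent(gt):
        arr = _gmyc_arrays_independent(gt, T)
        d = arr["d"]
        nc = len(arr["ev_k"]) - d

        def lam_init(p_d, p_c):
            sd = float(np.dot(arr["surv_k"]**p_d, arr["surv_kx"]))
            ud = math.log(max(d, 1e-300) / sd) if d else 0.0
            if arr["surv_v"].size:
                sc = float(np.dot(arr["surv_v"]**p_c, arr["surv_vx"]))
                uc = math.log(max(nc / sc, 1e-12))
            else:
                uc = 0.0
            return ud, uc

        if d == 0:
            def neg(theta):
                w, pc = theta
                if not (0 <= pc <= 10 and -28 <= w <= 19):
                    return 1e18
                ll = _gmyc_arrays_loglik(arr, 0.0, 1.0, math.exp(w), pc)
                return -ll if np.isfinite(ll) else 1e18

            starts = []
            for pc in p_grid:
                _, uc = lam_init(1.0, pc)
                for s in (0.25, 1.0, 4.0):
                    starts.append((uc + math.log(s), pc))
        else:
            def neg(theta):
                u, pd, w, pc = theta
                if not (0 <= pd <= 10 and 0 <= pc <= 10
                        and -28 <= u <= 19 and -28 <= w <= 19):
                    return 1e18
                ll = _gmyc_arrays_loglik(arr, math.exp(u), pd, math.exp(w), pc)
                return -ll if np.isfinite(ll) else 1e18

            starts = []
            for pd in p_grid:
                for pc in p_grid:
                    ud, uc = lam_init(pd, pc)
                    for sd, sc in ((1.0, 1.0), (0.25, 4.0), (4.0, 0.25)):
                        starts.append((ud + math.log(sd), pd,
                                       uc + math.log(sc), pc))
        scored = sorted(((neg(s), s) for s in starts), key=lambda t: t[0])
        cand_best = scored[0][0]
        for _, s in scored[:8]:
            res = minimize(neg, s, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 4000})
            cand_best = min(cand_best, res.fun)
        best = max(best, -cand_best)
    return float(best)


# ---------------------------------------------------------------------------
# Monophyly brute force


def monophyly_oracle(gt, target: set[str], support_threshold: float) -> str:
    """Exhaustive-clade monophyly verdict (yes/no/not_evaluable)."""
    target = set(target)
    tip_labels = {lab for lab, ids in gt.tip_map.items() if ids & target}
    if len(tip_labels) < 2:
        return "not_evaluable"
    clades = []
    for node in gt.tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        sup = 1.0 if node.parent_node is None else getattr(node, "support", None)
        clades.append((leaves, sup))
    containing = [c for c in clades if tip_labels <= c[0]]
    leaves, sup = min(containing, key=lambda c: len(c[0]))
    members = {sid for lab in leaves for sid in gt.tip_map[lab]}
    if not members <= target:
        return "no"
    if support_threshold > 0 and (sup is None or sup < support_threshold):
        return "no"
    return "yes"


# ---------------------------------------------------------------------------
# PTP: independent antichain enumeration


def enumerate_tip_partitions(gt) -> list[frozenset[frozenset[str]]]:
    """Every partition of the tips into clades, enumerated by choosing, per
    internal node, whether to cut below it — independently of the package's
    antichain recursion."""

    def rec(node):
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if node.is_leaf():
            return [frozenset([leaves])]
        child_parts = [rec(c) for c in node.child_nodes()]
        combos = [frozenset([leaves])]
        acc = [frozenset()]
        for parts in child_parts:
            acc = [a | p for a in acc for p in parts]
        combos.extend(acc)
        return combos

    return rec(gt.tree.seed_node)
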