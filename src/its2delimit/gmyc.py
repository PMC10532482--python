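"""Generalized mixed Yule-coalescent (GMYC) species delimitation.

Given an ultrametric tree, the model separates between-species
diversification from within-species coalescence. A delimitation assigns
every tip to a cluster (a putative species); internal nodes inside
clusters are coalescent events, nodes above them diversification
events. During the interval ending (rootward) at the k-th node age the
mixture intensity is

    b_k = lambda_div * s_k**p_div
        + lambda_coal * sum_j [n_jk * (n_jk - 1)]**p_coal

with s_k the number of species lineages and n_jk the number of lineages
of cluster j in that interval. The likelihood is the classical
waiting-time product over inter-node intervals: each interval
contributes ``ln(b_k) - b_k * x_k`` where b_k is the total mixture rate
prevailing when the interval's event is realized (the marginal
likelihood of the event times; the tree enters through the candidate
lineage-count trajectories only, which keeps candidate delimitations
comparable). Counts follow the backward (Kingman) convention: an event
is rated with the interval on its tipward side. The root event is
exposure-only in every candidate, so all candidates realize n - 2
events and the likelihood ratio is invariant to rescaling node heights.

The two rates and two scaling exponents are optimised jointly
(L-BFGS-B with analytic gradients, exponents bounded to [0.1, 5]),
started from the closed-form separable fit. The null model is the
better of the two single-process candidates (all-diversification /
all-coalescence); both belong to the candidate set, so
``best_loglik >= null_loglik`` holds structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .trees import node_heights

P_BOUNDS = (0.1, 5.0)


def branching_times(tree: dendropy.Tree, tol: float = 1e-6) -> np.ndarray:
    """Internal-node ages of an ultrametric tree, sorted descending."""
    heights = node_heights(tree, tol=tol)
    ages = [h for node, h in heights.items() if not node.is_leaf()]
    if len(ages) < 1:
        raise ValueError("tree has no internal nodes")
    return np.array(sorted(ages, reverse=True))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


class _GmycTree:
    """Flat arrays for fast likelihood evaluation of delimitations."""

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-6):
        heights = node_heights(tree, tol=tol)
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips < 3:
            raise ValueError("GMYC requires at least 3 tips")
        for n in internals:
            if len(n.child_nodes()) != 2:
                raise ValueError("GMYC requires a strictly binary tree")
        depth = {tree.seed_node: 0}
        for n in tree.preorder_node_iter():
            for c in n.child_nodes():
                depth[c] = depth[n] + 1
        # ascending age; ties broken deepest-first so every age-order
        # prefix from the top is ancestor-closed and the root is last
        internals.sort(key=lambda n: (heights[n], -depth[n]))
        self.nodes = internals
        self.n_events = len(internals)
        self.root_idx = self.n_events - 1
        idx = {n: k for k, n in enumerate(internals)}
        self.ages = np.array([heights[n] for n in internals])
        x = np.diff(np.concatenate([[0.0], self.ages]))
        self.x = x
        self.xcum = np.concatenate([[0.0], np.cumsum(x)])
        self.leaf_labels: list[list[str]] = []
        self.internal_desc: list[np.ndarray] = []
        self.tip_count = np.zeros(self.n_events, dtype=int)
        tmp_leaves: dict = {}
        tmp_desc: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                tmp_leaves[node] = [node.taxon.label]
                tmp_desc[node] = []
            else:
                kids = node.child_nodes()
                tmp_leaves[node] = tmp_leaves[kids[0]] + tmp_leaves[kids[1]]
                tmp_desc[node] = (
                    tmp_desc[kids[0]] + tmp_desc[kids[1]] + [idx[node]]
                )
        for k, node in enumerate(internals):
            self.leaf_labels.append(tmp_leaves[node])
            self.internal_desc.append(np.array(sorted(tmp_desc[node]), dtype=int))
            self.tip_count[k] = len(tmp_leaves[node])
        self.all_tips = list(tmp_leaves[tree.seed_node])
        self.n_tips = n_tips
        # children of each internal node: (kind, ref) with kind 'leaf'/'int'
        self.children: list[list] = []
        for node in internals:
            entry = []
            for c in node.child_nodes():
                if c.is_leaf():
                    entry.append(("leaf", c.taxon.label))
                else:
                    entry.append(("int", idx[c]))
            self.children.append(entry)
        self.parent = np.full(self.n_events, -1, dtype=int)
        for k, node in enumerate(internals):
            p = node.parent_node
            if p is not None and p in idx:
                self.parent[k] = idx[p]


def _profile_part(n_real: int, sum_ln_real: float, basis: np.ndarray,
                  exposure: np.ndarray):
    """Maximise N ln(N/A(p)) - N + p * sum_ln_real over p in bounds.

    ``basis`` and ``exposure`` define the integrated intensity
    A(p) = sum basis**p * exposure; the rate MLE is N / A(p).
    Returns (loglik, rate, p)."""
    if n_real == 0:
        return 0.0, 0.0, float(P_BOUNDS[0])
    if float(exposure.sum()) <= 0.0:
        # all events in zero-length intervals (tied node heights)
        return 0.0, 1e6, 1.0

    logb = np.log(basis)

    def loglik(p: float) -> float:
        A = float(np.exp(p * logb) @ exposure)
        if A <= 0.0:
            return -1e12
        return n_real * (np.log(n_real / A) - 1.0) + p * sum_ln_real

    res = minimize_scalar(
        lambda p: -loglik(p), bounds=P_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    p_hat = float(res.x)
    A = float(np.exp(p_hat * logb) @ exposure)
    if A <= 0.0:
        return 0.0, 1e6, 1.0
    return loglik(p_hat), n_real / A, p_hat


@dataclass
class _Candidate:
    roots: frozenset  # internal cluster-root indices
    loglik: float
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    n_params: int
    inside: np.ndarray  # bool per internal event: lies within a cluster

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


_LOG_RATE_BOUNDS = (-30.0, 15.0)


def _evaluate(gt: _GmycTree, roots: frozenset, n_params: int = 5) -> _Candidate:
    """Maximised waiting-time log-likelihood of one delimitation."""
    K = gt.n_events
    is_div = np.ones(K, dtype=bool)
    runs_nn: list[float] = []
    runs_lo: list[int] = []
    runs_hi: list[int] = []
    real_nn: list[float] = []
    for c in sorted(roots):
        desc = gt.internal_desc[c]
        is_div[desc] = False
        cnt = gt.tip_count[c]
        prev = -1
        for e in desc:
            nn = float(cnt * (cnt - 1))
            runs_nn.append(nn)
            runs_lo.append(prev + 1)
            runs_hi.append(int(e))
            if e != gt.root_idx:
                real_nn.append(nn)
            prev = int(e)
            cnt -= 1

    # species lineage counts per interval (backward convention)
    suffix = np.cumsum(is_div[::-1])[::-1]  # div events with index >= k
    s = 1.0 + suffix
    x = gt.x
    ln_s = np.log(s)
    nn_arr = np.array(runs_nn)
    lo = np.array(runs_lo, dtype=int)
    hi = np.array(runs_hi, dtype=int)
    have_coal = len(nn_arr) > 0
    ln_nn = np.log(nn_arr) if have_coal else None

    def interval_sums(values: np.ndarray) -> np.ndarray:
        # runs are constant over contiguous interval ranges
        dw = np.zeros(K + 1)
        np.add.at(dw, lo, values)
        np.add.at(dw, hi + 1, -values)
        out = np.cumsum(dw)[:K]
        # cancellation in the cumulative sum can leave tiny negatives
        return np.clip(out, 0.0, None)

    def neg_loglik_grad(theta):
        ud, pd, uc, pc = theta
        lam_d, lam_c = np.exp(ud), np.exp(uc)
        spd = np.exp(pd * ln_s)
        B = spd @ x
        B_dp = (spd * ln_s) @ x
        if have_coal:
            v = np.exp(pc * ln_nn)
            w = interval_sums(v)
            w2 = interval_sums(v * ln_nn)
            A = w @ x
            A_dp = w2 @ x
        else:
            w = np.zeros(K)
            w2 = np.zeros(K)
            A = A_dp = 0.0
        R = lam_d * spd + lam_c * w
        Rr = R[:-1]  # realized intervals: every event except the root
        ll = float(np.log(Rr).sum() - lam_d * B - lam_c * A)
        inv = 1.0 / Rr
        g = np.array([
            lam_d * (float(spd[:-1] @ inv) - B),
            lam_d * (float((spd[:-1] * ln_s[:-1]) @ inv) - B_dp),
            lam_c * (float(w[:-1] @ inv) - A),
            lam_c * (float(w2[:-1] @ inv) - A_dp),
        ])
        return -ll, -g

    # closed-form separable initialisation (events attributed to their
    # own component, rates profiled, exponents by bounded search)
    div_idx = np.nonzero(is_div)[0]
    real_div = div_idx[div_idx != gt.root_idx]
    n_div = len(real_div)
    sum_ln_div = float(ln_s[real_div].sum()) if n_div else 0.0
    _, lam_d0, p_d0 = _profile_part(n_div, sum_ln_div, s, x)
    n_coal = len(real_nn)
    if have_coal and n_coal:
        run_x = gt.xcum[hi + 1] - gt.xcum[lo]
        _, lam_c0, p_c0 = _profile_part(
            n_coal, float(np.log(real_nn).sum()), nn_arr, run_x
        )
    else:
        lam_c0, p_c0 = 0.0, 1.0

    bounds = [_LOG_RATE_BOUNDS, P_BOUNDS, _LOG_RATE_BOUNDS, P_BOUNDS]
    lob = np.array([b[0] for b in bounds])
    upb = np.array([b[1] for b in bounds])

    def start(vals):
        return np.clip(np.array(vals, dtype=float), lob, upb)

    total_events = K - 1
    mom_d = np.log(max(total_events / max(float(s @ x), 1e-12), 1e-12))
    starts = [
        start([np.log(max(lam_d0, 1e-12)), p_d0,
               np.log(max(lam_c0, 1e-12)), p_c0]),
        start([mom_d, 1.0, np.log(max(lam_c0, 1e-12)), 1.0]),
    ]
    best_val, best_theta = np.inf, starts[0]
    for th0 in starts:
        res = minimize(
            neg_loglik_grad, th0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun < best_val:
            best_val, best_theta = float(res.fun), res.x

    ud, pd, uc, pc = best_theta
    return _Candidate(
        roots=roots,
        loglik=-best_val,
        lambda_div=float(np.exp(ud)),
        p_div=float(pd),
        lambda_coal=float(np.exp(uc)),
        p_coal=float(pc),
        n_params=n_params,
        inside=~is_div,
    )


def _collapse_identical_tips(tree: dendropy.Tree, tol: float):
    """Keep one representative per set of tips joined at (near-)zero age.

    Zero-length waiting times are a point mass that the continuous
    waiting-time likelihood would exploit without bound (the coalescent
    rate diverges on zero exposure), which is why GMYC conventionally
    runs on unique haplotypes. Returns (pruned tree, representative ->
    collapsed labels map); the pruned tips are re-attached to their
    representative's cluster afterwards."""
    from .trees import node_heights, prune_taxa

    heights = node_heights(tree, tol=tol)
    H = max(heights.values())
    eps = max(tol * max(H, 1.0), 1e-12)
    groups: list[list[str]] = []
    visited: set = set()
    for node in tree.preorder_node_iter():
        if node in visited or node.is_leaf() or heights[node] > eps:
            continue
        # maximal zero-height subtree: all its tips are duplicates
        tips = [l.taxon.label for l in node.leaf_iter()]
        groups.append(tips)
        for sub in node.preorder_iter():
            visited.add(sub)
    duplicates = {tips[0]: tips[1:] for tips in groups if len(tips) > 1}
    drop = [l for reps in duplicates.values() for l in reps]
    if not drop:
        return tree, {}
    return prune_taxa(tree, drop), duplicates


def _expand_result(res: "GmycResult", duplicates: dict) -> "GmycResult":
    if not duplicates:
        return res

    def expand(labels):
        out = list(labels)
        for l in labels:
            out.extend(duplicates.get(l, []))
        return out

    res.clusters = [expand(c) for c in res.clusters]
    res.n_ml_clusters = sum(
        1 for c in res.clusters if len(c) >= res._min_cluster_size
    )
    res.node_support = {
        frozenset(expand(k)): v for k, v in res.node_support.items()
    }
    return res


def _threshold_roots(gt: _GmycTree, k_div: int) -> frozenset:
    """Cluster roots when the k_div oldest events are diversification."""
    if k_div == 0:
        return frozenset({gt.root_idx})
    div = set(range(gt.n_events - k_div, gt.n_events))
    roots = set()
    for d in div:
        for kind, ref in gt.children[d]:
            if kind == "int" and ref not in div:
                roots.add(ref)
    return frozenset(roots)


def _partition(gt: _GmycTree, roots: frozenset) -> list[list[str]]:
    clusters = [list(gt.leaf_labels[c]) for c in sorted(roots)]
    covered = {t for cl in clusters for t in cl}
    clusters.extend([[t] for t in gt.all_tips if t not in covered])
    return clusters


# ---------------------------------------------------------------------------
# public results
# ---------------------------------------------------------------------------


@dataclass
class GmycResult:
    """Outcome of a GMYC fit on one ultrametric tree."""

    null_loglik: float
    best_loglik: float
    thresholds: list[float]
    lambda_div: float
    p_div: float
    lambda_coal: float
    p_coal: float
    lr_stat: float
    p_value: float
    clusters: list[list[str]]
    n_ml_clusters: int
    node_support: dict[frozenset, float]
    mode: str = "single"
    n_candidates: int = 0
    aic_best: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "null_loglik": self.null_loglik,
            "best_loglik": self.best_loglik,
            "thresholds": list(self.thresholds),
            "rates": {
                "lambda_div": self.lambda_div,
                "p_div": self.p_div,
                "lambda_coal": self.lambda_coal,
                "p_coal": self.p_coal,
            },
            "lr_stat": self.lr_stat,
            "p_value": self.p_value,
            "n_ml_clusters": self.n_ml_clusters,
            "clusters": [sorted(c) for c in self.clusters],
            "node_support": {
                "|".join(sorted(k)): v for k, v in self.node_support.items()
            },
            "n_candidates": self.n_candidates,
            "aic_best": self.aic_best,
        }


def lr_test(null_loglik: float, best_loglik: float, df: int = 3) -> float:
    """Upper-tail chi-square p-value of 2 * (best - null)."""
    if best_loglik < null_loglik - 1e-9:
        raise ValueError("best_loglik is below null_loglik")
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(2.0 * (best_loglik - null_loglik), 0.0)
    return float(chi2.sf(stat, df))


def node_support_akaike(
    candidates: list[_Candidate], gt: _GmycTree
) -> dict[frozenset, float]:
    """Summed Akaike weights of the models in which each node lies inside
    a delimited entity. Keys are clade tip-label frozensets."""
    if not candidates:
        raise ValueError("empty candidate set")
    aics = np.array([c.aic for c in candidates])
    w = np.exp(-(aics - aics.min()) / 2.0)
    w = w / w.sum()
    inside = np.stack([c.inside for c in candidates])  # models x events
    support = w @ inside
    return {
        frozenset(gt.leaf_labels[k]): float(support[k])
        for k in range(gt.n_events)
    }


def _finalize(
    gt: _GmycTree,
    best: _Candidate,
    null_ll: float,
    candidates: list[_Candidate],
    thresholds: list[float],
    df: int,
    min_cluster_size: int,
    mode: str,
) -> GmycResult:
    clusters = _partition(gt, best.roots)
    n_ml = sum(1 for c in clusters if len(c) >= min_cluster_size)
    p = lr_test(null_ll, best.loglik, df=df)
    res = GmycResult(
        null_loglik=null_ll,
        best_loglik=best.loglik,
        thresholds=thresholds,
        lambda_div=best.lambda_div,
        p_div=best.p_div,
        lambda_coal=best.lambda_coal,
        p_coal=best.p_coal,
        lr_stat=max(2.0 * (best.loglik - null_ll), 0.0),
        p_value=p,
        clusters=clusters,
        n_ml_clusters=n_ml,
        node_support=node_support_akaike(candidates, gt),
        mode=mode,
        n_candidates=len(candidates),
        aic_best=best.aic,
    )
    res._min_cluster_size = min_cluster_size
    return res


def gmyc_single(
    tree: dendropy.Tree,
    *,
    df: int = 3,
    min_cluster_size: int = 2,
    tol: float = 1e-6,
) -> GmycResult:
    """Single-threshold GMYC: the threshold is taken at each observed
    branching time and the maximum-likelihood candidate is returned.

    Tips joined at zero age (identical profiles) are collapsed to one
    representative haplotype before fitting and restored to their
    representative's cluster afterwards."""
    tree, duplicates = _collapse_identical_tips(tree, tol)
    gt = _GmycTree(tree, tol=tol)
    candidates = []
    for k_div in range(gt.n_events + 1):
        roots = _threshold_roots(gt, k_div)
        candidates.append((k_div, _evaluate(gt, roots)))
    # null: better of the two single-process models
    all_coal = candidates[0][1]
    all_div = candidates[-1][1]
    null_ll = max(all_coal.loglik, all_div.loglik)
    best_k, best = max(candidates, key=lambda kc: kc[1].loglik)
    thresholds = (
        [float(gt.ages[gt.n_events - best_k])] if best_k >= 1 else []
    )
    res = _finalize(
        gt, best, null_ll, [c for _, c in candidates], thresholds,
        df, min_cluster_size, "single",
    )
    return _expand_result(res, duplicates)


def _neighbors(gt: _GmycTree, roots: frozenset):
    """Split/merge moves on the cluster-root antichain."""
    out = []
    for c in sorted(roots):
        kids = [ref for kind, ref in gt.children[c] if kind == "int"]
        # split c into its children (leaves become singletons implicitly)
        out.append(frozenset((set(roots) - {c}) | set(kids)))
    by_parent: dict[int, list[int]] = {}
    for c in roots:
        p = gt.parent[c]
        if p >= 0:
            by_parent.setdefault(p, []).append(c)
    for p, kids in by_parent.items():
        internal_kids = [ref for kind, ref in gt.children[p] if kind == "int"]
        # merge allowed when every internal child of p is a cluster root
        if set(internal_kids) <= set(roots):
            out.append(frozenset((set(roots) - set(internal_kids)) | {p}))
    return out


def gmyc_multiple(
    tree: dendropy.Tree,
    *,
    df: int = 3,
    min_cluster_size: int = 2,
    tol: float = 1e-6,
    max_steps: int = 200,
) -> GmycResult:
    """Multiple-threshold GMYC by AIC hill climbing.

    Starts from the single-threshold optimum; split/merge moves on the
    delimitation are accepted when they improve AIC, each accepted
    deviation adding one lineage-specific threshold parameter
    (k = 5 + deviations). Deterministic; the visited candidate set always
    contains the single-threshold optimum and feeds the Akaike-weight
    node supports. Identical tips are collapsed as in gmyc_single."""
    tree, duplicates = _collapse_identical_tips(tree, tol)
    gt = _GmycTree(tree, tol=tol)
    single_candidates = []
    for k_div in range(gt.n_events + 1):
        roots = _threshold_roots(gt, k_div)
        single_candidates.append(_evaluate(gt, roots))
    all_coal, all_div = single_candidates[0], single_candidates[-1]
    null_ll = max(all_coal.loglik, all_div.loglik)
    current = max(single_candidates, key=lambda c: c.loglik)

    visited: dict[frozenset, _Candidate] = {c.roots: c for c in single_candidates}
    m = 0
    for _ in range(max_steps):
        m_next = m + 1
        best_move = None
        for nb in _neighbors(gt, current.roots):
            if nb in visited and visited[nb].n_params <= 5 + m_next:
                cand = visited[nb]
            else:
                cand = _evaluate(gt, nb, n_params=5 + m_next)
                if nb not in visited:
                    visited[nb] = cand
            if cand.aic < current.aic - 1e-9:
                if best_move is None or cand.aic < best_move.aic - 1e-12:
                    best_move = cand
        if best_move is None:
            break
        current = best_move
        m = max(current.n_params - 5, 0)

    cut_ages = sorted(
        {
            float(gt.ages[gt.parent[c]])
            for c in current.roots
            if gt.parent[c] >= 0
        }
    )
    res = _finalize(
        gt, current, null_ll, list(visited.values()), cut_ages,
        df, min_cluster_size, "multiple",
    )
    return _expand_result(res, duplicates)
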