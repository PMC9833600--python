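"""Working-set and active-set computation with interaction pruning.

The solver never materializes all O(p^2) / O(p^3) candidate interaction
columns.  Instead, for each branch feature i (or realized pair (i, j)) it
keeps a residual snapshot rho_x from the last time the branch was fully
enumerated, together with pi_x, the largest absolute inner product any
supra-indexed partner column had with that snapshot.  These give a cheap
upper bound eta(x) on |X*_{x o j} . r| over every partner j > max(x): if
eta(x) <= lambda * ||r||_2 no interaction containing x as its leading
members can violate the square-root-lasso KKT condition, and the whole
branch is skipped.  Surviving branches are enumerated by walking the
row-major index of X, so only interactions that actually co-occur in some
sample are ever touched.

Three-way search applies the same bound a second time at the pair level:
triples (i, j, k) are enumerated only when eta({i, j}) exceeds the
admission threshold.  Realized pair columns are kept Simple-8b compressed
and re-used across rebuilds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set

import numpy as np

from .sparse import (
    CompressedColumn,
    DuplicateRegistry,
    InteractionId,
    SparseBinaryMatrix,
    decode_column,
    encode_column,
    interaction_column,
)


@dataclass
class WorkingSetCache:
    """Residual snapshots, inner-product bounds and realized-column caches.

    rho[x] is the residual vector the last time branch x was fully
    enumerated; pi[x] the largest |partner column . rho[x]| seen then.
    eta_cache memoizes eta(x) per residual version (a cached bound is valid
    only while the residuals are unchanged); col_cache stores realized pair
    interaction supports compressed.
    """

    rho: Dict[InteractionId, np.ndarray] = field(default_factory=dict)
    pi: Dict[InteractionId, float] = field(default_factory=dict)
    eta_cache: Dict[InteractionId, tuple] = field(default_factory=dict)
    col_cache: Dict[InteractionId, CompressedColumn] = field(default_factory=dict)
    #: bumped by the solver whenever the residual vector changes;
    #: invalidates eta_cache entries.
    residual_version: int = 0

    def pair_support(self, X: SparseBinaryMatrix, id: InteractionId) -> np.ndarray:
        """Realized (compressed, cached) support of a pair column."""
        c = self.col_cache.get(id)
        if c is None:
            sup, _ = interaction_column(X, id)
            self.col_cache[id] = encode_column(sup)
            return sup
        return decode_column(c)


@dataclass
class ActiveSet:
    """Candidates admitted at the current lambda, with their partial sums."""

    members: Set[InteractionId] = field(default_factory=set)
    partial_sums: Dict[InteractionId, float] = field(default_factory=dict)

    def add(self, id: InteractionId, s: float) -> None:
        self.members.add(id)
        self.partial_sums[id] = s


def _alpha(rho: np.ndarray, r: np.ndarray) -> float:
    """Least-squares projection coefficient of r on rho (0 for rho == 0)."""
    nsq = float(rho @ rho)
    if nsq == 0.0:
        return 0.0
    return float(rho @ r) / nsq


def eta_bound(
    x: InteractionId,
    r: np.ndarray,
    cache: WorkingSetCache,
    support: np.ndarray,
) -> float:
    """Upper bound on |X*_{x o j} . r| over all partner features j > max(x).

    Splits r into alpha * rho_x plus a remainder: the first part is bounded
    by |alpha| * pi_x, the remainder by the larger of the positive- and
    negative-part sums of (r - alpha * rho_x) over supp(x) (any partner
    column selects a subset of those rows).  Returns +inf when no snapshot
    is cached, forcing a fresh enumeration of the branch.
    """
    if x not in cache.rho:
        return math.inf
    key = cache.eta_cache.get(x)
    if key is not None and key[0] == cache.residual_version:
        return key[1]
    rho = cache.rho[x]
    a = _alpha(rho, r)
    d = r[support] - a * rho[support]
    pos = float(d[d > 0.0].sum())
    neg = float(-d[d < 0.0].sum())
    eta = abs(a) * cache.pi[x] + max(pos, neg)
    cache.eta_cache[x] = (cache.residual_version, eta)
    return eta


def eta_bound_nonbinary(
    x: InteractionId,
    r: np.ndarray,
    cache: WorkingSetCache,
    support: np.ndarray,
    vmax_all: float,
    vmax_x: float,
    n_partners: int = 1,
) -> float:
    """Real-valued variant of :func:`eta_bound`.

    A partner column's entries are bounded by |V_all^max| each (squared when
    the branch must also rule out three-way partners, n_partners = 2) and
    the branch's own entries by |V_x^max|, so the remainder term of the
    binary bound is scaled by vmax_x * max(vmax_all, vmax_all**n_partners).
    With all values equal to 1 this reduces exactly to the binary bound.
    """
    if x not in cache.rho:
        return math.inf
    rho = cache.rho[x]
    a = _alpha(rho, r)
    d = r[support] - a * rho[support]
    pos = float(d[d > 0.0].sum())
    neg = float(-d[d < 0.0].sum())
    va = abs(vmax_all)
    scale = abs(vmax_x) * max(va, va ** n_partners)
    return abs(a) * cache.pi[x] + scale * max(pos, neg)


def _branch_eta(
    X: SparseBinaryMatrix,
    x: InteractionId,
    r: np.ndarray,
    cache: WorkingSetCache,
    support: np.ndarray,
    depth: int,
) -> float:
    """Dispatch to the binary or value-scaled bound for branch x."""
    if X.col_values is None:
        return eta_bound(x, r, cache, support)
    vmax_all = max(
        (float(np.max(np.abs(v))) for v in X.col_values if v.size), default=0.0
    )
    if len(x) == 1:
        vmax_x = (
            float(np.max(np.abs(X.col_values[x[0]])))
            if X.col_values[x[0]].size
            else 0.0
        )
        n_partners = 2 if depth >= 3 else 1
    else:
        _, vals = interaction_column(X, x)
        vmax_x = float(np.max(np.abs(vals))) if vals is not None and vals.size else 0.0
        n_partners = 1
    return eta_bound_nonbinary(x, r, cache, support, vmax_all, vmax_x, n_partners)


def _single_sums(X: SparseBinaryMatrix, r: np.ndarray) -> np.ndarray:
    sums = np.empty(X.n_cols)
    for i in range(X.n_cols):
        sup = X.col_supports[i]
        if X.col_values is not None:
            sums[i] = float(X.col_values[i] @ r[sup])
        else:
            sums[i] = float(r[sup].sum())
    return sums


def _pair_sums_for_branch(
    X: SparseBinaryMatrix,
    i: int,
    r: np.ndarray,
    partner_mask: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Row-major accumulation of sum_{i,j} = X*_{i,j} . r for all j > i.

    Returns (partners, sums over those partners).  Walks only the rows in
    supp(X_i), so the cost is proportional to the co-occurrence count.
    """
    rows = X.col_supports[i]
    if rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    weights = r[rows]
    if X.col_values is not None:
        weights = weights * X.col_values[i]
    col_chunks = [X.row_supports[a] for a in rows]
    lens = np.fromiter((c.size for c in col_chunks), dtype=np.int64, count=rows.size)
    if int(lens.sum()) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    cols = np.concatenate(col_chunks)
    w = np.repeat(weights, lens)
    if X.row_values is not None:
        w = w * np.concatenate([X.row_values[a] for a in rows])
    sel = cols > i
    if partner_mask is not None:
        sel &= partner_mask[cols]
    cols = cols[sel]
    w = w[sel]
    acc = np.zeros(X.n_cols)
    np.add.at(acc, cols, w)
    partners = np.unique(cols)
    return partners, acc[partners]


def _triple_sums_for_pair(
    X: SparseBinaryMatrix,
    i: int,
    j: int,
    pair_sup: np.ndarray,
    r: np.ndarray,
    partner_mask: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """sum_{i,j,k} = X*_{i,j,k} . r for all k > j, via the pair's rows."""
    if pair_sup.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    weights = r[pair_sup]
    if X.col_values is not None:
        pi_pos = np.searchsorted(X.col_supports[i], pair_sup)
        pj_pos = np.searchsorted(X.col_supports[j], pair_sup)
        weights = weights * X.col_values[i][pi_pos] * X.col_values[j][pj_pos]
    col_chunks = [X.row_supports[a] for a in pair_sup]
    lens = np.fromiter((c.size for c in col_chunks), dtype=np.int64,
                       count=pair_sup.size)
    if int(lens.sum()) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    cols = np.concatenate(col_chunks)
    w = np.repeat(weights, lens)
    if X.row_values is not None:
        w = w * np.concatenate([X.row_values[a] for a in pair_sup])
    sel = cols > j
    if partner_mask is not None:
        sel &= partner_mask[cols]
    cols = cols[sel]
    w = w[sel]
    acc = np.zeros(X.n_cols)
    np.add.at(acc, cols, w)
    partners = np.unique(cols)
    return partners, acc[partners]


def _identify(
    X: SparseBinaryMatrix,
    r: np.ndarray,
    lam: float,
    omega: float,
    cache: WorkingSetCache,
    dedup: Optional[DuplicateRegistry],
    depth: int,
    hierarchy_set: Optional[Set[int]] = None,
) -> ActiveSet:
    threshold = lam * omega
    p = X.n_cols
    candidates: Dict[InteractionId, float] = {}

    sums1 = _single_sums(X, r)
    for i in range(p):
        if abs(sums1[i]) > threshold:
            candidates[(i,)] = sums1[i]

    if depth >= 2:
        partner_mask = None
        if hierarchy_set is not None:
            partner_mask = np.zeros(p, dtype=bool)
            for i in hierarchy_set:
                partner_mask[i] = True
        for i in range(p):
            if hierarchy_set is not None:
                # hierarchy mode replaces eta pruning: only sticky mains branch
                if i not in hierarchy_set:
                    continue
            else:
                xi = (i,)
                if (
                    _branch_eta(X, xi, r, cache, X.col_supports[i], depth)
                    <= threshold
                ):
                    continue
            partners, psums = _pair_sums_for_branch(X, i, r, partner_mask)
            gamma = abs(sums1[i])
            if psums.size:
                gamma = max(gamma, float(np.max(np.abs(psums))))
            for j, s in zip(partners, psums):
                if abs(s) > threshold:
                    candidates[(i, int(j))] = float(s)
            if depth >= 3:
                for j in partners:
                    pid = (i, int(j))
                    pair_sup = cache.pair_support(X, pid)
                    if hierarchy_set is None:
                        if (
                            _branch_eta(X, pid, r, cache, pair_sup, depth)
                            <= threshold
                        ):
                            continue
                    kparts, tsums = _triple_sums_for_pair(
                        X, i, int(j), pair_sup, r, partner_mask
                    )
                    gamma_star = float(np.max(np.abs(tsums))) if tsums.size else 0.0
                    for k, s in zip(kparts, tsums):
                        if abs(s) > threshold:
                            candidates[(i, int(j), int(k))] = float(s)
                    cache.pi[pid] = gamma_star
                    cache.rho[pid] = r.copy()
                    gamma = max(gamma, gamma_star)
            if hierarchy_set is None:
                cache.pi[(i,)] = gamma
                cache.rho[(i,)] = r.copy()

    active = ActiveSet()
    for id in sorted(candidates):
        if dedup is not None:
            if len(id) == 1:
                sup = X.col_supports[id[0]]
            elif len(id) == 2:
                sup = cache.pair_support(X, id)
            else:
                sup, _ = interaction_column(X, id)
            if not dedup.admit(id, sup):
                continue
        active.add(id, candidates[id])
    return active


def identify_active_set_pairwise(
    X: SparseBinaryMatrix,
    r: np.ndarray,
    lam: float,
    omega: float,
    cache: WorkingSetCache,
    dedup: Optional[DuplicateRegistry] = None,
    hierarchy_set: Optional[Set[int]] = None,
) -> ActiveSet:
    """Admit all main and pairwise candidates with |X*_id . r| > lam * omega.

    Branches whose eta bound rules out every partner are skipped without
    enumerating a single interaction; everything else is found by row-major
    traversal.  Duplicate-support and hierarchy-excluded columns never enter.
    """
    return _identify(X, r, lam, omega, cache, dedup, depth=2,
                     hierarchy_set=hierarchy_set)


def identify_active_set_threeway(
    X: SparseBinaryMatrix,
    r: np.ndarray,
    lam: float,
    omega: float,
    cache: WorkingSetCache,
    dedup: Optional[DuplicateRegistry] = None,
    hierarchy_set: Optional[Set[int]] = None,
) -> ActiveSet:
    """As the pairwise version, plus second-level pruning for triples.

    Triples (i, j, k) are enumerated only when eta({i, j}) exceeds the
    admission threshold; realized pair columns are cached compressed.
    """
    return _identify(X, r, lam, omega, cache, dedup, depth=3,
                     hierarchy_set=hierarchy_set)


def kkt_violations(
    X: SparseBinaryMatrix,
    beta: Dict[InteractionId, float],
    r: np.ndarray,
    lam: float,
    depth: int,
    tol: float = 1e-8,
    exclude: Iterable[InteractionId] = (),
) -> list:
    """Exhaustive post-fit optimality audit (small instances only).

    Returns every candidate id up to ``depth`` whose coefficient is zero yet
    whose column-residual inner product exceeds lam * ||r||_2 * (1 + tol).
    An empty list certifies the zero pattern is optimal.  ``exclude`` lists
    ids deliberately kept out of the model (duplicates, hierarchy-filtered).
    """
    omega = float(np.linalg.norm(r))
    limit = lam * omega * (1.0 + tol)
    excluded = set(exclude)
    out = []
    for order in range(1, depth + 1):
        for combo in itertools.combinations(range(X.n_cols), order):
            if combo in excluded:
                continue
            if beta.get(combo, 0.0) != 0.0:
                continue
            sup, vals = interaction_column(X, combo)
            s = float(vals @ r[sup]) if vals is not None else float(r[sup].sum())
            if abs(s) > limit:
                out.append(combo)
    return out
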