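"""Independent dense reference implementations used as test oracles.

The reference solver fully materializes every candidate interaction column
of X* as a dense vector and runs brute-force threshold admission plus
plain-Python cyclic soft-threshold descent: no eta bounds, no residual
snapshots, no row-major traversal, no compression.  It mirrors the staged
per-lambda structure (mains, then pairs, then triples; rebuild until no new
admission; first-admitted-support-wins duplicate suppression; sticky
hierarchy) so that a pruned fit must reproduce its coefficient path
exactly if and only if the pruning machinery never changes the solution.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def materialize_xstar(Xd: np.ndarray, depth: int) -> dict:
    """Dense element-wise-product column for every id up to depth."""
    n, p = Xd.shape
    cols = {}
    for order in range(1, depth + 1):
        for id in itertools.combinations(range(p), order):
            col = Xd[:, id[0]].astype(float).copy()
            for i in id[1:]:
                col = col * Xd[:, i]
            cols[id] = col
    return cols


def _cd_cycle(stage, cols, colsq, beta, r, lam, tol, max_sweeps=100_000):
    for _ in range(max_sweeps):
        max_step = 0.0
        max_beta = 0.0
        for id in stage:
            a = colsq[id]
            if a == 0.0:
                continue
            col = cols[id]
            g = float(col @ r)
            b_old = beta.get(id, 0.0)
            z = b_old + g / a
            thr = lam * float(np.linalg.norm(r)) / a
            if z > thr:
                bn = z - thr
            elif z < -thr:
                bn = z + thr
            else:
                bn = 0.0
            d = bn - b_old
            if d != 0.0:
                r -= col * d
                beta[id] = bn
            max_step = max(max_step, abs(d))
            max_beta = max(max_beta, abs(bn))
        if max_step <= tol * max(1.0, max_beta):
            return
    raise RuntimeError("reference CD did not converge")


def fit_reference(
    Xd: np.ndarray,
    y: np.ndarray,
    depth: int = 2,
    n_lambda: int = 5,
    max_nonzero: int = 10_000,
    tol: float = 1e-10,
    hierarchy: bool = False,
    lambda_min_override: float | None = None,
):
    """Unpruned dense staged square-root-lasso path.

    Returns (beta dict, list of per-lambda beta dicts, lambda values used).
    """
    n, p = Xd.shape
    cols = materialize_xstar(Xd, depth)
    colsq = {id: float(c @ c) for id, c in cols.items()}
    ids = sorted(cols)
    p_int = len(ids)
    if lambda_min_override is not None:
        lam_min = lambda_min_override
    else:
        lam_min = 1.1 / math.sqrt(n) * float(norm.ppf(1 - 0.05 / (2 * p_int)))
    ynorm = float(np.linalg.norm(y))
    lam_max = (
        max(abs(float(Xd[:, k] @ y)) for k in range(p)) / ynorm * (1.0 + 1e-10)
        if ynorm
        else 0.0
    )
    if n_lambda == 1 or lam_max <= lam_min:
        path = np.array([lam_min])
    else:
        path = np.geomspace(lam_max, lam_min, n_lambda)

    beta: dict = {}
    r = y.astype(float).copy()
    sticky: set = set()
    canonical: dict = {}
    duplicates: set = set()
    per_lambda = []
    for lam in path:
        members = {id for id, b in beta.items() if b != 0.0}
        solved = False
        for _ in range(200):
            omega = float(np.linalg.norm(r))
            admitted = []
            for id in ids:
                if hierarchy and len(id) > 1 and not all(i in sticky for i in id):
                    continue
                if abs(float(cols[id] @ r)) > lam * omega:
                    admitted.append(id)
            act = set()
            for id in sorted(admitted):
                if id in duplicates:
                    continue
                key = np.flatnonzero(cols[id]).tobytes()
                owner = canonical.get(key)
                if owner is None:
                    canonical[key] = id
                    act.add(id)
                elif owner == id:
                    act.add(id)
                else:
                    duplicates.add(id)
            new = act - members
            if solved and not new:
                break
            members |= new
            for order in range(1, depth + 1):
                stage = sorted(id for id in members if len(id) <= order)
                if stage:
                    _cd_cycle(stage, cols, colsq, beta, r, lam, tol)
            if hierarchy:
                sticky.update(
                    id[0] for id, b in beta.items() if len(id) == 1 and b != 0.0
                )
            solved = True
        else:
            raise RuntimeError("reference rebuild loop did not settle")
        beta = {id: b for id, b in beta.items() if b != 0.0}
        per_lambda.append(dict(beta))
        if len(beta) >= max_nonzero:
            break
    return beta, per_lambda, [float(l) for l in path[: len(per_lambda)]]


def dense_threshold_set(Xd: np.ndarray, r: np.ndarray, lam: float,
                        omega: float, depth: int) -> set:
    """Brute-force {id : |X*_id . r| > lam * omega} up to depth."""
    cols = materialize_xstar(Xd, depth)
    return {id for id, c in cols.items() if abs(float(c @ r)) > lam * omega}


def mann_whitney_auc(strength: np.ndarray, labels: np.ndarray) -> float:
    """Rank-sum AUROC oracle: P(true > false) + 0.5 P(tie)."""
    pos = strength[labels]
    neg = strength[~labels]
    wins = ties = 0.0
    for a in pos:
        wins += float((a > neg).sum())
        ties += float((a == neg).sum())
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
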