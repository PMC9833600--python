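"""Square-root-lasso coordinate descent over staged interaction orders.

The model is  y ~ X* beta  with the square-root-lasso objective

    ||y - X* beta||_2 + lambda * ||beta||_1

whose tuning parameter is pivotal with respect to the noise scale: the
terminal lambda has the closed form 1.1 / sqrt(n) * Phi^{-1}(1 - 0.05/(2 p_int))
and needs no cross-validation.  Each coordinate update is a
majorize-minimize step: the norm term is majorized by its tangent at the
current residual, which turns the coordinate subproblem into a soft
threshold at lambda * ||r||_2 / ||col||^2.  Fixed points therefore satisfy
the KKT condition |col . r| <= lambda * ||r||_2 for zero coefficients, and
the true objective decreases at every update.

At each lambda on a geometric path the active set is rebuilt (pruning
module) and solved in stages - main effects to convergence first, then
pairs, then triples - so higher orders only absorb variance the lower
orders cannot explain.  The rebuild/solve loop repeats until a fresh
identification admits nothing new, which makes the exhaustive KKT audit
pass exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from numba import njit
from scipy.stats import norm as _normal

from .pruning import (
    ActiveSet,
    WorkingSetCache,
    _single_sums,
    identify_active_set_pairwise,
    identify_active_set_threeway,
)
from .sparse import (
    DuplicateRegistry,
    InteractionId,
    SparseBinaryMatrix,
    interaction_column,
)


class ConvergenceError(RuntimeError):
    """Cyclic descent failed to converge within the sweep cap."""

    def __init__(self, sweeps: int, last_delta: float):
        super().__init__(
            f"no convergence after {sweeps} sweeps (last sweep delta {last_delta:g})"
        )
        self.sweeps = sweeps
        self.last_delta = last_delta


@dataclass
class FitConfig:
    """Fitting options.

    depth: highest interaction order (1 = mains only, 3 = three-way).
    max_nonzero: halt at the end of the first lambda whose model holds at
        least this many nonzero effects.
    convergence_tol: a sweep converges when the largest coefficient change
        is below tol * max(1, largest |beta|); default 1% .
    n_lambda: length of the geometric lambda path.
    hierarchy: restrict interactions to features that have at some point
        held a nonzero main effect (sticky membership).
    """

    depth: int = 2
    max_nonzero: int = 100
    convergence_tol: float = 0.01
    n_lambda: int = 100
    hierarchy: bool = False
    lambda_min_override: Optional[float] = None
    max_sweeps: int = 100_000

    def __post_init__(self) -> None:
        if self.depth not in (1, 2, 3):
            raise ValueError("depth must be 1, 2 or 3")
        if self.max_nonzero < 1:
            raise ValueError("max_nonzero must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class ModelState:
    """Coefficients, residuals and the running residual norm."""

    beta: Dict[InteractionId, float]
    r: np.ndarray
    lambda_current: float = math.inf

    @property
    def omega(self) -> float:
        return float(np.linalg.norm(self.r))

    # the square-root-lasso error term ||Y - X beta||_2 equals omega
    e_mse = omega

    @property
    def n_nonzero(self) -> int:
        return sum(1 for b in self.beta.values() if b != 0.0)


@dataclass
class FitResult:
    """A completed fit: final state plus per-lambda diagnostics."""

    state: ModelState
    lambda_path: List[float]
    nonzero_history: List[int]
    #: coefficient snapshot (nonzero entries) at the end of each lambda
    beta_history: List[Dict[InteractionId, float]]
    config: FitConfig
    cache: WorkingSetCache
    dedup: DuplicateRegistry
    sticky_mains: Set[int]

    @property
    def selected(self) -> List[InteractionId]:
        return sorted(id for id, b in self.state.beta.items() if b != 0.0)


def lambda_min(n: int, p_int: int) -> float:
    """Closed-form terminal lambda: 1.1 / sqrt(n) * Phi^{-1}(1 - 0.05 / (2 p_int)).

    Phi^{-1} is the standard-normal quantile; the value grows with the
    number of candidate columns and shrinks as 1/sqrt(n).
    """
    if n < 1 or p_int < 1:
        raise ValueError("n and p_int must be >= 1")
    return 1.1 / math.sqrt(n) * float(_normal.ppf(1.0 - 0.05 / (2.0 * p_int)))


def lambda_path(lam_max: float, lam_min: float, n_lambda: int) -> np.ndarray:
    """Geometric sequence from lam_max down to lam_min, inclusive."""
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    if n_lambda == 1 or lam_max <= lam_min:
        return np.array([lam_min])
    return np.geomspace(lam_max, lam_min, n_lambda)


@njit(cache=True)
def _cd_kernel(indptr, indices, values, colsq, beta, r, lam, tol, max_sweeps):
    """Cyclic soft-threshold sweeps over the active members.

    Residual sum of squares is refreshed from scratch at each sweep start
    and maintained incrementally within the sweep, so the threshold always
    uses the current ||r||_2.  Returns (sweeps used, last sweep delta);
    sweeps is -1 on non-convergence.
    """
    m = beta.shape[0]
    n = r.shape[0]
    max_step = 0.0
    for sweep in range(max_sweeps):
        rsq = 0.0
        for i in range(n):
            rsq += r[i] * r[i]
        max_step = 0.0
        max_beta = 0.0
        for k in range(m):
            s = indptr[k]
            e = indptr[k + 1]
            if s == e:
                continue
            g = 0.0
            for t in range(s, e):
                g += values[t] * r[indices[t]]
            a = colsq[k]
            z = beta[k] + g / a
            if rsq < 0.0:
                rsq = 0.0
            thr = lam * math.sqrt(rsq) / a
            if z > thr:
                bn = z - thr
            elif z < -thr:
                bn = z + thr
            else:
                bn = 0.0
            d = bn - beta[k]
            if d != 0.0:
                beta[k] = bn
                for t in range(s, e):
                    i2 = indices[t]
                    ro = r[i2]
                    rn = ro - values[t] * d
                    rsq += rn * rn - ro * ro
                    r[i2] = rn
            ad = abs(d)
            if ad > max_step:
                max_step = ad
            ab = abs(bn)
            if ab > max_beta:
                max_beta = ab
        floor = max_beta if max_beta > 1.0 else 1.0
        if max_step <= tol * floor:
            return sweep + 1, max_step
    return -1, max_step


def coordinate_update(
    state: ModelState,
    id: InteractionId,
    support: np.ndarray,
    values: Optional[np.ndarray],
    lam: float,
) -> ModelState:
    """Single soft-threshold update of one coefficient (in place).

    Empty columns are a no-op with the coefficient forced to zero.
    """
    if support.size == 0:
        state.beta[id] = 0.0
        return state
    v = values if values is not None else np.ones(support.size)
    r = state.r
    g = float(v @ r[support])
    a = float(v @ v)
    b_old = state.beta.get(id, 0.0)
    z = b_old + g / a
    thr = lam * float(np.linalg.norm(r)) / a
    if z > thr:
        b_new = z - thr
    elif z < -thr:
        b_new = z + thr
    else:
        b_new = 0.0
    if b_new != b_old:
        r[support] -= v * (b_new - b_old)
    state.beta[id] = b_new
    return state


class _ColumnStore:
    """Materialized (support, values, ||col||^2) per candidate id."""

    def __init__(self, X: SparseBinaryMatrix, cache: WorkingSetCache):
        self.X = X
        self.cache = cache
        self._cols: Dict[InteractionId, tuple] = {}

    def get(self, id: InteractionId):
        col = self._cols.get(id)
        if col is None:
            if len(id) == 1:
                sup = self.X.col_supports[id[0]]
                vals = (
                    self.X.col_values[id[0]]
                    if self.X.col_values is not None
                    else None
                )
            elif len(id) == 2 and self.X.col_values is None:
                sup = self.cache.pair_support(self.X, id)
                vals = None
            else:
                sup, vals = interaction_column(self.X, id)
            v = vals if vals is not None else np.ones(sup.size)
            col = (sup, v, float(v @ v))
            self._cols[id] = col
        return col


def solve_subproblem(
    state: ModelState,
    active: Sequence[InteractionId],
    columns: _ColumnStore,
    lam: float,
    tol: float,
    max_sweeps: int = 100_000,
) -> Tuple[ModelState, int]:
    """Cyclic descent over ``active`` (sorted id order) until convergence."""
    members = sorted(set(active))
    if not members:
        return state, 0
    sups, vals, sqs = [], [], []
    for id in members:
        sup, v, sq = columns.get(id)
        sups.append(sup)
        vals.append(v)
        sqs.append(sq)
    lens = np.array([s.size for s in sups], dtype=np.int64)
    indptr = np.zeros(len(members) + 1, dtype=np.int64)
    np.cumsum(lens, out=indptr[1:])
    indices = (
        np.concatenate(sups) if lens.sum() else np.empty(0, dtype=np.int64)
    )
    values = np.concatenate(vals) if lens.sum() else np.empty(0)
    colsq = np.array([sq if sq > 0 else 1.0 for sq in sqs])
    beta = np.array([state.beta.get(id, 0.0) for id in members])
    sweeps, last_delta = _cd_kernel(
        indptr, indices, values.astype(np.float64), colsq, beta, state.r,
        lam, tol, max_sweeps,
    )
    for id, b in zip(members, beta):
        state.beta[id] = float(b)
    if sweeps < 0:
        raise ConvergenceError(max_sweeps, float(last_delta))
    return state, sweeps


def _lambda_max(X: SparseBinaryMatrix, y: np.ndarray) -> float:
    """Smallest lambda at which the all-zero model satisfies the KKT
    condition over single-feature columns: max_k |X_k . y| / ||y||_2."""
    ynorm = float(np.linalg.norm(y))
    if ynorm == 0.0:
        return 0.0
    best = 0.0
    for k in range(X.n_cols):
        sup = X.col_supports[k]
        if X.col_values is not None:
            s = abs(float(X.col_values[k] @ y[sup]))
        else:
            s = abs(float(y[sup].sum()))
        best = max(best, s)
    # nudged up so the all-zero model is strictly optimal at lam_max even
    # under floating-point ties
    return best / ynorm * (1.0 + 1e-10)


def _n_candidates(p: int, depth: int) -> int:
    total = p
    if depth >= 2:
        total += p * (p - 1) // 2
    if depth >= 3:
        total += p * (p - 1) * (p - 2) // 6
    return total


def fit(X: SparseBinaryMatrix, y: np.ndarray, cfg: FitConfig) -> FitResult:
    """Walk the lambda path, rebuilding and solving staged active sets.

    At each lambda, main effects are solved to convergence first, then
    mains+pairs, then mains+pairs+triples (up to cfg.depth); the
    rebuild/solve loop repeats until no new candidate is admitted.  Fitting
    halts at the end of the first lambda iteration holding at least
    cfg.max_nonzero nonzero effects, or at the terminal lambda.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.shape[0] != X.n_rows:
        raise ValueError(
            f"phenotype length {y.shape} does not match n_rows={X.n_rows}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")

    p_int = _n_candidates(X.n_cols, cfg.depth)
    lam_min = (
        cfg.lambda_min_override
        if cfg.lambda_min_override is not None
        else lambda_min(X.n_rows, p_int)
    )
    path = lambda_path(_lambda_max(X, y), lam_min, cfg.n_lambda)

    state = ModelState(beta={}, r=y.copy())
    cache = WorkingSetCache()
    dedup = DuplicateRegistry()
    columns = _ColumnStore(X, cache)
    sticky: Set[int] = set()
    identify = (
        identify_active_set_threeway if cfg.depth >= 3
        else identify_active_set_pairwise
    )

    nonzero_history: List[int] = []
    beta_history: List[Dict[InteractionId, float]] = []
    for lam in path:
        members: Set[InteractionId] = {
            id for id, b in state.beta.items() if b != 0.0
        }
        solved_once = False
        for _rebuild in range(200):
            omega = state.omega
            if cfg.depth == 1:
                active = ActiveSet()
                sums = _single_sums(X, state.r)
                for i in range(X.n_cols):
                    if abs(sums[i]) > lam * omega and dedup.admit(
                        (i,), X.col_supports[i]
                    ):
                        active.add((i,), float(sums[i]))
            else:
                active = identify(
                    X, state.r, lam, omega, cache, dedup,
                    hierarchy_set=sticky if cfg.hierarchy else None,
                )
            new = active.members - members
            if solved_once and not new:
                break
            members |= new
            for order in range(1, cfg.depth + 1):
                stage = [id for id in members if len(id) <= order]
                if not stage:
                    continue
                state, _ = solve_subproblem(
                    state, stage, columns, lam, cfg.convergence_tol,
                    cfg.max_sweeps,
                )
                cache.residual_version += 1
            if cfg.hierarchy:
                sticky.update(
                    id[0]
                    for id, b in state.beta.items()
                    if len(id) == 1 and b != 0.0
                )
            solved_once = True
        else:
            raise ConvergenceError(200, math.nan)
        # drop exact zeros so later stages and halting see true counts
        state.beta = {id: b for id, b in state.beta.items() if b != 0.0}
        state.lambda_current = float(lam)
        nonzero_history.append(state.n_nonzero)
        beta_history.append(dict(state.beta))
        if state.n_nonzero >= cfg.max_nonzero:
            break
    return FitResult(
        state=state,
        lambda_path=[float(l) for l in path[: len(nonzero_history)]],
        nonzero_history=nonzero_history,
        beta_history=beta_history,
        config=cfg,
        cache=cache,
        dedup=dedup,
        sticky_mains=sticky,
    )
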