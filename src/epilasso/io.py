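"""File formats and the post-selection least-squares refit.

Design matrices are read from MatrixMarket coordinate files (1-based,
pattern / integer / real) or delimited tables with a header row of feature
names; phenotypes are plain single-column text.  The final effect table
follows the schema (lasso estimate, least-squares estimate, p-value, up to
three feature names), sorted by p-value.

The refit realizes the selected interaction columns as a dense matrix Z and
fits Y ~ Z by ordinary least squares with an intercept; the resulting
estimates are unbiased given the selection, and their t-test p-values, the
adjusted R-squared and the AIC are reported as-is.  Note the p-values do
not account for how the columns were selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.linalg
import scipy.sparse
import statsmodels.api as sm

from .sparse import InteractionId, SparseBinaryMatrix, interaction_column

EFFECT_TABLE_COLUMNS = [
    "lasso_estimate",
    "least_squares_estimate",
    "p_value",
    "gene_1",
    "gene_2",
    "gene_3",
]


def _default_names(p: int) -> List[str]:
    return [f"col{j}" for j in range(p)]


def read_design(
    path: str | Path,
    format: str = "mtx",
    values: str = "binary",
) -> SparseBinaryMatrix:
    """Read a design matrix from MatrixMarket ("mtx") or delimited ("csv").

    In binary mode any nonzero entry becomes 1; in real mode entry values
    are preserved.  CSV files must carry a header row of feature names;
    MatrixMarket columns are named col<j> (0-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    real = values == "real"
    if values not in ("binary", "real"):
        raise ValueError(f"values must be 'binary' or 'real', got {values!r}")
    if format == "mtx":
        try:
            mat = spio.mmread(str(path))
        except ValueError as e:
            raise ValueError(f"{path}: malformed MatrixMarket file: {e}") from e
        mat = scipy.sparse.coo_matrix(mat)
        if mat.nnz and mat.row.min() < 0:
            raise ValueError(f"{path}: negative row index")
        names = _default_names(mat.shape[1])
        return SparseBinaryMatrix.from_scipy(mat, real_values=real, names=names)
    if format == "csv":
        try:
            df = pd.read_csv(path, sep=None, engine="python")
        except pd.errors.ParserError as e:
            raise ValueError(f"{path}: malformed delimited file: {e}") from e
        arr = df.to_numpy(dtype=np.float64)
        return SparseBinaryMatrix.from_dense(
            arr, real_values=real, names=[str(c) for c in df.columns]
        )
    raise ValueError(f"unknown design format {format!r}")


def write_design(X: SparseBinaryMatrix, path: str | Path) -> None:
    """Write as 1-based MatrixMarket coordinate (real field)."""
    rows, cols, data = [], [], []
    for j, sup in enumerate(X.col_supports):
        rows.extend(int(i) for i in sup)
        cols.extend([j] * sup.size)
        vals = X.col_values[j] if X.col_values is not None else np.ones(sup.size)
        data.extend(float(v) for v in vals)
    coo = scipy.sparse.coo_matrix(
        (data, (rows, cols)), shape=(X.n_rows, X.n_cols)
    )
    spio.mmwrite(str(path), coo)


def read_phenotype(path: str | Path) -> np.ndarray:
    y = np.loadtxt(path, dtype=np.float64, ndmin=1)
    if y.ndim != 1:
        raise ValueError(f"{path}: phenotype must be a single column")
    return y


def write_phenotype(y: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(y), fmt="%.17g")


def write_truth(effects: Dict[InteractionId, float], path: str | Path,
                names: Optional[Sequence[str]] = None) -> None:
    rows = []
    for id in sorted(effects):
        genes = [
            (names[i] if names is not None else f"col{i}") for i in id
        ] + [""] * (3 - len(id))
        rows.append(genes + [effects[id]])
    pd.DataFrame(
        rows, columns=["gene_1", "gene_2", "gene_3", "true_beta"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> Dict[Tuple[str, ...], float]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_1": str, "gene_2": str,
                                            "gene_3": str})
    out: Dict[Tuple[str, ...], float] = {}
    for _, row in df.iterrows():
        genes = tuple(
            str(row[c]) for c in ("gene_1", "gene_2", "gene_3")
            if c in df.columns and isinstance(row[c], str) and row[c] != ""
            and row[c] != "nan"
        )
        out[genes] = float(row.iloc[-1])
    return out


@dataclass
class RefitMeta:
    adjusted_r2: float
    aic: float
    dropped_collinear: List[InteractionId]


def refit_ols(
    X: SparseBinaryMatrix,
    y: np.ndarray,
    selected: Sequence[InteractionId],
    lasso_estimates: Optional[Dict[InteractionId, float]] = None,
) -> Tuple[pd.DataFrame, RefitMeta]:
    """Post-selection OLS refit Y ~ Z over the selected interaction columns.

    Z holds the realized columns of the selected effects; collinear columns
    (beyond an intercept-augmented pivoted-QR rank check) are dropped with
    a record in the returned metadata.  The effect table is sorted by
    p-value ascending.
    """
    selected = sorted(set(selected))
    if not selected:
        raise ValueError("no effects selected; nothing to refit")
    y = np.asarray(y, dtype=np.float64)
    if len(selected) >= X.n_rows:
        raise ValueError(
            f"{len(selected)} selected effects with only {X.n_rows} samples; "
            "stop the lasso at a larger lambda"
        )
    Z = np.zeros((X.n_rows, len(selected)))
    for t, id in enumerate(selected):
        sup, vals = interaction_column(X, id)
        Z[sup, t] = vals if vals is not None else 1.0
    design = np.column_stack([np.ones(X.n_rows), Z])
    _, Rq, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    rank_tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > rank_tol).sum())
    keep_design = sorted(piv[:rank])
    kept = [selected[j - 1] for j in keep_design if j != 0]
    dropped = [id for id in selected if id not in kept]
    cols = [selected.index(id) for id in kept]
    model = sm.OLS(y, sm.add_constant(Z[:, cols], has_constant="add")).fit()
    names = X.names if X.names is not None else _default_names(X.n_cols)
    rows = []
    for t, id in enumerate(kept):
        genes = [names[i] for i in id] + [""] * (3 - len(id))
        rows.append(
            {
                "lasso_estimate": (
                    lasso_estimates.get(id, np.nan)
                    if lasso_estimates is not None
                    else np.nan
                ),
                "least_squares_estimate": model.params[t + 1],
                "p_value": model.pvalues[t + 1],
                "gene_1": genes[0],
                "gene_2": genes[1],
                "gene_3": genes[2],
            }
        )
    table = (
        pd.DataFrame(rows, columns=EFFECT_TABLE_COLUMNS)
        .sort_values("p_value", kind="stable")
        .reset_index(drop=True)
    )
    meta = RefitMeta(
        adjusted_r2=float(model.rsquared_adj),
        aic=float(model.aic),
        dropped_collinear=dropped,
    )
    return table, meta


def write_effect_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_run_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
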