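"""Mass-univariate GLM with max-t permutation FWE correction.

Each metric (band power, exponent, CoE, peak parameter, global AEC) in each
parcel gets its own ordinary-least-squares fit to a shared subject-level
design matrix. Effects are summarised as contrasts of parameter estimates
(copes) with t-statistics, and family-wise error across parcels (and bands,
where relevant) is controlled non-parametrically: the regressor(s) of
interest are permuted across subjects with nuisance regressors held fixed,
the maximum |t| over all cells is recorded per permutation, and the
corrected p-value is the exceedance probability of the observed |t| under
that null,

    p = (1 + #{max-|t| null >= |t_obs|}) / (n_perm + 1).

The module also provides the design builders for the three analyses
(healthy-ageing regression, pairwise group comparison, per-group beta-ageing
slopes), the residual degrees-of-freedom report, and the demographic
chi-squared sex-balance check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "Contrast",
    "GLMFit",
    "PermGLMResult",
    "build_design",
    "fit_glm",
    "maxt_permutation",
    "residual_df_report",
    "chi_squared_sex_balance",
    "sex_counts_from_percent",
]


@dataclass
class DesignMatrix:
    """Subject-level design: rows align with the metric table's subjects."""

    matrix: np.ndarray
    columns: list[str]
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match column names")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < len(self.columns):
            corr = np.corrcoef(self.matrix, rowvar=False)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {len(self.columns)}); "
                f"most collinear columns: {self.columns[i]!r}, {self.columns[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


@dataclass
class Contrast:
    """Weight vector over design columns; tested two-tailed."""

    name: str
    weights: np.ndarray
    two_tailed: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights):
            raise ValueError(f"contrast {self.name!r} is all zero")


class GLMFit(NamedTuple):
    cope: float
    se: float
    t: float
    df: int


@dataclass
class PermGLMResult:
    """Copes, t-statistics and max-t FWE-corrected p-values per cell."""

    contrast: str
    cell_labels: list
    copes: np.ndarray
    ses: np.ndarray
    ts: np.ndarray
    df: int
    null_max_t: np.ndarray
    p_fwe: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cell_labels,
                "contrast": self.contrast,
                "cope": self.copes,
                "se": self.ses,
                "t": self.ts,
                "df": self.df,
                "p_fwe": self.p_fwe,
            }
        )


def _centred(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _encode_sex(sex: pd.Series) -> np.ndarray:
    if sex.dtype == object:
        mapping = {"M": 1.0, "F": 0.0, "male": 1.0, "female": 0.0}
        try:
            return sex.map(mapping).to_numpy(dtype=float)
        except Exception as err:
            raise ValueError(f"unrecognised sex coding: {sex.unique()}") from err
    return sex.to_numpy(dtype=float)


def _indicator_columns(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Centred indicator columns for every level beyond the first."""
    levels = list(pd.unique(values))
    cols, names = [], []
    for level in levels[1:]:
        cols.append(_centred((values == level).to_numpy(dtype=float)))
        names.append(f"{prefix}[{level}]")
    return (np.column_stack(cols) if cols else np.empty((len(values), 0)), names)


def build_design(
    records: pd.DataFrame, analysis: str
) -> tuple[DesignMatrix, list[Contrast]]:
    """Design matrix and contrasts for one of the three analyses.

    ``records`` must carry columns ``subject_id, group, age, sex, scanner``
    (plus ``gm_volume`` for the group comparison). Covariates are
    mean-centred; constant covariate columns (e.g. a single-scanner cohort)
    are dropped with a warning.

    analyses
    --------
    ``ageing``
        Columns {intercept, age, sex, scanner}; one contrast on age.
    ``group_compare``
        One indicator per group plus centred {age, sex, scanner, gm_volume};
        pairwise (+1, -1) group contrasts.
    ``beta_ageing_by_group``
        Per-group intercepts and per-group (centred) age slopes; contrasts
        on age-slope differences between groups.
    """
    required = {"subject_id", "group", "age", "sex", "scanner"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"covariate table missing columns: {sorted(missing_cols)}")
    if records[list(required)].isna().any().any():
        bad = records.index[records[list(required)].isna().any(axis=1)].tolist()
        raise ValueError(f"missing covariates in rows {bad}")

    n = len(records)
    age = records["age"].to_numpy(dtype=float)
    sex = _encode_sex(records["sex"])
    scan_cols, scan_names = _indicator_columns(records["scanner"], "scanner")
    if not scan_names:
        warnings.warn("single-level scanner column dropped from design", stacklevel=2)
    groups = list(pd.unique(records["group"]))

    def nuisance(extra_gm: bool):
        cols = [_centred(age), _centred(sex)]
        names = ["age", "sex"]
        if scan_names:
            cols.append(scan_cols)
            names += scan_names
        if extra_gm:
            if "gm_volume" not in records:
                raise ValueError("group comparison requires a gm_volume column")
            cols.append(_centred(records["gm_volume"].to_numpy(dtype=float)))
            names.append("gm_volume")
        return np.column_stack([np.column_stack([c]) if c.ndim == 1 else c for c in cols]), names

    if analysis == "ageing":
        cols = [np.ones(n), age, _centred(sex)]
        names = ["intercept", "age", "sex"]
        if scan_names:
            cols.append(scan_cols)
            names += scan_names
        X = np.column_stack([np.column_stack([c]) if c.ndim == 1 else c for c in cols])
        design = DesignMatrix(X, names, list(records["subject_id"]))
        w = np.zeros(len(names))
        w[names.index("age")] = 1.0
        return design, [Contrast("age", w)]

    if analysis == "group_compare":
        if len(groups) < 2:
            raise ValueError("group comparison needs at least 2 groups")
        counts = records["group"].value_counts()
        if (counts < 2).any():
            raise ValueError(f"need >= 2 subjects per group, got {counts.to_dict()}")
        ind = np.column_stack(
            [(records["group"] == g).to_numpy(dtype=float) for g in groups]
        )
        nuis, nuis_names = nuisance(extra_gm=True)
        names = [f"group[{g}]" for g in groups] + nuis_names
        design = DesignMatrix(np.column_stack([ind, nuis]), names, list(records["subject_id"]))
        contrasts = []
        for i, gi in enumerate(groups):
            for j, gj in enumerate(groups):
                if i < j:
                    w = np.zeros(len(names))
                    w[i], w[j] = 1.0, -1.0
                    contrasts.append(Contrast(f"{gi}-{gj}", w))
        return design, contrasts

    if analysis == "beta_ageing_by_group":
        if len(groups) < 2:
            raise ValueError("slope comparison needs at least 2 groups")
        age_c = _centred(age)
        ind = [(records["group"] == g).to_numpy(dtype=float) for g in groups]
        cols = ind + [ig * age_c for ig in ind] + [_centred(sex)]
        names = (
            [f"group[{g}]" for g in groups]
            + [f"age:{g}" for g in groups]
            + ["sex"]
        )
        if scan_names:
            cols.append(scan_cols)
            names += scan_names
        X = np.column_stack([np.column_stack([c]) if c.ndim == 1 else c for c in cols])
        design = DesignMatrix(X, names, list(records["subject_id"]))
        contrasts = []
        for i, gi in enumerate(groups):
            for j, gj in enumerate(groups):
                if i < j:
                    w = np.zeros(len(names))
                    w[names.index(f"age:{gi}")] = 1.0
                    w[names.index(f"age:{gj}")] = -1.0
                    contrasts.append(Contrast(f"age:{gi}-age:{gj}", w))
        return design, contrasts

    raise ValueError(f"unknown analysis {analysis!r}")


def _ols_t(Y: np.ndarray, X: np.ndarray, w: np.ndarray, df: int):
    """Vectorised OLS copes/SEs/t for all columns of Y against a fixed X."""
    xtx_inv = np.linalg.pinv(X.T @ X)
    proj = xtx_inv @ X.T
    beta = proj @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    copes = w @ beta
    var_w = float(w @ xtx_inv @ w)
    ses = np.sqrt(np.clip(var_w * sigma2, 1e-300, None))
    return copes, ses, copes / ses


def fit_glm(y: np.ndarray, X: DesignMatrix | np.ndarray, c: Contrast) -> GLMFit:
    """OLS fit of a single metric vector; cope, SE, t and residual df."""
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != Xm.shape[0]:
        raise ValueError("metric vector and design have different numbers of subjects")
    df = y.shape[0] - np.linalg.matrix_rank(Xm)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    resid = y - Xm @ (np.linalg.pinv(Xm) @ y)
    if np.sum(resid**2) <= 1e-12 * max(float(np.var(y)), 1e-30) * y.shape[0]:
        raise ValueError("zero residual variance: t-statistic undefined")
    copes, ses, ts = _ols_t(y[:, None], Xm, c.weights, df)
    return GLMFit(float(copes[0]), float(ses[0]), float(ts[0]), int(df))


def maxt_permutation(
    Y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    c: Contrast,
    n_perm: int = 5000,
    seed: int = 0,
    cell_labels: list | None = None,
    effect_columns: np.ndarray | None = None,
) -> PermGLMResult:
    """Max-t permutation FWE correction across all cells of Y.

    ``Y`` is subjects x cells (cells = parcels x metrics/bands). Rows of the
    effect columns — by default the columns with non-zero contrast weight —
    are permuted across subjects with nuisance columns held fixed; the null
    distribution is the per-permutation maximum of |t| over all cells.
    """
    Xm = (X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)).copy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, n_cells = Y.shape
    if Xm.shape[0] != n:
        raise ValueError("Y and X have different numbers of subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if math.factorial(n) < n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist for n={n}; "
            "sampling with replacement",
            stacklevel=2,
        )
    eff = (
        np.nonzero(c.weights)[0]
        if effect_columns is None
        else np.asarray(effect_columns, dtype=int)
    )
    df = n - np.linalg.matrix_rank(Xm)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    copes, ses, ts = _ols_t(Y, Xm, c.weights, df)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    Xp = Xm.copy()
    for k in range(n_perm):
        perm = rng.permutation(n)
        Xp[:, eff] = Xm[perm][:, eff]
        _, _, tp = _ols_t(Y, Xp, c.weights, df)
        null[k] = np.max(np.abs(tp))

    p_fwe = (1 + np.sum(null[:, None] >= np.abs(ts)[None, :], axis=0)) / (n_perm + 1)
    return PermGLMResult(
        contrast=c.name,
        cell_labels=list(cell_labels) if cell_labels is not None else list(range(n_cells)),
        copes=copes,
        ses=ses,
        ts=ts,
        df=int(df),
        null_max_t=null,
        p_fwe=p_fwe,
    )


def residual_df_report(
    n_subjects: int, X: DesignMatrix | np.ndarray, n_comparisons: int = 1
) -> dict:
    """Operative residual df plus the conventional reporting formula.

    The operative degrees of freedom used for inference are
    ``n - rank(X)``. The reporting convention
    ``n - (n_comparisons + n_regressors - 1 + 1)`` is echoed alongside for
    results tables; with ambiguous regressor bookkeeping the two can differ,
    and the operative value is authoritative.
    """
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    if n_subjects <= 0 or n_comparisons <= 0:
        raise ValueError("n_subjects and n_comparisons must be positive")
    rank = int(np.linalg.matrix_rank(Xm))
    n_regressors = Xm.shape[1]
    return {
        "operative_df": n_subjects - rank,
        "formula_df": n_subjects - (n_comparisons + n_regressors - 1 + 1),
        "rank": rank,
        "n_regressors": n_regressors,
    }


def chi_squared_sex_balance(counts: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared test of sex balance across groups.

    ``counts`` is a groups x 2 (male, female) table. No continuity
    correction is applied; df = (rows - 1)(cols - 1).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("counts must be a groups x {male, female} table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column in contingency table")
    chi2, _p, df, _exp = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df)


def sex_counts_from_percent(ns, pct_male) -> np.ndarray:
    """Reconstruct a male/female count table from group sizes and % male."""
    rows = []
    for n, pct in zip(ns, pct_male):
        male = int(round(n * pct / 100.0))
        rows.append((male, n - male))
    return np.asarray(rows)
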