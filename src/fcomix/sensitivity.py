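"""Sensitivity and secondary analyses around the FCO estimates.

Covers the correlation of FCO with age, tumor purity and leukocyte
infiltration; purity-adjusted linear models; the nonzero-IQR screen that
restricts secondary analyses to cohorts where the FCO estimate actually
varies; the FCO-tumor-stage trend; and extraction of individual probe
betas (e.g. the three EZH2-associated library CpGs) into a tidy table.

All linear models here reuse the OLS core of :mod:`fcomix.comparison`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import CovariateSpec, _check_rank, _ols
from .io import FcomixError


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str           # "pearson" or "spearman"
    r: float              # NaN when degenerate
    p: float
    n: int
    zero_variance: bool = False


@dataclass(frozen=True)
class SlopeResult:
    """OLS slope of FCO on a numeric predictor (purity, stage...)."""

    variable: str
    coef: float
    t: float
    p: float
    n: int
    degenerate: bool = False


def correlate_fco(
    fco: pd.Series,
    covariate: pd.Series,
    method: str = "spearman",
    variable: str = "",
) -> CorrelationResult:
    """Pairwise-complete correlation between FCO and a numeric covariate.

    Spearman (default; robust to the heavy zero-inflation typical of FCO
    estimates) is computed as Pearson on midranks; p-values use the
    t approximation. Zero variance in either vector yields an NA result
    with ``zero_variance=True`` rather than an exception.
    """
    if method not in ("pearson", "spearman"):
        raise FcomixError(f"unknown correlation method {method!r}")
    df = pd.DataFrame({"fco": fco, "cov": covariate}).dropna()
    n = len(df)
    if n < 3:
        raise FcomixError(f"need >= 3 complete pairs, got {n}")
    x = df["fco"].to_numpy(dtype=float)
    y = df["cov"].to_numpy(dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(variable, method, np.nan, np.nan, n,
                                 zero_variance=True)
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(variable, method, r, p, n)


def purity_adjusted_model(
    fco: pd.Series,
    purity: pd.Series,
    sheet: pd.DataFrame,
    spec: CovariateSpec,
) -> SlopeResult:
    """OLS of FCO on tumor purity plus the screened covariates.

    Reports the purity coefficient: a negative value means samples with a
    larger malignant-cell fraction carry less of the fetal signature.
    """
    return _slope_model(fco, purity, sheet, spec, variable="purity")


def stage_association(fco: pd.Series, stage: pd.Series) -> SlopeResult:
    """Linear trend of FCO on tumor stage coded as an integer score.

    Stage may be given as integers 1-4 or roman numerals (sub-stages such
    as IIIa collapse to the major stage). A single observed stage level
    yields a degenerate NA result.
    """
    stage_num = stage.map(encode_stage) if stage.dtype == object else stage
    df = pd.DataFrame({"fco": fco, "stage": stage_num}).dropna()
    if len(df) < 3:
        raise FcomixError(f"need >= 3 samples with stage, got {len(df)}")
    if df["stage"].nunique() < 2:
        return SlopeResult("stage", np.nan, np.nan, np.nan, len(df),
                           degenerate=True)
    empty_spec = CovariateSpec((), ())
    return _slope_model(df["fco"], df["stage"], pd.DataFrame(index=df.index),
                        empty_spec, variable="stage")


def _slope_model(
    fco: pd.Series,
    predictor: pd.Series,
    sheet: pd.DataFrame,
    spec: CovariateSpec,
    variable: str,
) -> SlopeResult:
    df = pd.DataFrame({"fco": fco, variable: predictor})
    for name in spec.used:
        col = sheet[name].reindex(fco.index)
        if col.dtype == object:
            col = col.replace("", np.nan)
        df[name] = col
    df = df.dropna()
    if len(df) < 3:
        raise FcomixError(f"need >= 3 complete-case samples, got {len(df)}")
    if df[variable].nunique() < 2:
        return SlopeResult(variable, np.nan, np.nan, np.nan, len(df),
                           degenerate=True)
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for name in spec.used:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            X[name] = col.astype(float)
        else:
            for lev in sorted(col.unique())[1:]:
                X[f"{name}[{lev}]"] = (col == lev).astype(float)
    X[variable] = df[variable].astype(float)
    _check_rank(X)
    y = df["fco"].to_numpy(dtype=float)
    beta, _, resid, sigma2 = _ols(y, X.to_numpy())
    df_resid = len(y) - X.shape[1]
    XtX_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
    j = X.columns.get_loc(variable)
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    t = float(beta[j] / se)
    p = float(2 * stats.t.sf(abs(t), df_resid))
    return SlopeResult(variable, float(beta[j]), t, p, len(y))


_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def encode_stage(value) -> float:
    """Map a stage label to an ordinal 1-4 score.

    Accepts integers, "Stage IIIa"-style strings and bare roman numerals;
    sub-stage letters are stripped so IIIa/IIIb collapse to 3. Returns NaN
    for missing/unparseable values.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, np.integer)):
        return float(value)
    if isinstance(value, float):
        return value
    s = str(value).strip().lower()
    if not s or s in ("na", "nan"):
        return np.nan
    s = s.removeprefix("stage").strip()
    s = s.rstrip("abc")
    if s in _ROMAN:
        return float(_ROMAN[s])
    try:
        return float(int(s))
    except ValueError:
        return np.nan


def iqr_screen(fco_by_cohort: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Select cohorts whose FCO interquartile range is nonzero.

    Cohorts where the middle half of samples all share one FCO value
    (typically all zero) carry no usable variation for stage/subtype
    analyses and are screened out. Quartiles use linear interpolation.

    Accepts either a mapping cohort -> values or a DataFrame with
    ``study`` and ``fco_fraction`` columns. Returns a table with columns
    ``study, n, iqr, included`` sorted by study name.
    """
    if isinstance(fco_by_cohort, pd.DataFrame):
        groups = {
            study: sub["fco_fraction"].dropna().to_numpy()
            for study, sub in fco_by_cohort.groupby("study")
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in fco_by_cohort.items()}
    rows = []
    for study in sorted(groups):
        vals = groups[study]
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        iqr = float(q3 - q1)
        rows.append({"study": study, "n": len(vals), "iqr": iqr,
                     "included": iqr > 0})
    return pd.DataFrame(rows)


def extract_probe_betas(
    betas: pd.DataFrame,
    probe_ids: Sequence[str],
    sheet: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Long-format betas for selected probes (e.g. the EZH2-associated CpGs).

    Returns a tidy table with columns ``probe, sample, group, beta``
    (group empty when no sheet is given) plus a list of warnings for
    requested probes absent from the matrix (absence is not fatal).
    """
    warnings = [
        f"probe {p!r} not present in beta matrix"
        for p in probe_ids if p not in betas.index
    ]
    present = [p for p in probe_ids if p in betas.index]
    if not present:
        long = pd.DataFrame(columns=["probe", "sample", "group", "beta"])
        return long, warnings
    sub = betas.loc[present]
    long = (
        sub.reset_index(names="probe")
        .melt(id_vars="probe", var_name="sample", value_name="beta")
    )
    if sheet is not None and "group" in sheet.columns:
        long["group"] = long["sample"].map(sheet["group"]).fillna("")
    else:
        long["group"] = ""
    return long[["probe", "sample", "group", "beta"]], warnings
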