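"""Tumor vs nontumor comparison of estimated FCO fractions.

Three complementary procedures are applied per cohort:

1. a Wilcoxon rank-sum test on the raw FCO values (exact enumeration for
   tiny untied samples, otherwise normal approximation with tie and
   continuity corrections);
2. an ordinary least-squares model of FCO on tumor/nontumor status with
   adjustment for available covariates (age, gender, race, vital status by
   default), complete-case, with the group coefficient expressed as tumor
   minus nontumor;
3. a randomization-based test: the group labels are permuted uniformly at
   random (covariates stay attached to their samples), the adjusted model is
   refit B times (default 50,000) and the two-sided empirical p-value is the
   fraction of null |t| statistics at least as large as the observed |t|.
   With zero exceedances the p-value is reported at the floor 1/B and
   rendered "<1/B" (e.g. "<2E-05" at B = 50,000).

Cohorts with fewer than 3 samples in either group, or with no variation in
FCO at all (e.g. uniformly zero fractions in both groups), yield NA results
rather than errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FcomixError

DEFAULT_COVARIATES = ("age", "gender", "race", "vital_status")

#: Covariates missing in more than this fraction of samples are dropped.
MISSINGNESS_THRESHOLD = 0.5

#: Pooled sample size at or below which the rank-sum null is enumerated
#: exactly (untied data only).
EXACT_RANKSUM_MAX_N = 10

#: Default permutation count for the randomization-based test.
DEFAULT_PERMUTATIONS = 50_000

_PERM_CHUNK = 5_000


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates requested for adjustment and those actually usable."""

    requested: tuple[str, ...]
    used: tuple[str, ...]
    dropped_reasons: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class LinearModelResult:
    """Adjusted OLS fit of FCO on group status."""

    coef: float           # tumor minus nontumor, FCO-fraction units
    t: float
    p: float
    n: int
    n_tumor: int
    n_nontumor: int
    df_resid: int
    params: pd.Series
    fitted: np.ndarray
    resid: np.ndarray
    hat_diag: np.ndarray
    sigma2: float         # residual mean square


@dataclass(frozen=True)
class PermutationResult:
    p: float
    floor: bool           # True when zero null exceedances (p reported as 1/B)
    B: int
    seed: int
    t_obs: float


@dataclass(frozen=True)
class ComparisonResult:
    """Per-cohort three-way comparison summary.

    ``na_reason`` is None for a complete result, otherwise "small_group"
    (fewer than 3 samples in a group) or "degenerate_variance" (no FCO
    variation to test, e.g. all-zero fractions in both groups).
    """

    study: str
    n_tumor: int
    n_nontumor: int
    wilcoxon_p: float | None
    lm_coef: float | None
    lm_t: float | None
    lm_p: float | None
    perm_p: float | None
    perm_floor: bool
    B: int
    seed: int
    covariates: CovariateSpec | None = None
    na_reason: str | None = None
    mean_fco_tumor: float | None = None
    mean_fco_nontumor: float | None = None


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of the first group (midranks
    for ties). For pooled n <= 10 with no ties the null is enumerated
    exactly over all C(m+n, m) group assignments; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise FcomixError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())
    m, n = x.size, y.size
    no_ties = np.unique(pooled).size == pooled.size
    if m + n <= EXACT_RANKSUM_MAX_N and no_ties:
        # Exact: the null rank-sum distribution over all rank assignments.
        mu = m * (m + n + 1) / 2.0
        dev = abs(w_obs - mu)
        total = comb(m + n, m)
        hits = sum(
            1
            for idx in combinations(range(1, m + n + 1), m)
            if abs(sum(idx) - mu) >= dev - 1e-9
        )
        return w_obs, hits / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w_obs, float(res.pvalue)


# ---------------------------------------------------------------------------
# Covariate screening and design construction
# ---------------------------------------------------------------------------

def screen_covariates(
    sheet: pd.DataFrame,
    requested: Sequence[str] = DEFAULT_COVARIATES,
    max_missing: float = MISSINGNESS_THRESHOLD,
) -> CovariateSpec:
    """Decide which requested covariates can be adjusted for.

    A covariate is dropped when it is absent from the sheet, when its
    missingness fraction exceeds ``max_missing``, or when it has a single
    unique non-missing level (e.g. gender in an all-female cohort), with
    the reason recorded.
    """
    used: list[str] = []
    reasons: dict[str, str] = {}
    for name in requested:
        if name not in sheet.columns:
            reasons[name] = "absent"
            continue
        col = sheet[name]
        col = col.replace("", np.nan) if col.dtype == object else col
        frac_missing = col.isna().mean() if len(col) else 1.0
        if frac_missing > max_missing:
            reasons[name] = "missingness"
            continue
        if col.dropna().nunique() <= 1:
            reasons[name] = "single level"
            continue
        used.append(name)
    return CovariateSpec(tuple(requested), tuple(used), reasons)


def _numeric_group(group: pd.Series) -> pd.Series:
    levels = set(group.dropna().unique())
    if not levels <= {"tumor", "nontumor"}:
        raise FcomixError(
            f"group labels must be 'tumor'/'nontumor', got {sorted(levels)}"
        )
    return group.map({"nontumor": 0.0, "tumor": 1.0})


def build_design(
    fco: pd.Series,
    group: pd.Series,
    sheet: pd.DataFrame,
    spec: CovariateSpec,
) -> tuple[pd.Series, pd.DataFrame]:
    """Complete-case response and design matrix for the adjusted model.

    Columns: ``const``, dummy-coded categorical covariates (reference =
    first level in sorted order), numeric covariates, and ``group`` coded
    0 = nontumor, 1 = tumor (last column).
    """
    df = pd.DataFrame({"fco": fco, "group": _numeric_group(group)})
    for name in spec.used:
        col = sheet[name].reindex(fco.index)
        if col.dtype == object:
            col = col.replace("", np.nan)
        df[name] = col
    df = df.dropna()
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for name in spec.used:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            X[name] = col.astype(float)
        else:
            levels = sorted(col.unique())
            for lev in levels[1:]:
                X[f"{name}[{lev}]"] = (col == lev).astype(float)
    X["group"] = df["group"]
    return df["fco"], X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        full = rank
        suspects = [
            col for col in X.columns
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == full
        ]
        raise FcomixError(
            f"design matrix rank-deficient; collinear columns: {suspects}"
        )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """OLS fit returning (beta, fitted, resid, sigma2)."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    df_resid = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else np.nan
    return beta, fitted, resid, sigma2


def adjusted_linear_model(
    fco: pd.Series,
    group: pd.Series,
    sheet: pd.DataFrame,
    spec: CovariateSpec,
) -> LinearModelResult:
    """OLS of FCO on tumor/nontumor status adjusted for screened covariates.

    Complete-case rows only; the group coefficient (tumor minus nontumor,
    FCO-fraction units) is tested with a t-statistic on n - p residual
    degrees of freedom.
    """
    y, X = build_design(fco, group, sheet, spec)
    g = X["group"]
    n_tum = int((g == 1).sum())
    n_non = int((g == 0).sum())
    if min(n_tum, n_non) < 2:
        raise FcomixError(
            f"need >= 2 complete-case samples per group, got {n_tum}/{n_non}"
        )
    _check_rank(X)
    beta, fitted, resid, sigma2 = _ols(y.to_numpy(), X.to_numpy())
    df_resid = len(y) - X.shape[1]
    XtX_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    j = X.columns.get_loc("group")
    tval = beta[j] / se[j]
    pval = 2 * stats.t.sf(abs(tval), df_resid)
    Q, _ = np.linalg.qr(X.to_numpy())
    hat = np.sum(Q**2, axis=1)
    return LinearModelResult(
        coef=float(beta[j]),
        t=float(tval),
        p=float(pval),
        n=len(y),
        n_tumor=n_tum,
        n_nontumor=n_non,
        df_resid=df_resid,
        params=pd.Series(beta, index=X.columns),
        fitted=fitted,
        resid=resid,
        hat_diag=hat,
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# Randomization-based test
# ---------------------------------------------------------------------------

def _permutation_t_stats(
    y: np.ndarray, Z: np.ndarray, G: np.ndarray
) -> np.ndarray:
    """t-statistics of the group coefficient for each permuted label column.

    ``Z`` is the nuisance design (intercept + covariates), ``G`` holds one
    permuted 0/1 group vector per column. Uses the
    partialled-out (Frisch–Waugh) form so each permutation costs O(n·p).
    """
    Q, _ = np.linalg.qr(Z)
    y_t = y - Q @ (Q.T @ y)
    G_t = G - Q @ (Q.T @ G)
    den = np.einsum("ij,ij->j", G_t, G_t)
    num = G_t.T @ y_t
    df = len(y) - Z.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = num / den
        rss = np.maximum(float(y_t @ y_t) - coef * num, 0.0)
        sigma2 = rss / df
        t = coef / np.sqrt(sigma2 / den)
        # A perfect permuted fit has an unbounded t-statistic.
        exact = (rss == 0.0) & (den > 0)
        t[exact] = np.inf * np.sign(coef[exact])
    # A permuted label vector lying in the covariate span carries no
    # information on the group effect; score it as t = 0.
    t[~np.isfinite(t) & ~np.isinf(t)] = 0.0
    return t


def randomization_test(
    fco: pd.Series,
    group: pd.Series,
    sheet: pd.DataFrame,
    spec: CovariateSpec,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    method: str = "sample",
) -> PermutationResult:
    """Permutation null for the adjusted group t-statistic.

    Group labels are permuted uniformly at random B times (covariates stay
    attached to samples), the adjusted OLS model is refit and the group
    t-statistic recorded; the empirical two-sided p is
    #{|t*_b| >= |t_obs|} / B. Zero exceedances are reported at the floor
    1/B with ``floor=True`` (rendered "<1/B"). Identical (data, B, seed)
    gives identical results.

    With ``method="exhaustive"`` every distinct assignment of the group
    labels (all C(n, n_tumor) of them) is enumerated once instead of
    sampling, giving the exact permutation p; feasible for small cohorts
    only (the count must not exceed B).
    """
    if B < 1:
        raise FcomixError(f"permutation count must be >= 1, got {B}")
    if method not in ("sample", "exhaustive"):
        raise FcomixError(f"unknown permutation method {method!r}")
    obs = adjusted_linear_model(fco, group, sheet, spec)
    y, X = build_design(fco, group, sheet, spec)
    yv = y.to_numpy()
    Z = X.drop(columns="group").to_numpy()
    g = X["group"].to_numpy()
    n = len(g)
    k = int(g.sum())
    if method == "exhaustive":
        total = comb(n, k)
        if total > B:
            raise FcomixError(
                f"exhaustive enumeration needs B >= C({n},{k}) = {total}"
            )
        G = np.zeros((n, total))
        for b, idx in enumerate(combinations(range(n), k)):
            G[list(idx), b] = 1.0
        t_null = _permutation_t_stats(yv, Z, G)
        count = int(np.sum(np.abs(t_null) >= abs(obs.t) - 1e-12))
        return PermutationResult(p=count / total, floor=False, B=total,
                                 seed=seed, t_obs=obs.t)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < B:
        b = min(_PERM_CHUNK, B - done)
        G = rng.permuted(np.tile(g, (b, 1)), axis=1).T
        t_null = _permutation_t_stats(yv, Z, G)
        count += int(np.sum(np.abs(t_null) >= abs(obs.t) - 1e-12))
        done += b
    if count == 0:
        return PermutationResult(p=1.0 / B, floor=True, B=B, seed=seed, t_obs=obs.t)
    return PermutationResult(p=count / B, floor=False, B=B, seed=seed, t_obs=obs.t)


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(model: LinearModelResult) -> pd.DataFrame:
    """Quantities for normal-QQ and spread-location plots.

    Standardized residuals are internally studentized,
    e_i / (s * sqrt(1 - h_ii)); theoretical normal quantiles use the
    (i - 0.5)/n plotting convention on the sorted residuals. An exact-fit
    model yields all-zero standardized residuals.
    """
    n = len(model.resid)
    s = np.sqrt(model.sigma2)
    scale = max(1.0, float(np.abs(model.fitted).max(initial=0.0)))
    denom = s * np.sqrt(np.clip(1.0 - model.hat_diag, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        std = model.resid / denom
    std[~np.isfinite(std)] = 0.0
    # an exact fit leaves only floating-point dust in the residuals
    if not np.isfinite(s) or s <= 1e-10 * scale:
        std = np.zeros(n)
    order = np.argsort(np.argsort(std, kind="stable"), kind="stable")
    theo = stats.norm.ppf((order + 0.5) / n)
    return pd.DataFrame(
        {
            "fitted": model.fitted,
            "std_resid": std,
            "theoretical_quantile": theo,
            "sqrt_abs_std_resid": np.sqrt(np.abs(std)),
        }
    )


# ---------------------------------------------------------------------------
# Per-cohort orchestration and rendering
# ---------------------------------------------------------------------------

def compare_groups(
    fco: pd.Series,
    sheet: pd.DataFrame,
    requested: Sequence[str] = DEFAULT_COVARIATES,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    study: str = "",
) -> ComparisonResult:
    """Run all three tumor-vs-nontumor tests on one cohort.

    ``fco`` is indexed by sample ID; ``sheet`` supplies the ``group``
    column and covariates. Returns NA results (with a reason) for cohorts
    with fewer than 3 samples in either group or with no FCO variation.
    """
    group = sheet["group"].reindex(fco.index)
    ok = fco.notna() & group.notna()
    fco, group = fco[ok], group[ok]
    gnum = _numeric_group(group)
    n_tum = int((gnum == 1).sum())
    n_non = int((gnum == 0).sum())
    mean_t = float(fco[gnum == 1].mean()) if n_tum else None
    mean_n = float(fco[gnum == 0].mean()) if n_non else None
    base = dict(
        study=study, n_tumor=n_tum, n_nontumor=n_non, B=B, seed=seed,
        mean_fco_tumor=mean_t, mean_fco_nontumor=mean_n,
        wilcoxon_p=None, lm_coef=None, lm_t=None, lm_p=None,
        perm_p=None, perm_floor=False,
    )
    if min(n_tum, n_non) < 3:
        return ComparisonResult(**base, na_reason="small_group")
    if float(np.var(fco.to_numpy())) == 0.0:
        return ComparisonResult(**base, na_reason="degenerate_variance")
    spec = screen_covariates(sheet.loc[fco.index], requested)
    _, wilcoxon_p = rank_sum_test(fco[gnum == 1], fco[gnum == 0])
    lm = adjusted_linear_model(fco, group, sheet, spec)
    perm = randomization_test(fco, group, sheet, spec, B=B, seed=seed)
    base.update(
        wilcoxon_p=wilcoxon_p, lm_coef=lm.coef, lm_t=lm.t, lm_p=lm.p,
        perm_p=perm.p, perm_floor=perm.floor, covariates=spec,
    )
    return ComparisonResult(**base)


def format_pvalue(p: float | None, floor: bool = False, B: int | None = None) -> str:
    """Render a p-value with 3 significant digits; floored permutation
    p-values render as "<1/B" (e.g. "<2E-05" at B = 50,000)."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "NA"
    if floor and B:
        return f"<{1.0 / B:.0E}"
    return f"{p:.3G}"


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tab-separable per-cohort summary with rendered p-values."""
    rows = []
    for r in results:
        rows.append(
            {
                "study": r.study,
                "n_tumor": r.n_tumor,
                "n_nontumor": r.n_nontumor,
                "mean_fco_tumor": r.mean_fco_tumor,
                "mean_fco_nontumor": r.mean_fco_nontumor,
                "lm_coef": r.lm_coef,
                "wilcoxon_p": format_pvalue(r.wilcoxon_p),
                "lm_p": format_pvalue(r.lm_p),
                "perm_p": format_pvalue(r.perm_p, r.perm_floor, r.B),
            }
        )
    return pd.DataFrame(rows)
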