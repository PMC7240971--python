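"""Hierarchical association analyses for metabolite panels.

Repeated visits make observations within a subject dependent, so every
association test is a Gaussian random-intercept (subject-level) model
estimated by REML, with Wald p-values and standardized coefficients.
Families of tests are adjusted with the Benjamini-Yekutieli step-up
procedure, which controls the false discovery rate under arbitrary
dependence; significance is always judged on adjusted p-values at 5%.

Analyses provided: per-age-interval SDS trends (metabolite levels are only
locally linear in age), BMI-SDS associations with a sex-interaction gate,
Tanner-stage contrasts against the pre-pubertal reference stage, and
metabolite x laboratory-marker "correlation" matrices whose cells are
standardized mixed-model coefficients, with agglomerative clustering of the
metabolite correlation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MixedModelFit",
    "AssociationResult",
    "CorrelationMatrix",
    "ALPHA",
    "fit_random_intercept",
    "by_adjust",
    "interval_trends",
    "bmi_association",
    "tanner_contrasts",
    "lab_correlations",
    "cluster_correlation_profiles",
    "DEFAULT_AGE_CUTS",
]

ALPHA = 0.05  # nominal significance level on adjusted p-values

# interval boundaries (years) within which SDS trends are treated as linear
DEFAULT_AGE_CUTS = (1.0, 5.0, 9.0, 13.0)


@dataclass
class MixedModelFit:
    """Result of a Gaussian random-intercept fit.

    Coefficients are standardized: the response and all continuous columns
    of the design are z-scaled before fitting, so slopes are per-SD.
    """

    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    re_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    method: str  # "mixed" | "ols"
    warning: str | None = None


@dataclass
class AssociationResult:
    metabolite: str
    covariate: str
    stratum: str  # "F" | "M" | "pooled"
    estimate: float
    se: float
    p_raw: float
    p_adj: float = np.nan
    significant: bool = False
    estimable: bool = True
    n_obs: int = 0
    note: str = ""


@dataclass
class CorrelationMatrix:
    """Metabolites x markers standardized-coefficient matrix."""

    estimates: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    mode: str  # "absolute" | "sds"
    cluster_labels: pd.Series | None = None
    missing_markers: list = field(default_factory=list)


def _is_continuous(col: np.ndarray) -> bool:
    return np.unique(col[np.isfinite(col)]).size > 2


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    return (v - np.mean(v)) / sd


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # pivoted QR exposes which columns fail to add rank
        _, r, piv = sla.qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _reml_profile(y, exog, gidx, n_groups):
    """Profiled REML pieces for the single-random-intercept model.

    With V = sigma_e^2 * H(lam), H block-diagonal with blocks I + lam*J,
    everything reduces to group sums: X'H^-1X = X'X - sum_i w_i s_i s_i'
    with w_i = lam/(1 + lam*n_i), s_i the within-group column sums.
    Returns a closure evaluating the REML deviance (up to a constant) and
    the GLS quantities at a given variance ratio lam.
    """
    n, p = exog.shape
    xtx = exog.T @ exog
    xty = exog.T @ y
    yty = float(y @ y)
    ni = np.bincount(gidx, minlength=n_groups).astype(float)
    sx = np.zeros((n_groups, p))
    np.add.at(sx, gidx, exog)
    sy = np.bincount(gidx, weights=y, minlength=n_groups)

    def pieces(lam):
        w = lam / (1.0 + lam * ni)
        xhx = xtx - (sx * w[:, None]).T @ sx
        xhy = xty - sx.T @ (w * sy)
        yhy = yty - float(w @ (sy * sy))
        beta = np.linalg.solve(xhx, xhy)
        rss = yhy - float(beta @ xhy)  # r' H^-1 r at the GLS solution
        sigma_e2 = max(rss / (n - p), 1e-300)
        sign, logdet_xhx = np.linalg.slogdet(xhx)
        dev = (
            (n - p) * np.log(sigma_e2)
            + float(np.sum(np.log1p(lam * ni)))
            + logdet_xhx
        )
        return dev, beta, sigma_e2, xhx

    return pieces


def fit_random_intercept(y, X: pd.DataFrame, groups, standardize: bool = True) -> MixedModelFit:
    """Gaussian random-intercept model estimated by REML, with Wald p-values.

    The variance ratio lam = sigma_u^2/sigma_e^2 is found by scalar
    minimization of the profiled REML deviance (the other parameters have
    closed forms given lam), which is exact for this one-random-effect
    model and fast enough for simulation studies.  ``X`` must not contain
    an intercept column (one is added).  With a single group the model
    degenerates to ordinary least squares, returned with a warning flag;
    a numerically perfect fit likewise falls back to OLS, since the
    variance decomposition is then unidentifiable.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).copy()
    groups = np.asarray(groups)
    if y.size != len(X) or y.size != groups.size:
        raise ValueError("y, X and groups must have equal length")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if standardize:
        for j in range(Xv.shape[1]):
            col = Xv[:, j]
            if _is_continuous(col) and np.std(col, ddof=1) > 0:
                Xv[:, j] = _standardize(col)
        if np.std(y, ddof=1) > 0:
            y = _standardize(y)
    exog = np.column_stack([np.ones(y.size), Xv])
    _check_rank(exog, ["Intercept"] + names)
    n, p = exog.shape
    _, gidx = np.unique(groups, return_inverse=True)
    n_groups = int(gidx.max()) + 1

    def _wald(beta, cov, method, warning, re_var, resid_var):
        se = np.sqrt(np.diag(cov))
        zstat = beta / se
        pv = 2.0 * stats.norm.sf(np.abs(zstat))
        return MixedModelFit(
            coefficients=pd.Series(beta[1:], index=names),
            se=pd.Series(se[1:], index=names),
            pvalues=pd.Series(pv[1:], index=names),
            re_var=re_var,
            resid_var=resid_var,
            n_obs=int(n),
            n_groups=n_groups,
            method=method,
            warning=warning,
        )

    def _ols(warning):
        beta, _, _, _ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ beta
        dof = max(n - p, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(exog.T @ exog)
        # t-based p-values in the OLS fallback
        se = np.sqrt(np.diag(cov))
        tstat = beta / se
        pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
        return MixedModelFit(
            coefficients=pd.Series(beta[1:], index=names),
            se=pd.Series(se[1:], index=names),
            pvalues=pd.Series(pv[1:], index=names),
            re_var=0.0,
            resid_var=s2,
            n_obs=int(n),
            n_groups=n_groups,
            method="ols",
            warning=warning,
        )

    if n_groups < 2:
        return _ols("single group: fell back to ordinary regression")
    beta0, _, _, _ = np.linalg.lstsq(exog, y, rcond=None)
    ssr0 = float(np.sum((y - exog @ beta0) ** 2))
    if ssr0 < 1e-10 * max(1.0, float(y @ y)):
        return _ols("perfect fit: variance components unidentifiable")

    pieces = _reml_profile(y, exog, gidx, n_groups)
    # minimize over log-lam to cover [~0, 1e6] smoothly; boundary lam=0 checked
    res = optimize.minimize_scalar(
        lambda t: pieces(np.exp(t))[0], bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    if pieces(0.0)[0] <= res.fun:
        lam = 0.0
    dev, beta, sigma_e2, xhx = pieces(lam)
    cov = sigma_e2 * np.linalg.inv(xhx)
    return _wald(
        beta, cov, "mixed", None,
        re_var=lam * sigma_e2, resid_var=sigma_e2,
    )


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment.

    p_adj(i) = min_{j >= i} min(1, m * c(m) * p_(j) / j) with
    c(m) = sum_{h=1..m} 1/h; order-preserving and capped at one, valid
    under arbitrary dependence between the tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _adjust_results(results: list[AssociationResult], alpha: float = ALPHA) -> None:
    """BY-adjust one family of results in place (not-estimable rows skipped)."""
    idx = [i for i, r in enumerate(results) if r.estimable and np.isfinite(r.p_raw)]
    if not idx:
        return
    adj = by_adjust([results[i].p_raw for i in idx])
    for i, a in zip(idx, adj):
        results[i].p_adj = float(a)
        results[i].significant = bool(a < alpha)


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _require_sex(df: pd.DataFrame, sex_col: str) -> None:
    vals = df[sex_col]
    if vals.isna().any() or not set(vals.dropna().unique()) <= {"F", "M"}:
        raise ValueError("sex codes must be 'F'/'M' with no missing values")


# ---------------------------------------------------------------------------
# analyses


def interval_trends(
    df: pd.DataFrame,
    value_cols,
    cuts=DEFAULT_AGE_CUTS,
    age_col: str = "age_years",
    sex_col: str = "sex",
    subject_col: str = "subject_id",
    age_range=(0.25, 18.0),
    min_obs: int = 30,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-age-interval, per-sex SDS-on-age slopes with subject random intercepts.

    ``cuts`` partition [lo, hi] into half-open intervals [a, b); an age
    exactly at a cut belongs to the right-hand interval (the final interval
    is closed at the upper end).  Intervals with fewer than ``min_obs``
    usable observations are reported not-estimable rather than dropped.
    One BY family per call, spanning all metabolites, sexes and intervals.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    _require_sex(df, sex_col)
    cuts = sorted(float(c) for c in cuts)
    lo, hi = age_range
    if cuts and (cuts[0] <= lo or cuts[-1] >= hi):
        raise ValueError("interval cuts must lie strictly inside the age range")
    edges = [lo] + cuts + [hi]
    age = df[age_col].to_numpy(dtype=float)
    bin_idx = np.searchsorted(np.asarray(cuts), age, side="right")
    results: list[AssociationResult] = []
    for col in value_cols:
        for sx in ("F", "M"):
            for b in range(len(edges) - 1):
                label = f"age[{edges[b]},{edges[b + 1]})"
                m = (bin_idx == b) & (df[sex_col] == sx).to_numpy()
                sub = df.loc[m, [col, age_col, subject_col]].dropna()
                r = AssociationResult(
                    metabolite=col, covariate=label, stratum=sx,
                    estimate=np.nan, se=np.nan, p_raw=np.nan,
                    estimable=False, n_obs=len(sub),
                )
                if len(sub) >= min_obs and sub[age_col].nunique() > 2:
                    fit = fit_random_intercept(
                        sub[col], sub[[age_col]], sub[subject_col]
                    )
                    r.estimate = float(fit.coefficients.iloc[0])
                    r.se = float(fit.se.iloc[0])
                    r.p_raw = float(np.clip(fit.pvalues.iloc[0], 1e-300, 1.0))
                    r.estimable = True
                else:
                    r.note = f"not estimable: n={len(sub)} < {min_obs}"
                results.append(r)
    _adjust_results(results, alpha)
    return results_frame(results)


def bmi_association(
    df: pd.DataFrame,
    value_cols,
    bmi_col: str = "bmi_sds",
    sex_col: str = "sex",
    subject_col: str = "subject_id",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Metabolite-SDS vs BMI-SDS with a sex-interaction gate.

    For each metabolite fits ``sds ~ bmi + sex + bmi x sex`` with a subject
    random intercept; interaction p-values are BY-adjusted across the
    metabolite family.  Where the adjusted interaction is significant the
    association is re-estimated and reported per sex, otherwise a single
    pooled estimate (sex-adjusted) is reported.  The reported slopes form
    one BY family.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    _require_sex(df, sex_col)
    inter_p = {}
    for col in value_cols:
        sub = df[[col, bmi_col, sex_col, subject_col]].dropna()
        male = (sub[sex_col] == "M").astype(float)
        X = pd.DataFrame(
            {
                bmi_col: sub[bmi_col].to_numpy(dtype=float),
                "sex_M": male.to_numpy(),
                f"{bmi_col}:sex_M": sub[bmi_col].to_numpy(dtype=float) * male.to_numpy(),
            }
        )
        fit = fit_random_intercept(sub[col], X, sub[subject_col])
        inter_p[col] = float(np.clip(fit.pvalues[f"{bmi_col}:sex_M"], 1e-300, 1.0))
    inter_adj = dict(zip(inter_p, by_adjust(list(inter_p.values()))))

    results: list[AssociationResult] = []
    for col in value_cols:
        sub = df[[col, bmi_col, sex_col, subject_col]].dropna()
        if inter_adj[col] < alpha:
            for sx in ("F", "M"):
                s = sub[sub[sex_col] == sx]
                fit = fit_random_intercept(s[col], s[[bmi_col]], s[subject_col])
                results.append(
                    AssociationResult(
                        metabolite=col, covariate=bmi_col, stratum=sx,
                        estimate=float(fit.coefficients[bmi_col]),
                        se=float(fit.se[bmi_col]),
                        p_raw=float(np.clip(fit.pvalues[bmi_col], 1e-300, 1.0)),
                        n_obs=fit.n_obs,
                        note=f"sex interaction p_adj={inter_adj[col]:.3g}",
                    )
                )
        else:
            male = (sub[sex_col] == "M").astype(float)
            X = pd.DataFrame(
                {bmi_col: sub[bmi_col].to_numpy(dtype=float), "sex_M": male.to_numpy()}
            )
            fit = fit_random_intercept(sub[col], X, sub[subject_col])
            results.append(
                AssociationResult(
                    metabolite=col, covariate=bmi_col, stratum="pooled",
                    estimate=float(fit.coefficients[bmi_col]),
                    se=float(fit.se[bmi_col]),
                    p_raw=float(np.clip(fit.pvalues[bmi_col], 1e-300, 1.0)),
                    n_obs=fit.n_obs,
                    note=f"sex interaction p_adj={inter_adj[col]:.3g}",
                )
            )
    _adjust_results(results, alpha)
    return results_frame(results)


def tanner_contrasts(
    df: pd.DataFrame,
    value_cols,
    stage_col: str = "tanner_stage",
    sex_col: str = "sex",
    subject_col: str = "subject_id",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Stage 2-5 vs stage 1 contrasts, stratified by sex.

    Tanner stage enters as a categorical factor with the pre-pubertal stage
    1 as reference, one random-intercept model per sex; the four contrasts
    per metabolite and sex form a single BY family across the call.  Stages
    with zero observations are reported not-estimable.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    _require_sex(df, sex_col)
    results: list[AssociationResult] = []
    for col in value_cols:
        for sx in ("F", "M"):
            sub = df[df[sex_col] == sx][[col, stage_col, subject_col]].dropna()
            stages = sub[stage_col].astype(int)
            if not stages.isin([1, 2, 3, 4, 5]).all():
                raise ValueError("Tanner stages must be coded 1-5")
            present = sorted(stages.unique())
            dummies = {
                f"tanner_{k}": (stages == k).astype(float).to_numpy()
                for k in (2, 3, 4, 5)
                if k in present
            }
            fit = None
            if dummies and 1 in present:
                fit = fit_random_intercept(
                    sub[col], pd.DataFrame(dummies, index=sub.index), sub[subject_col]
                )
            for k in (2, 3, 4, 5):
                name = f"tanner_{k}"
                r = AssociationResult(
                    metabolite=col, covariate=name, stratum=sx,
                    estimate=np.nan, se=np.nan, p_raw=np.nan, estimable=False,
                    n_obs=int((stages == k).sum()),
                )
                if fit is not None and name in dummies:
                    r.estimate = float(fit.coefficients[name])
                    r.se = float(fit.se[name])
                    r.p_raw = float(np.clip(fit.pvalues[name], 1e-300, 1.0))
                    r.estimable = True
                else:
                    r.note = "not estimable: stage unobserved"
                results.append(r)
    _adjust_results(results, alpha)
    return results_frame(results)


def lab_correlations(
    metab: pd.DataFrame,
    markers: pd.DataFrame,
    groups,
    mode: str = "absolute",
    alpha: float = ALPHA,
) -> CorrelationMatrix:
    """Metabolite x marker association matrix from random-intercept models.

    Each cell is the standardized coefficient of one marker regressed on by
    one metabolite (both z-scaled), which plays the role of a correlation
    while accounting for repeated measurements per subject; cells are
    clipped to [-1, 1].  ``mode`` records whether inputs are absolute
    concentrations or SDS (age/sex-adjusted) values.  One BY family per
    matrix.  Zero-variance markers are reported missing.
    """
    if mode not in ("absolute", "sds"):
        raise ValueError("mode must be 'absolute' or 'sds'")
    if len(metab) != len(markers):
        raise ValueError("metabolite and marker tables must have matching rows")
    groups = np.asarray(groups)
    mets = list(metab.columns)
    mks = list(markers.columns)
    est = pd.DataFrame(np.nan, index=mets, columns=mks)
    praw = pd.DataFrame(np.nan, index=mets, columns=mks)
    missing = []
    for mk in mks:
        x = markers[mk].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if np.std(x[ok], ddof=1) == 0 or ok.sum() < 3:
            missing.append(mk)
            continue
        for met in mets:
            y = metab[met].to_numpy(dtype=float)
            use = ok & np.isfinite(y)
            fit = fit_random_intercept(
                y[use], pd.DataFrame({mk: x[use]}), groups[use]
            )
            est.loc[met, mk] = float(np.clip(fit.coefficients[mk], -1.0, 1.0))
            praw.loc[met, mk] = float(np.clip(fit.pvalues[mk], 1e-300, 1.0))
    padj = praw.copy()
    flat = praw.to_numpy().ravel()
    good = np.isfinite(flat)
    if good.any():
        adj = np.full(flat.size, np.nan)
        adj[good] = by_adjust(flat[good])
        padj = pd.DataFrame(adj.reshape(praw.shape), index=mets, columns=mks)
    return CorrelationMatrix(
        estimates=est, p_raw=praw, p_adj=padj, mode=mode, missing_markers=missing
    )


def cluster_correlation_profiles(matrix: CorrelationMatrix, k: int = 5) -> pd.Series:
    """Agglomerative clustering (Euclidean, average linkage) of metabolite rows.

    Groups metabolites whose marker-correlation signatures are similar.
    Labels are canonicalized by first occurrence in row order, so the
    partition is invariant (up to renaming) under row permutation.
    """
    rows = matrix.estimates.drop(columns=matrix.missing_markers, errors="ignore")
    n = len(rows)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    data = rows.to_numpy(dtype=float)
    data = np.nan_to_num(data, nan=0.0)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage="average")
        labels = model.fit_predict(data)
    remap = {}
    canon = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        canon[i] = remap[lab]
    out = pd.Series(canon, index=rows.index, name="cluster")
    matrix.cluster_labels = out
    return out
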