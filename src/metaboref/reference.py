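"""Age- and sex-dependent LMS reference curves.

Each distribution parameter (L, M, S and, for BCT, a constant tau) is a
smooth function of age represented on a B-spline basis over a square-root
transformed age axis — the sqrt transform gives infancy, where metabolite
levels change fastest, more resolution per basis function.  Links: identity
for L, log for M, S and tau, so positivity of M and S is structural.

Fitting maximizes the full log-likelihood of the Box-Cox family over all
spline coefficients jointly; smoothness is controlled by the basis dimension
(the degrees of freedom per parameter), and the df combination is chosen by
BIC over a candidate grid.  Cohorts with repeated visits and sibling
clusters violate the iid likelihood; :func:`fit_reference_resampled` breaks
that dependence by refitting on one observation per family per iteration and
aggregating the parameter curves by pointwise median.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

from .distributions import LMSParams, _boxcox_inv, _boxcox_z, _loglik_arrays, t_to_normal_sds

__all__ = [
    "AGE_RANGE",
    "SplineBasis",
    "ParamCurve",
    "LMSCurves",
    "FittedReference",
    "DEFAULT_DF_GRID",
    "PERCENTILE_LEVELS",
    "fit_reference",
    "select_distribution",
    "fit_reference_resampled",
    "percentile_table",
    "sds",
    "residual_diagnostics",
]

AGE_RANGE = (0.25, 18.0)
PERCENTILE_LEVELS = (2.5, 10.0, 50.0, 90.0, 97.5)

# candidate spline dimensions per parameter: richer for the median, leaner
# for skewness and spread which are harder to localize
DEFAULT_DF_GRID = {"L": (1, 2, 3), "M": (2, 3, 4, 5), "S": (1, 2, 3)}


class SplineBasis:
    """B-spline basis of dimension ``df`` on u = sqrt(age).

    ``df == 1`` is the constant basis; for ``df >= 2`` the degree is
    ``min(3, df - 1)`` with equally spaced interior knots, so the basis has
    exactly ``df`` columns and forms a partition of unity.
    """

    def __init__(self, df: int, age_range=AGE_RANGE):
        if df < 1:
            raise ValueError("basis dimension must be >= 1")
        self.df = int(df)
        self.age_range = (float(age_range[0]), float(age_range[1]))
        self.u0 = np.sqrt(self.age_range[0])
        self.u1 = np.sqrt(self.age_range[1])
        if df == 1:
            self.degree = 0
            self.knots = np.array([self.u0, self.u1])
        else:
            k = min(3, df - 1)
            self.degree = k
            interior = np.linspace(self.u0, self.u1, df - k + 1)[1:-1]
            self.knots = np.concatenate(
                [[self.u0] * (k + 1), interior, [self.u1] * (k + 1)]
            )

    def design(self, age) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        u = np.sqrt(np.clip(age, self.age_range[0], self.age_range[1]))
        if self.df == 1:
            return np.ones((u.size, 1))
        # nudge the right endpoint inside the support of the last interval
        u = np.minimum(u, self.u1 - 1e-12)
        return BSpline.design_matrix(u, self.knots, self.degree).toarray()

    def to_dict(self) -> dict:
        return {"df": self.df, "age_range": list(self.age_range)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(d["df"], tuple(d["age_range"]))


@dataclass
class ParamCurve:
    """One distribution parameter as a smooth function of age."""

    basis: SplineBasis
    coef: np.ndarray
    link: str  # "identity" | "log"

    def __call__(self, age) -> np.ndarray:
        eta = self.basis.design(age) @ np.asarray(self.coef, dtype=float)
        return np.exp(eta) if self.link == "log" else eta

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.to_dict(),
            "coef": np.asarray(self.coef, dtype=float).tolist(),
            "link": self.link,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamCurve":
        return cls(SplineBasis.from_dict(d["basis"]), np.asarray(d["coef"]), d["link"])


@dataclass
class LMSCurves:
    """Smooth age-functions of L, M, S (and constant tau for BCT)."""

    family: str  # "BCCG" | "BCT"
    L: ParamCurve
    M: ParamCurve
    S: ParamCurve
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("BCCG", "BCT"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if (self.family == "BCT") != (self.tau is not None):
            raise ValueError("tau must be present exactly for the BCT family")

    @property
    def age_range(self):
        return self.M.basis.age_range

    def params_at(self, age):
        """Evaluate (L, M, S) arrays at the given ages."""
        return self.L(age), self.M(age), self.S(age)

    def at(self, age: float) -> LMSParams:
        L, M, S = self.params_at(age)
        return LMSParams(float(L[0]), float(M[0]), float(S[0]), self.tau)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "L": self.L.to_dict(),
            "M": self.M.to_dict(),
            "S": self.S.to_dict(),
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMSCurves":
        return cls(
            family=d["family"],
            L=ParamCurve.from_dict(d["L"]),
            M=ParamCurve.from_dict(d["M"]),
            S=ParamCurve.from_dict(d["S"]),
            tau=d.get("tau"),
        )


@dataclass
class FittedReference:
    """A fitted reference distribution for one metabolite and sex."""

    metabolite: str
    sex: str
    family: str
    curves: LMSCurves
    df_per_parameter: dict
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    resample_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metabolite": self.metabolite,
            "sex": self.sex,
            "family": self.family,
            "curves": self.curves.to_dict(),
            "df_per_parameter": dict(self.df_per_parameter),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "resample_info": dict(self.resample_info),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedReference":
        d = dict(d)
        d["curves"] = LMSCurves.from_dict(d["curves"])
        return cls(**d)


# ---------------------------------------------------------------------------
# fitting


def _normalize_grid(df_grid) -> list[tuple[int, int, int]]:
    """Accept a per-parameter dict or an explicit list of (dfL, dfM, dfS)."""
    if df_grid is None:
        df_grid = DEFAULT_DF_GRID
    if isinstance(df_grid, dict):
        combos = list(itertools.product(df_grid["L"], df_grid["M"], df_grid["S"]))
    else:
        combos = [tuple(int(v) for v in c) for c in df_grid]
    # visit simpler models first so warm starts grow in complexity
    return sorted(set(combos), key=lambda c: (sum(c), c))


def _theta_split(theta, dfs, bct):
    dL, dM, dS = dfs
    cL = theta[:dL]
    cM = theta[dL : dL + dM]
    cS = theta[dL + dM : dL + dM + dS]
    log_tau = theta[-1] if bct else None
    return cL, cM, cS, log_tau


def _default_init(age, y, bases, bct):
    BL, BM, BS = bases
    order = np.argsort(age)
    w = max(25, len(y) // 20) | 1
    med = (
        pd.Series(np.asarray(y, dtype=float)[order])
        .rolling(w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    cM, *_ = np.linalg.lstsq(BM[order], np.log(med), rcond=None)
    resid = np.log(y) - BM @ cM
    s0 = float(np.clip(np.std(resid), 0.02, 1.0))
    cS = np.full(BS.shape[1], np.log(s0))
    cL = np.ones(BL.shape[1])
    theta = np.concatenate([cL, cM, cS, [np.log(10.0)] if bct else []])
    return theta


def _project_init(curves: LMSCurves, bases, age_grid, bct):
    """Warm start: least-squares projection of existing curves onto new bases."""
    BL, BM, BS = (b for b in bases)
    L, M, S = curves.params_at(age_grid)
    cL, *_ = np.linalg.lstsq(BL, L, rcond=None)
    cM, *_ = np.linalg.lstsq(BM, np.log(M), rcond=None)
    cS, *_ = np.linalg.lstsq(BS, np.log(S), rcond=None)
    tau = curves.tau if curves.tau is not None else 10.0
    return np.concatenate([cL, cM, cS, [np.log(tau)] if bct else []])


def _fit_single(age, y, dfs, family, age_range, init_curves=None):
    """Maximum-likelihood fit at a fixed df combination.

    Returns (curves, loglik, n_params, converged, nll_init, nll_final).
    """
    bct = family == "BCT"
    basisL = SplineBasis(dfs[0], age_range)
    basisM = SplineBasis(dfs[1], age_range)
    basisS = SplineBasis(dfs[2], age_range)
    BL = basisL.design(age)
    BM = basisM.design(age)
    BS = basisS.design(age)
    y = np.asarray(y, dtype=float)

    def nll(theta):
        cL, cM, cS, lt = _theta_split(theta, dfs, bct)
        L = BL @ cL
        M = np.exp(BM @ cM)
        S = np.exp(BS @ cS)
        tau = np.exp(np.clip(lt, np.log(1.0), np.log(1e7))) if bct else None
        ll = _loglik_arrays(y, L, M, S, tau)
        bad = ~np.isfinite(ll)
        if bad.any():
            return -float(ll[~bad].sum()) + 1e6 * int(bad.sum())
        return -float(ll.sum())

    if init_curves is not None:
        grid = np.linspace(age_range[0], age_range[1], 200)
        Bg = (basisL.design(grid), basisM.design(grid), basisS.design(grid))
        theta0 = _project_init(init_curves, Bg, grid, bct)
    else:
        theta0 = _default_init(age, y, (BL, BM, BS), bct)
    nll0 = nll(theta0)

    best = None
    converged = False
    jitter_rng = np.random.default_rng(0)
    start = theta0
    for attempt in range(3):
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", options={"maxiter": 600, "maxfun": 20000}
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun <= nll0 + 1e-8:
            converged = True
            best = res
            break
        start = theta0 + jitter_rng.normal(0.0, 0.05, size=theta0.size)

    cL, cM, cS, lt = _theta_split(best.x, dfs, bct)
    curves = LMSCurves(
        family=family,
        L=ParamCurve(basisL, cL, "identity"),
        M=ParamCurve(basisM, cM, "log"),
        S=ParamCurve(basisS, cS, "log"),
        tau=float(np.exp(lt)) if bct else None,
    )
    n_params = sum(dfs) + (1 if bct else 0)
    return curves, -float(best.fun), n_params, converged, nll0, float(best.fun)


def _validate_obs(age, y, age_range):
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.shape != y.shape:
        raise ValueError("age and value arrays must have equal length")
    if y.size < 50:
        raise ValueError(f"reference fitting requires >= 50 observations, got {y.size}")
    if np.any(y <= 0):
        raise ValueError("all values must be strictly positive; run QC first")
    if np.any((age < age_range[0] - 1e-9) | (age > age_range[1] + 1e-9)):
        raise ValueError(f"ages must lie within {age_range}")
    return age, y


def fit_reference(
    age,
    y,
    family: str = "BCCG",
    df_grid=None,
    age_range=AGE_RANGE,
    metabolite: str = "",
    sex: str = "",
) -> FittedReference:
    """Fit LMS reference curves by maximum likelihood with BIC df selection.

    ``df_grid`` is either a dict of candidate dimensions per parameter
    (default ``DEFAULT_DF_GRID``) or an explicit list of (dfL, dfM, dfS)
    tuples.  The model minimizing BIC among converged fits is returned;
    AIC is reported alongside.  Deterministic given data and settings.
    """
    if family not in ("BCCG", "BCT"):
        raise ValueError(f"unknown distribution family {family!r}")
    age, y = _validate_obs(age, y, age_range)
    combos = _normalize_grid(df_grid)
    n = y.size

    best = None
    warm = None
    for dfs in combos:
        curves, loglik, k, conv, _, _ = _fit_single(
            age, y, dfs, family, age_range, init_curves=warm
        )
        bic = -2.0 * loglik + np.log(n) * k
        aic = -2.0 * loglik + 2.0 * k
        cand = (bic, aic, loglik, k, dfs, curves, conv)
        if conv and (warm is None or loglik > best[2]):
            warm = curves
        if conv and (best is None or not best[6] or bic < best[0]):
            best = cand
        elif best is None:
            best = cand
    bic, aic, loglik, k, dfs, curves, conv = best
    return FittedReference(
        metabolite=metabolite,
        sex=sex,
        family=family,
        curves=curves,
        df_per_parameter={"L": dfs[0], "M": dfs[1], "S": dfs[2], "tau": int(family == "BCT")},
        loglik=loglik,
        aic=aic,
        bic=bic,
        n_obs=int(n),
        converged=bool(conv),
    )


def select_distribution(age, y, df_grid=None, age_range=AGE_RANGE, **kw):
    """Choose BCCG vs BCT by BIC, preferring parsimony on ties.

    The four-parameter BCT is returned only when its BIC is strictly lower
    than the three-parameter BCCG's — the kurtosis parameter has to pay its
    penalty.  Returns ``(family, {"BCCG": fit, "BCT": fit})``.
    """
    fits = {
        fam: fit_reference(age, y, family=fam, df_grid=df_grid, age_range=age_range, **kw)
        for fam in ("BCCG", "BCT")
    }
    bad = [fam for fam, f in fits.items() if not f.converged]
    if bad:
        raise RuntimeError(
            f"distribution selection aborted: non-converged fit(s) for {bad}; "
            f"BICs: { {fam: f.bic for fam, f in fits.items()} }"
        )
    family = "BCT" if fits["BCT"].bic < fits["BCCG"].bic else "BCCG"
    return family, fits


def fit_reference_resampled(
    table: pd.DataFrame,
    metabolite: str,
    sex: str | None = None,
    family: str = "BCCG",
    df_grid=None,
    n_iter: int = 100,
    seed: int = 0,
    age_range=AGE_RANGE,
    age_col: str = "age_years",
    family_col: str = "family_id",
    max_drop_fraction: float = 0.2,
) -> FittedReference:
    """Cluster-aware reference fit: one observation per family per iteration.

    Repeated visits of a subject and sibling pairs make observations within
    a family dependent; sampling a single observation per family restores an
    independent likelihood.  Each of ``n_iter`` iterations fits at the df
    combination selected once on the full data, parameter curves are
    evaluated on a fixed age grid, aggregated by pointwise median, and
    re-smoothed onto the basis.  Non-convergent iterations are dropped and
    counted; more than ``max_drop_fraction`` dropped fails the operation.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sub = table
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    sub = sub[np.isfinite(sub[metabolite].astype(float)) & (sub[metabolite] > 0)]
    if sub.empty:
        raise ValueError(f"no usable observations for {metabolite!r} (sex={sex!r})")
    age_all = sub[age_col].to_numpy(dtype=float)
    y_all = sub[metabolite].to_numpy(dtype=float)

    full = fit_reference(
        age_all, y_all, family=family, df_grid=df_grid, age_range=age_range,
        metabolite=metabolite, sex=sex or "pooled",
    )
    dfs = (
        full.df_per_parameter["L"],
        full.df_per_parameter["M"],
        full.df_per_parameter["S"],
    )

    fam_groups = [idx.to_numpy() for _, idx in sub.groupby(family_col).groups.items()]
    pos = {label: i for i, label in enumerate(sub.index)}
    fam_groups = [np.array([pos[i] for i in g]) for g in fam_groups]

    rng = np.random.default_rng(seed)
    grid = np.linspace(age_range[0], age_range[1], 101)
    L_draws, M_draws, S_draws, tau_draws = [], [], [], []
    dropped = 0
    for _ in range(n_iter):
        pick = np.array([g[rng.integers(len(g))] for g in fam_groups])
        curves, loglik, k, conv, _, _ = _fit_single(
            age_all[pick], y_all[pick], dfs, family, age_range, init_curves=full.curves
        )
        if not conv:
            dropped += 1
            continue
        L, M, S = curves.params_at(grid)
        L_draws.append(L)
        M_draws.append(M)
        S_draws.append(S)
        if curves.tau is not None:
            tau_draws.append(curves.tau)
    if dropped > max_drop_fraction * n_iter:
        raise RuntimeError(
            f"resampled fit failed: {dropped}/{n_iter} iterations non-convergent"
        )

    Lmed = np.median(L_draws, axis=0)
    Mmed = np.median(M_draws, axis=0)
    Smed = np.median(S_draws, axis=0)
    basisL, basisM, basisS = (SplineBasis(d, age_range) for d in dfs)
    cL, *_ = np.linalg.lstsq(basisL.design(grid), Lmed, rcond=None)
    cM, *_ = np.linalg.lstsq(basisM.design(grid), np.log(Mmed), rcond=None)
    cS, *_ = np.linalg.lstsq(basisS.design(grid), np.log(Smed), rcond=None)
    curves = LMSCurves(
        family=family,
        L=ParamCurve(basisL, cL, "identity"),
        M=ParamCurve(basisM, cM, "log"),
        S=ParamCurve(basisS, cS, "log"),
        tau=float(np.median(tau_draws)) if family == "BCT" else None,
    )
    tau_arr = curves.tau
    ll = float(
        _loglik_arrays(y_all, *curves.params_at(age_all), tau_arr).sum()
    )
    k = sum(dfs) + (1 if family == "BCT" else 0)
    return FittedReference(
        metabolite=metabolite,
        sex=sex or "pooled",
        family=family,
        curves=curves,
        df_per_parameter=dict(full.df_per_parameter),
        loglik=ll,
        aic=-2 * ll + 2 * k,
        bic=-2 * ll + np.log(y_all.size) * k,
        n_obs=int(y_all.size),
        converged=True,
        resample_info={"n_iter": n_iter, "n_dropped": dropped, "seed": seed},
    )


# ---------------------------------------------------------------------------
# downstream use of a fitted reference


def percentile_table(
    ref: FittedReference, ages, levels=PERCENTILE_LEVELS
) -> pd.DataFrame:
    """Tabulate fitted percentile curves at the given ages.

    Long format: columns age, sex, metabolite, level (percent), value.
    Entries are exactly ``lms_quantile(level/100, curves(age))``.
    """
    if not ref.converged:
        raise ValueError("percentile_table requires a converged reference")
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 100)):
        raise ValueError("percentile levels must lie strictly inside (0, 100)")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    L, M, S = ref.curves.params_at(ages)
    tau = ref.curves.tau
    rows = []
    for lev in levels:
        z = stats.t.ppf(lev / 100, df=tau) if tau is not None else stats.norm.ppf(lev / 100)
        vals = _boxcox_inv(z, L, M, S)
        rows.append(
            pd.DataFrame(
                {
                    "age": ages,
                    "sex": ref.sex,
                    "metabolite": ref.metabolite,
                    "level": lev,
                    "value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sds(value, age, ref: FittedReference):
    """Age-adjusted standard deviation score of a concentration.

    For BCCG references this is the Cole-Green z directly; for BCT the
    t-referenced z is mapped to a normal-equivalent SDS by the probability
    integral transform, so SDS is N(0,1)-scaled in both families.
    No extrapolation: ages outside the fitted range are rejected.
    """
    if not ref.converged:
        raise ValueError("sds requires a converged reference")
    scalar_in = np.ndim(value) == 0 and np.ndim(age) == 0
    value = np.asarray(value, dtype=float)
    age = np.asarray(age, dtype=float)
    lo, hi = ref.curves.age_range
    if np.any((age < lo - 1e-9) | (age > hi + 1e-9)):
        raise ValueError(f"age outside the fitted range [{lo}, {hi}]; no extrapolation")
    if np.any(value <= 0):
        raise ValueError("sds requires strictly positive concentrations")
    L, M, S = ref.curves.params_at(age)
    z = _boxcox_z(value, L, M, S)
    if ref.curves.tau is not None:
        z = t_to_normal_sds(z, ref.curves.tau)
    z = np.asarray(z)
    return float(z.reshape(())) if scalar_in else z.reshape(np.shape(value) or z.shape)


@dataclass(frozen=True)
class ResidualSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    qq_deviation: float
    reliable: bool


def residual_diagnostics(ref: FittedReference, age, y) -> ResidualSummary:
    """Moments and a QQ deviation statistic of the z-residuals.

    The QQ deviation is the sup over a fixed probability grid of
    |ECDF(z at the theoretical quantile) - p| — a gridded Kolmogorov-Smirnov
    statistic against the standard normal (BCT residuals are mapped to the
    normal scale first).  Summaries on fewer than 20 residuals are flagged
    unreliable.
    """
    z = np.asarray(sds(y, age, ref), dtype=float)
    n = z.size
    pgrid = np.linspace(0.005, 0.995, 199)
    zq = stats.norm.ppf(pgrid)
    emp = (z[:, None] <= zq[None, :]).mean(axis=0)
    qq_dev = float(np.max(np.abs(emp - pgrid)))
    return ResidualSummary(
        n=int(n),
        mean=float(np.mean(z)),
        sd=float(np.std(z, ddof=1)),
        skewness=float(stats.skew(z)),
        excess_kurtosis=float(stats.kurtosis(z)),
        qq_deviation=qq_dev,
        reliable=n >= 20,
    )
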