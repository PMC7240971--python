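"""Box-Cox Cole-Green (BCCG) and Box-Cox t (BCT) distribution machinery.

The LMS method summarizes an age-varying, positively supported distribution
through three curves: L (Box-Cox power, governing skewness), M (median) and
S (coefficient of variation).  An observation ``y`` maps to a z-score via the
Cole-Green transform

    z = ((y/M)**L - 1) / (L*S)        for L != 0
    z = ln(y/M) / S                   for L == 0

Under BCCG the z-score is referred to a standard normal truncated to the
region where the transform is invertible; under BCT it is referred to a
Student t with ``tau`` degrees of freedom, which adds a kurtosis adjustment.
Percentiles follow by inverting the transform at the reference quantile:

    C_alpha = M * (1 + L*S*z_alpha)**(1/L)   (L != 0),   M * exp(S*z_alpha)  (L == 0).

All public functions reject non-positive concentrations: zeros encode
non-detects and must be handled before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LMSParams", "lms_z", "lms_quantile", "lms_logpdf", "t_to_normal_sds"]

# below this magnitude the power branch of the Box-Cox transform loses
# precision to cancellation; switch to the exact L=0 log form
_L_EPS = 1e-5


@dataclass(frozen=True)
class LMSParams:
    """Pointwise LMS distribution parameters at one age.

    Parameters
    ----------
    L : Box-Cox power (dimensionless skewness parameter).
    M : median, in concentration units; must be positive.
    S : coefficient of variation; must be positive.
    tau : Student-t degrees of freedom; present if and only if the
        distribution is BCT.  Must be positive when given.
    """

    L: float
    M: float
    S: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"M must be positive, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"S must be positive, got {self.S}")
        if self.tau is not None and not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    @property
    def is_bct(self) -> bool:
        return self.tau is not None


def _check_positive(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "concentrations must be strictly positive; zeros encode "
            "non-detects and must be removed upstream"
        )
    return y


def _boxcox_z(y, L, M, S):
    """Vectorized Cole-Green transform; L, M, S broadcast against y."""
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    logr = np.log(y / M)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    z_pow = (np.exp(Lsafe * logr) - 1.0) / (Lsafe * S)
    z_log = logr / S
    return np.where(small, z_log, z_pow)


def _boxcox_inv(z, L, M, S):
    """Invert the Cole-Green transform: z-score -> concentration."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    small = np.abs(L) < _L_EPS
    Lsafe = np.where(small, 1.0, L)
    arg = 1.0 + Lsafe * S * z
    if np.any(~small & (arg <= 0)):
        raise ValueError("percentile outside support")
    argsafe = np.where(small | (arg <= 0), 1.0, arg)
    y_pow = M * np.exp(np.log(argsafe) / Lsafe)
    y_log = M * np.exp(S * z)
    return np.where(small, y_log, y_pow)


def _kernel_quantile(alpha, tau):
    if tau is None:
        return stats.norm.ppf(alpha)
    return stats.t.ppf(alpha, df=tau)


def _kernel_cdf(z, tau):
    if tau is None:
        return stats.norm.cdf(z)
    return stats.t.cdf(z, df=tau)


def _kernel_logpdf(z, tau):
    if tau is None:
        return stats.norm.logpdf(z)
    return stats.t.logpdf(z, df=tau)


def _log_trunc_const(L, S, tau):
    """log of the truncation normalizer P(Z < 1/(S|L|)) on the kernel scale.

    The Box-Cox transform maps y > 0 onto a half line of z values bounded by
    1/(S|L|); the kernel mass beyond that bound is excluded.  For L = 0 the
    support is the whole line and the constant is 1.
    """
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    small = np.abs(L) < _L_EPS
    bound = 1.0 / (S * np.where(small, 1.0, np.abs(L)))
    if tau is None:
        logc = stats.norm.logcdf(bound)
    else:
        logc = np.log(stats.t.cdf(bound, df=tau))
    return np.where(small, 0.0, logc)


def lms_z(y, p: LMSParams):
    """Map a concentration to its z-score under the LMS parameters ``p``.

    For BCT parameters the returned z is the same Cole-Green transform;
    its null distribution is Student t with ``p.tau`` degrees of freedom
    (use :func:`t_to_normal_sds` for a normal-equivalent SDS).
    """
    y = _check_positive(y)
    out = _boxcox_z(y, p.L, p.M, p.S)
    return float(out) if out.ndim == 0 else out


def lms_quantile(alpha, p: LMSParams):
    """Concentration at cumulative probability ``alpha`` under ``p``."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("alpha must lie strictly inside (0, 1)")
    z = _kernel_quantile(alpha, p.tau)
    out = _boxcox_inv(z, p.L, p.M, p.S)
    return float(out) if out.ndim == 0 else out


def lms_logpdf(y, p: LMSParams):
    """Log-density of the (truncated-at-zero) Box-Cox normal / Box-Cox t.

    Includes the Jacobian term ``(L-1)*ln(y/M) - ln(M*S)`` and the exact
    truncation normalizer so that the density integrates to one on (0, inf).
    """
    y = _check_positive(y)
    z = _boxcox_z(y, p.L, p.M, p.S)
    logjac = (p.L - 1.0) * np.log(y / p.M) - np.log(p.M * p.S)
    out = logjac + _kernel_logpdf(z, p.tau) - _log_trunc_const(p.L, p.S, p.tau)
    return float(out) if out.ndim == 0 else out


def t_to_normal_sds(z, tau: float):
    """Map a t-referenced z-score to a normal-equivalent SDS.

    Probability integral transform: Phi^{-1}(T_tau(z)).  Used when scoring
    against BCT references so that SDS values from BCCG and BCT references
    share the standard-normal scale.
    """
    return stats.norm.ppf(stats.t.cdf(np.asarray(z, dtype=float), df=tau))


def _loglik_arrays(y, L, M, S, tau):
    """Pointwise log-likelihood with parameter arrays (internal, for fitting).

    Same density as :func:`lms_logpdf` but accepts per-observation L, M, S
    arrays, and returns -inf (rather than raising) where the observation
    falls outside the parameter support, so optimizers can recover.
    """
    y = np.asarray(y, dtype=float)
    with np.errstate(all="ignore"):
        z = _boxcox_z(y, L, M, S)
        logjac = (L - 1.0) * np.log(y / M) - np.log(M * S)
        ll = logjac + _kernel_logpdf(z, tau) - _log_trunc_const(L, S, tau)
    return np.where(np.isfinite(ll), ll, -np.inf)
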