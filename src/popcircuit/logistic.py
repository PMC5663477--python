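"""Two-parameter logistic input-output model of a neural population.

Each neuron's probability of firing in a time bin is a logistic function of
a scalar input drive ``f``::

    q(f) = 1 / (1 + exp(-beta * (f - f_half)))

``beta`` is the slope and ``f_half`` the input at which q = 0.5.  For
interpretability the midpoint is converted to a *threshold*: the input level
at which the neuron reaches a small reference spike probability
``q_thresh`` (0.01 throughout)::

    f_thresh = f_half + log(q_thresh / (1 - q_thresh)) / beta

When the drive is a standard-normal random variable shared across neurons,
the model yields closed quadrature expressions for a neuron's mean firing
probability and for the pairwise correlation of two neurons that are
conditionally independent given the drive.  This module provides the
per-neuron binomial fit, those analytic maps, fixed-rate contours, and local
finite-difference sensitivities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit

__all__ = [
    "Q_THRESH_DEFAULT",
    "LogisticFit",
    "logistic_q",
    "q_from_threshold",
    "fit_logistic",
    "threshold_from_fit",
    "f_half_from_threshold",
    "mean_rate",
    "pair_correlation",
    "pair_correlation_fits",
    "rate_contour",
    "local_sensitivity",
    "drive_nodes",
]

Q_THRESH_DEFAULT = 0.01
BETA_CAP = 1e4

#: logit of the default q_thresh; f_thresh = f_half + _LOGIT_QT / beta
_LOGIT_QT = float(np.log(Q_THRESH_DEFAULT / (1.0 - Q_THRESH_DEFAULT)))


@dataclass
class LogisticFit:
    """Fitted logistic response of one neuron.

    ``domain`` records the scale the fit lives on: ``"l4_fraction"`` for
    circuit-simulation response curves, ``"standard_normal"`` for the
    analytic shared-drive model.  The two scales are never mixed.
    """

    beta: float
    f_half: float
    f_thresh: float = field(default=np.nan)
    q_thresh: float = Q_THRESH_DEFAULT
    domain: str = "standard_normal"
    degenerate: bool = False
    separated: bool = False

    def __post_init__(self):
        if np.isnan(self.f_thresh) and self.beta > 0:
            self.f_thresh = threshold_from_fit(self)

    @property
    def valid(self) -> bool:
        return not self.degenerate


def logistic_q(f, beta, f_half):
    """Spike probability q(f) in the midpoint parameterization."""
    f = np.asarray(f, dtype=float)
    return expit(beta * (f - f_half))


def q_from_threshold(f, beta, f_thresh, q_thresh=Q_THRESH_DEFAULT):
    """Spike probability q(f) in the (slope, threshold) parameterization.

    Continuous in beta: as beta -> 0 the curve flattens to q == q_thresh.
    """
    f = np.asarray(f, dtype=float)
    logit_qt = np.log(q_thresh / (1.0 - q_thresh))
    return expit(beta * (f - f_thresh) + logit_qt)


def threshold_from_fit(fit: "LogisticFit") -> float:
    """Convert a midpoint fit to the threshold f_thresh.

    f_thresh = f_half + log(q_thresh/(1-q_thresh)) / beta.  Undefined for
    beta == 0 (returns NaN).
    """
    if fit.beta <= 0:
        return np.nan
    return fit.f_half + np.log(fit.q_thresh / (1.0 - fit.q_thresh)) / fit.beta


def f_half_from_threshold(beta, f_thresh, q_thresh=Q_THRESH_DEFAULT):
    return f_thresh - np.log(q_thresh / (1.0 - q_thresh)) / beta


def fit_logistic(
    f_levels,
    success_counts,
    trial_counts,
    q_thresh=Q_THRESH_DEFAULT,
    beta_cap=BETA_CAP,
    domain="l4_fraction",
) -> LogisticFit:
    """Binomial maximum-likelihood logistic fit of q(f).

    Parameters
    ----------
    f_levels : array of input levels (>= 2 distinct values)
    success_counts, trial_counts : per-level spike counts and trials

    Degenerate data (all-0, all-1, or perfectly separated responses) are
    returned flagged instead of raising; separated fits have beta capped.
    """
    f = np.asarray(f_levels, dtype=float)
    k = np.asarray(success_counts, dtype=float)
    n = np.asarray(trial_counts, dtype=float)
    if f.size < 2 or np.unique(f).size < 2:
        raise ValueError("need at least two distinct input levels")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("success counts must lie in [0, trials]")

    tot_k, tot_n = k.sum(), n.sum()
    if tot_k == 0 or tot_k == tot_n:
        # all-silent or all-saturated: slope unidentifiable
        return LogisticFit(0.0, np.nan, np.nan, q_thresh, domain, degenerate=True)

    # perfect step: q jumps 0 -> 1 between adjacent levels, so the binomial
    # likelihood has no finite maximum; cap the slope at the step location
    order = np.argsort(f)
    qhat = k[order] / n[order]
    if np.all((qhat == 0) | (qhat == 1)) and np.all(np.diff(qhat) >= 0):
        jump = int(np.argmax(qhat == 1))
        f_half = 0.5 * (f[order][jump - 1] + f[order][jump])
        fit = LogisticFit(float(beta_cap), float(f_half), np.nan, q_thresh,
                          domain, degenerate=False, separated=True)
        return fit

    import statsmodels.api as sm

    exog = sm.add_constant(f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(np.column_stack([k, n - k]), exog,
                           family=sm.families.Binomial())
            res = model.fit(maxiter=200)
            intercept, slope = res.params
        except Exception:
            return LogisticFit(0.0, np.nan, np.nan, q_thresh, domain,
                               degenerate=True)

    separated = False
    if not np.isfinite(slope) or not np.isfinite(intercept):
        return LogisticFit(0.0, np.nan, np.nan, q_thresh, domain, degenerate=True)
    if abs(slope) > beta_cap:
        separated = True
        slope = np.sign(slope) * beta_cap
    if slope <= 0:
        # response decreasing in f: outside the model family, flag it
        return LogisticFit(0.0, np.nan, np.nan, q_thresh, domain, degenerate=True)

    f_half = -intercept / slope
    fit = LogisticFit(float(slope), float(f_half), np.nan, q_thresh, domain,
                      degenerate=False, separated=separated)
    return fit


# ---------------------------------------------------------------------------
# Analytic maps over a standard-normal shared drive
# ---------------------------------------------------------------------------

_GH_CACHE: dict = {}


def drive_nodes(n_nodes=201):
    """Gauss-Hermite nodes/weights for E[.] under the N(0,1) drive.

    Returns (x, w) with sum(w) == 1.
    """
    key = int(n_nodes)
    if key not in _GH_CACHE:
        x, w = np.polynomial.hermite_e.hermegauss(key)
        _GH_CACHE[key] = (x, w / w.sum())
    return _GH_CACHE[key]


def _mean_rate_adaptive(beta, f_thresh, q_thresh):
    if beta == 0:
        return 0.5    # zero slope: the curve is flat at its midpoint value
    f_half = f_half_from_threshold(beta, f_thresh, q_thresh)

    def integrand(f):
        return expit(beta * (f - f_half)) * stats.norm.pdf(f)

    lo = min(f_half, 0.0) - 12.0
    hi = max(f_half, 0.0) + 12.0
    a, _ = integrate.quad(integrand, -np.inf, lo, epsabs=1e-12, limit=200)
    b, _ = integrate.quad(integrand, lo, f_half, epsabs=1e-12, limit=200)
    c, _ = integrate.quad(integrand, f_half, hi, epsabs=1e-12, limit=200)
    d, _ = integrate.quad(integrand, hi, np.inf, epsabs=1e-12, limit=200)
    return float(a + b + c + d)


def mean_rate(beta, f_thresh, q_thresh=Q_THRESH_DEFAULT, method="adaptive",
              n_nodes=201):
    """Mean firing probability mu = E_f[q(f)] under the N(0,1) drive.

    ``method="adaptive"`` (default) uses adaptive quadrature split at the
    midpoint, accurate to ~1e-10 even for near-step slopes.  ``method="gauss"``
    uses fixed Gauss-Hermite nodes, faster inside fitting loops but less
    accurate for beta >~ 30.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return 0.5
    if method == "adaptive":
        return _mean_rate_adaptive(beta, f_thresh, q_thresh)
    x, w = drive_nodes(n_nodes)
    return float(np.dot(w, q_from_threshold(x, beta, f_thresh, q_thresh)))


def pair_correlation(beta_a, f_thresh_a, beta_b=None, f_thresh_b=None,
                     q_thresh=Q_THRESH_DEFAULT, method="adaptive",
                     n_nodes=201):
    """Pairwise correlation of two logistic neurons sharing the drive.

    cov = E_f[q_a q_b] - mu_a mu_b; corr = cov / sqrt(mu_a(1-mu_a) mu_b(1-mu_b)),
    the variance of the conditionally independent Bernoulli spike counts.
    Omitting (beta_b, f_thresh_b) gives the homogeneous pair.  Returns 0.0
    when either neuron is saturated (zero variance); callers that need the
    flag can test mu in {0, 1} via `mean_rate`.
    """
    if beta_b is None:
        beta_b, f_thresh_b = beta_a, f_thresh_a
    if beta_a == 0 or beta_b == 0:
        return 0.0     # a flat neuron (q constant) is uncorrelated with anything
    mu_a = mean_rate(beta_a, f_thresh_a, q_thresh, method, n_nodes)
    mu_b = mean_rate(beta_b, f_thresh_b, q_thresh, method, n_nodes)
    var = mu_a * (1 - mu_a) * mu_b * (1 - mu_b)
    if var <= 1e-12:    # saturated neuron: correlation undefined, report 0
        return 0.0
    if method == "adaptive":
        fha = f_half_from_threshold(beta_a, f_thresh_a, q_thresh) if beta_a > 0 else 0.0
        fhb = f_half_from_threshold(beta_b, f_thresh_b, q_thresh) if beta_b > 0 else 0.0

        def integrand(f):
            return (q_from_threshold(f, beta_a, f_thresh_a, q_thresh)
                    * q_from_threshold(f, beta_b, f_thresh_b, q_thresh)
                    * stats.norm.pdf(f))

        pts = sorted({min(fha, fhb), max(fha, fhb)})
        eqq = 0.0
        segs = [-np.inf] + [p for p in pts if -12 < p < 12] + [np.inf]
        for lo, hi in zip(segs[:-1], segs[1:]):
            val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, limit=200)
            eqq += val
    else:
        x, w = drive_nodes(n_nodes)
        qa = q_from_threshold(x, beta_a, f_thresh_a, q_thresh)
        qb = q_from_threshold(x, beta_b, f_thresh_b, q_thresh)
        eqq = float(np.dot(w, qa * qb))
    cov = eqq - mu_a * mu_b
    return float(np.clip(cov / np.sqrt(var), -1.0, 1.0))


def pair_correlation_fits(fit_a: LogisticFit, fit_b: LogisticFit, **kw):
    return pair_correlation(fit_a.beta, fit_a.f_thresh,
                            fit_b.beta, fit_b.f_thresh,
                            q_thresh=fit_a.q_thresh, **kw)


def threshold_for_rate(beta, target_mu, q_thresh=Q_THRESH_DEFAULT,
                       method="adaptive", xtol=1e-12):
    """Solve mean_rate(beta, f_thresh) == target_mu for f_thresh.

    mu is strictly decreasing in f_thresh at fixed beta > 0, so the root is
    bracketed then found by Brent's method (|mu error| <= ~1e-8).
    """
    if not (0 < target_mu < 1):
        raise ValueError("target_mu must lie in (0, 1)")
    if beta <= 0:
        raise ValueError("beta must be > 0")

    def g(th):
        return mean_rate(beta, th, q_thresh, method) - target_mu

    lo, hi = -5.0, 5.0
    for _ in range(60):
        if g(lo) > 0 > g(hi):
            break
        if g(lo) <= 0:
            lo *= 2.0
        if g(hi) >= 0:
            hi *= 2.0
    else:
        raise RuntimeError("could not bracket the rate contour root")
    return float(optimize.brentq(g, lo, hi, xtol=xtol))


def slope_threshold_for_stats(target_mu, target_corr,
                              beta_bracket=(1e-3, 500.0),
                              q_thresh=Q_THRESH_DEFAULT):
    """Homogeneous (slope, threshold) matching a target (rate, correlation).

    Moves along the fixed-rate contour, where the pair correlation is
    monotone in the slope, and solves corr(beta) == target_corr by Brent's
    method on log(beta).  Targets outside the attainable range (corr -> 0
    only as beta -> 0, corr -> 1 as beta -> inf) are clamped to the bracket
    endpoint.
    """
    lo, hi = beta_bracket

    def corr_at(beta):
        th = threshold_for_rate(beta, target_mu, q_thresh)
        return pair_correlation(beta, th, q_thresh=q_thresh), th

    c_lo, th_lo = corr_at(lo)
    c_hi, th_hi = corr_at(hi)
    if target_corr <= c_lo:
        return lo, th_lo
    if target_corr >= c_hi:
        return hi, th_hi

    def g(logb):
        return corr_at(np.exp(logb))[0] - target_corr

    logb = optimize.brentq(g, np.log(lo), np.log(hi), xtol=1e-10)
    beta = float(np.exp(logb))
    return beta, threshold_for_rate(beta, target_mu, q_thresh)


def rate_contour(target_mu, beta_grid, q_thresh=Q_THRESH_DEFAULT,
                 method="adaptive"):
    """Fixed-firing-rate contour in (slope, threshold) space.

    For each slope in ``beta_grid`` solves for the threshold that yields the
    target mean rate, and evaluates the homogeneous pair correlation there.

    Returns
    -------
    list of (beta, f_thresh, corr); entries with failed root-finding carry
    NaN threshold/corr.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid <= 0) or np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be positive and strictly increasing")
    out = []
    for beta in beta_grid:
        try:
            th = threshold_for_rate(beta, target_mu, q_thresh, method)
            corr = pair_correlation(beta, th, q_thresh=q_thresh, method=method)
        except RuntimeError:
            th, corr = np.nan, np.nan
        out.append((float(beta), th, corr))
    return out


def local_sensitivity(beta, f_thresh, h=1e-3, q_thresh=Q_THRESH_DEFAULT,
                      method="adaptive"):
    """Finite-difference sensitivities of (mu, corr) to (slope, threshold).

    Central differences with relative step ``h * max(|param|, 1)``; if the
    slope step would cross beta <= 0 a one-sided forward difference is used
    and flagged.

    Returns dict with keys dmu_dbeta, dmu_dtheta, dcorr_dbeta, dcorr_dtheta,
    one_sided_beta.
    """
    if beta <= 0 or h <= 0:
        raise ValueError("beta and h must be > 0")
    hb = h * max(abs(beta), 1.0)
    ht = h * max(abs(f_thresh), 1.0)

    one_sided = beta - hb <= 0

    def mu(b, t):
        return mean_rate(b, t, q_thresh, method)

    def rho(b, t):
        return pair_correlation(b, t, q_thresh=q_thresh, method=method)

    if one_sided:
        dmu_db = (mu(beta + hb, f_thresh) - mu(beta, f_thresh)) / hb
        drho_db = (rho(beta + hb, f_thresh) - rho(beta, f_thresh)) / hb
    else:
        dmu_db = (mu(beta + hb, f_thresh) - mu(beta - hb, f_thresh)) / (2 * hb)
        drho_db = (rho(beta + hb, f_thresh) - rho(beta - hb, f_thresh)) / (2 * hb)
    dmu_dt = (mu(beta, f_thresh + ht) - mu(beta, f_thresh - ht)) / (2 * ht)
    drho_dt = (rho(beta, f_thresh + ht) - rho(beta, f_thresh - ht)) / (2 * ht)
    return {
        "dmu_dbeta": dmu_db,
        "dmu_dtheta": dmu_dt,
        "dcorr_dbeta": drho_db,
        "dcorr_dtheta": drho_dt,
        "one_sided_beta": one_sided,
    }
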