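"""Five-parameter population version of the logistic response model.

Cell-to-cell heterogeneity is captured by a 2D Gaussian over each neuron's
(threshold, slope) pair: mean threshold, mean slope, the two standard
deviations, and the threshold-slope correlation.  Given these five
parameters the model predicts three population activity statistics —
mean firing probability, s.d. of firing probabilities across neurons, and
mean pairwise correlation — by numerical integration over the parameter
distribution and the shared standard-normal drive.

Fitting inverts this map: an accept/reject random-perturbation descent on
the summed squared error between predicted and target statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ActivityStatistics
from .logistic import Q_THRESH_DEFAULT, drive_nodes, q_from_threshold

__all__ = [
    "PopulationLogisticParams",
    "predict_stats",
    "PopulationLogisticModel",
    "fit_population",
    "validate_fit",
]


@dataclass
class PopulationLogisticParams:
    """2D Gaussian over per-neuron (threshold, slope)."""

    mu_thresh: float
    mu_slope: float
    sd_thresh: float
    sd_slope: float
    rho_slope_thresh: float = 0.0

    def __post_init__(self):
        if self.sd_thresh < 0 or self.sd_slope < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (-1.0 <= self.rho_slope_thresh <= 1.0):
            raise ValueError("rho_slope_thresh must lie in [-1, 1]")

    @property
    def covariance(self) -> np.ndarray:
        c = self.rho_slope_thresh * self.sd_thresh * self.sd_slope
        return np.array([[self.sd_thresh**2, c], [c, self.sd_slope**2]])

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_thresh, self.mu_slope, self.sd_thresh,
                         self.sd_slope, self.rho_slope_thresh])

    @classmethod
    def from_array(cls, a) -> "PopulationLogisticParams":
        return cls(*[float(v) for v in a])

    def to_dict(self) -> dict:
        return asdict(self)

    def sample(self, n, rng: np.random.Generator):
        """Draw n (threshold, slope) pairs; slope truncated at 0."""
        mean = [self.mu_thresh, self.mu_slope]
        draws = rng.multivariate_normal(mean, self.covariance, size=n,
                                        method="eigh")
        thresh = draws[:, 0]
        slope = np.clip(draws[:, 1], 0.0, None)
        return thresh, slope


_HG_CACHE: dict = {}


def _param_nodes(n_nodes):
    key = int(n_nodes)
    if key not in _HG_CACHE:
        x, w = np.polynomial.hermite_e.hermegauss(key)
        _HG_CACHE[key] = (x, w / w.sum())
    return _HG_CACHE[key]


def predict_stats(params: PopulationLogisticParams,
                  q_thresh=Q_THRESH_DEFAULT,
                  n_nodes_param=13, n_nodes_drive=61) -> ActivityStatistics:
    """Predict (mean rate, rate s.d., mean pairwise correlation).

    The expectation over the 2D Gaussian of (threshold, slope) uses a
    tensor-product Gauss-Hermite rule mapped through the Cholesky factor of
    the covariance; Gaussian mass at negative slopes is truncated to slope 0.
    Neuron pairs have independent parameter draws but share the drive, so
    E_f[q_a q_b] couples every pair of parameter nodes through the drive
    quadrature.  Deterministic for fixed quadrature orders.
    """
    if not isinstance(params, PopulationLogisticParams):
        params = PopulationLogisticParams.from_array(np.asarray(params))
    rho = params.rho_slope_thresh
    z, wz = _param_nodes(n_nodes_param)

    if params.sd_thresh == 0 and params.sd_slope == 0:
        thetas = np.array([params.mu_thresh])
        slopes = np.array([params.mu_slope])
        wp = np.array([1.0])
    elif abs(rho) >= 1.0 or params.sd_thresh == 0 or params.sd_slope == 0:
        # rank-1 (degenerate ridge) or one-dimensional spread: 1D reduction
        thetas = params.mu_thresh + params.sd_thresh * z
        slopes = params.mu_slope + np.sign(rho if rho != 0 else 1.0) \
            * params.sd_slope * z
        if params.sd_thresh == 0:
            thetas = np.full_like(z, params.mu_thresh)
        if params.sd_slope == 0:
            slopes = np.full_like(z, params.mu_slope)
        wp = wz
    else:
        z1 = np.repeat(z, n_nodes_param)
        z2 = np.tile(z, n_nodes_param)
        wp = np.repeat(wz, n_nodes_param) * np.tile(wz, n_nodes_param)
        thetas = params.mu_thresh + params.sd_thresh * z1
        slopes = params.mu_slope + params.sd_slope * (
            rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    slopes = np.clip(slopes, 0.0, None)

    f, wf = drive_nodes(n_nodes_drive)
    # q matrix: parameter nodes x drive nodes
    logit_qt = np.log(q_thresh / (1.0 - q_thresh))
    arg = slopes[:, None] * (f[None, :] - thetas[:, None]) + logit_qt
    from scipy.special import expit
    Q = expit(arg)

    mu = Q @ wf
    mean_rate = float(wp @ mu)
    var_rate = float(wp @ mu**2) - mean_rate**2
    sd_rate = float(np.sqrt(max(var_rate, 0.0)))

    # E_f[q_a q_b] over all parameter-node pairs
    Eab = (Q * wf[None, :]) @ Q.T
    cov = Eab - np.outer(mu, mu)
    var = mu * (1.0 - mu)
    good = var > 1e-14
    denom = np.sqrt(np.outer(var, var))
    corr = np.zeros_like(cov)
    mask = np.outer(good, good)
    corr[mask] = cov[mask] / denom[mask]
    mean_corr = float(wp @ corr @ wp)

    return ActivityStatistics(mean_rate=min(max(mean_rate, 0.0), 1.0),
                              sd_rate=sd_rate,
                              mean_corr=float(np.clip(mean_corr, -1.0, 1.0)))


class PopulationLogisticModel(BaseEstimator):
    """Accept/reject stochastic-descent fit of the 5-parameter model.

    The fit repeatedly perturbs all five parameters with zero-mean Gaussian
    noise, recomputes the predicted statistics, and accepts the proposal
    only if the summed squared error against the target decreases; it stops
    when the error drops below ``tol`` or after ``max_iter`` proposals.
    The perturbation s.d. starts at ``step_frac`` of each parameter's scale
    and is multiplied by ``step_decay`` after ``patience`` consecutive
    rejections (set ``step_decay=1.0`` for the fixed-step variant).

    Parameters
    ----------
    init : array-like of 5 or None
        Starting guess (threshold mean, slope mean, threshold s.d.,
        slope s.d., rho); defaults to (1, 2, 0.5, 0.5, 0).
    n_restarts : independent seeded restarts; the best error wins.

    Attributes (after fit)
    ----------------------
    params_ : PopulationLogisticParams
    error_ : float, final summed squared error
    converged_ : bool
    trajectory_ : ndarray of accepted errors (non-increasing)
    n_iter_ : proposals used by the winning restart
    """

    def __init__(self, init=None, step_frac=0.02, tol=1e-6, max_iter=200_000,
                 patience=300, step_decay=0.5, min_step_factor=1e-9,
                 n_restarts=5, q_thresh=Q_THRESH_DEFAULT,
                 n_nodes_param=13, n_nodes_drive=61, random_state=None):
        self.init = init
        self.step_frac = step_frac
        self.tol = tol
        self.max_iter = max_iter
        self.patience = patience
        self.step_decay = step_decay
        self.min_step_factor = min_step_factor
        self.n_restarts = n_restarts
        self.q_thresh = q_thresh
        self.n_nodes_param = n_nodes_param
        self.n_nodes_drive = n_nodes_drive
        self.random_state = random_state

    def _predict(self, p):
        return predict_stats(PopulationLogisticParams.from_array(p),
                             self.q_thresh, self.n_nodes_param,
                             self.n_nodes_drive).as_array()

    @staticmethod
    def _clip(p):
        p[2] = max(p[2], 0.0)
        p[3] = max(p[3], 0.0)
        p[4] = float(np.clip(p[4], -0.999, 0.999))
        return p

    def _descend(self, target, p0, rng):
        p = self._clip(np.array(p0, dtype=float))
        scale = np.maximum(np.abs(p), [0.5, 0.5, 0.1, 0.1, 0.1])
        step = self.step_frac * scale
        err = float(np.sum((self._predict(p) - target) ** 2))
        traj = [err]
        rejects = 0
        it = 0
        while err > self.tol and it < self.max_iter:
            it += 1
            prop = self._clip(p + rng.normal(0.0, step))
            e = float(np.sum((self._predict(prop) - target) ** 2))
            if e < err:
                p, err = prop, e
                traj.append(err)
                rejects = 0
            else:
                rejects += 1
                if rejects >= self.patience:
                    step = step * self.step_decay
                    rejects = 0
                    if np.all(step < self.min_step_factor * scale):
                        break
        return p, err, np.array(traj), it

    def fit(self, target, y=None):
        """Fit to target statistics (ActivityStatistics or 3-array)."""
        if isinstance(target, ActivityStatistics):
            target = target.as_array()
        target = np.asarray(target, dtype=float)
        if target.shape != (3,):
            raise ValueError("target must supply (mean_rate, sd_rate, mean_corr)")
        if not (0 <= target[0] <= 1) or target[1] < 0:
            raise ValueError("target statistics out of range")

        p0 = np.array([1.0, 2.0, 0.5, 0.5, 0.0]) if self.init is None \
            else np.asarray(self.init, dtype=float)
        root = np.random.SeedSequence(self.random_state)
        best = None
        for i, ss in enumerate(root.spawn(max(self.n_restarts, 1))):
            rng = np.random.default_rng(ss)
            start = p0 if i == 0 else self._clip(
                p0 + rng.normal(0.0, 0.5 * np.maximum(np.abs(p0), 0.5)))
            p, err, traj, it = self._descend(target, start, rng)
            if best is None or err < best[1]:
                best = (p, err, traj, it)
            if best[1] <= self.tol:
                break
        p, err, traj, it = best
        self.params_ = PopulationLogisticParams.from_array(p)
        self.error_ = err
        self.trajectory_ = traj
        self.n_iter_ = it
        self.converged_ = bool(err <= self.tol)
        self.target_ = target
        return self

    def predict_stats(self):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "params_")
        return predict_stats(self.params_, self.q_thresh,
                             self.n_nodes_param, self.n_nodes_drive)

    def report(self) -> dict:
        return {
            "params": self.params_.to_dict(),
            "final_error": self.error_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "trajectory_length": int(len(self.trajectory_)),
        }


def fit_population(target, init=None, step_sd=0.02, tol=1e-6,
                   max_iter=200_000, seed=None, n_restarts=5,
                   **kw) -> PopulationLogisticModel:
    """Functional wrapper over :class:`PopulationLogisticModel`."""
    model = PopulationLogisticModel(init=init, step_frac=step_sd, tol=tol,
                                    max_iter=max_iter, random_state=seed,
                                    n_restarts=n_restarts, **kw)
    return model.fit(target)


def validate_fit(params: PopulationLogisticParams, target, n_neurons,
                 n_bins, seed=None) -> dict:
    """Sample a raster from fitted params and compare statistics to target.

    Draws a binary raster via the synthetic generator, computes the three
    statistics on the samples, and reports each against the target with a
    bootstrap-free Monte-Carlo error bar (binomial/CLT based).
    """
    from .synth import GroundTruthSpec, sample_raster, binary_summary_stats

    spec = GroundTruthSpec(pop_params=params, n_neurons=n_neurons,
                           n_bins=n_bins, seed=seed)
    _, binary = sample_raster(spec)
    sampled = binary_summary_stats(binary)
    if isinstance(target, ActivityStatistics):
        target = target.as_array()
    target = np.asarray(target, dtype=float)
    est = sampled.as_array()
    # MC error bars: CLT on the time dimension
    se = np.array([
        sampled.sd_rate / np.sqrt(max(n_neurons, 2)),
        sampled.sd_rate / np.sqrt(2.0 * max(n_neurons - 1, 1)),
        1.0 / np.sqrt(n_bins),
    ])
    mismatch = np.abs(est - target) > 3.0 * np.maximum(se, 1e-12)
    return {
        "target": target.tolist(),
        "sampled": est.tolist(),
        "mc_se": se.tolist(),
        "mismatch_beyond_3se": mismatch.tolist(),
        "any_mismatch": bool(mismatch.any()),
        "n_neurons": int(n_neurons),
        "n_bins": int(n_bins),
    }
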