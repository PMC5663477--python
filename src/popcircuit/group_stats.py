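"""Bootstrap group statistics: pooled-null mean-difference tests and
chi-squared confidence ellipses for 2D mean shifts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = [
    "BootstrapResult",
    "bootstrap_mean_diff",
    "ConfidenceEllipse",
    "confidence_ellipse",
    "mean_diff_ellipse",
]


@dataclass
class BootstrapResult:
    delta_obs: float
    p_value: float
    n1: int
    n2: int
    n_boot: int
    seed: int | None = None
    null_mean: float = 0.0
    null_sd: float = 0.0
    null_samples: np.ndarray | None = field(default=None, repr=False)


def bootstrap_mean_diff(group1, group2, n_boot=100_000, seed=None,
                        keep_null=False) -> BootstrapResult:
    """Two-sided pooled-null bootstrap test of a group-mean difference.

    The two groups are pooled; hypothetical groups of the original sizes
    are resampled with replacement from the pool and their mean difference
    recorded, building the null distribution of the difference.  The
    p-value is the two-sided tail mass at the observed difference, with an
    add-one correction so p > 0:
    p = (1 + #{|d_null| >= |d_obs|}) / (n_boot + 1).
    """
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    delta_obs = float(g1.mean() - g2.mean())
    pool = np.concatenate([g1, g2])
    rng = np.random.default_rng(seed)
    n1, n2 = g1.size, g2.size
    # vectorized in blocks to bound memory at large n_boot
    block = max(1, min(n_boot, int(2e7 // (n1 + n2))))
    exceed = 0
    kept = [] if keep_null else None
    s = ss = 0.0
    done = 0
    while done < n_boot:
        b = min(block, n_boot - done)
        d = (pool[rng.integers(0, pool.size, (b, n1))].mean(axis=1)
             - pool[rng.integers(0, pool.size, (b, n2))].mean(axis=1))
        exceed += int((np.abs(d) >= abs(delta_obs)).sum())
        s += d.sum()
        ss += (d ** 2).sum()
        if kept is not None:
            kept.append(d)
        done += b
    p = (1 + exceed) / (n_boot + 1)
    null_mean = s / n_boot
    null_sd = float(np.sqrt(max(ss / n_boot - null_mean**2, 0.0)))
    return BootstrapResult(
        delta_obs=delta_obs, p_value=float(p), n1=n1, n2=n2, n_boot=n_boot,
        seed=seed, null_mean=float(null_mean), null_sd=null_sd,
        null_samples=np.concatenate(kept) if kept is not None else None)


@dataclass
class ConfidenceEllipse:
    center: np.ndarray
    covariance: np.ndarray
    level: float
    chi2_quantile: float
    semi_axes: np.ndarray
    angle_rad: float
    degenerate: bool = False

    def contains(self, point) -> bool:
        """Mahalanobis membership test for a 2-vector."""
        d = np.asarray(point, dtype=float) - self.center
        if self.degenerate:
            return False
        md2 = d @ np.linalg.solve(self.covariance, d)
        return bool(md2 <= self.chi2_quantile)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "covariance": self.covariance.tolist(),
            "level": self.level,
            "chi2_quantile": self.chi2_quantile,
            "semi_axes": self.semi_axes.tolist(),
            "angle_rad": self.angle_rad,
            "degenerate": self.degenerate,
        }


def _ellipse_from_cov(center, cov, level):
    q = float(chi2.ppf(level, df=2))
    eigval, eigvec = np.linalg.eigh(cov)
    degenerate = bool(eigval.min() <= 1e-14 * max(eigval.max(), 1e-300)
                      or eigval.max() <= 0)
    semi = np.sqrt(np.clip(eigval, 0, None) * q)[::-1]
    major = eigvec[:, np.argmax(eigval)]
    angle = float(np.arctan2(major[1], major[0]))
    return ConfidenceEllipse(center=np.asarray(center, dtype=float),
                             covariance=cov, level=level, chi2_quantile=q,
                             semi_axes=semi, angle_rad=angle,
                             degenerate=degenerate)


def confidence_ellipse(samples_2d, level=0.95, n_boot=100_000,
                       seed=None) -> ConfidenceEllipse:
    """Bootstrap confidence ellipse for the mean of paired 2D samples.

    The sample mean's covariance is estimated by bootstrapping the rows;
    semi-axes are sqrt(chi2_{level,2} * eigenvalues), oriented along the
    eigenvectors.  Rank-deficient sample clouds yield a flagged degenerate
    ellipse.
    """
    x = np.asarray(samples_2d, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise ValueError("need >= 3 paired 2D samples")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    idx = rng.integers(0, n, (n_boot, n))
    means = x[idx].mean(axis=1)
    cov = np.cov(means.T)
    return _ellipse_from_cov(x.mean(axis=0), cov, level)


def mean_diff_ellipse(group1_2d, group2_2d, level=0.95, n_boot=100_000,
                      seed=None) -> ConfidenceEllipse:
    """Confidence ellipse for the difference of two group means in 2D,
    bootstrapping each group independently."""
    a = np.asarray(group1_2d, dtype=float)
    b = np.asarray(group2_2d, dtype=float)
    rng = np.random.default_rng(seed)
    ma = a[rng.integers(0, a.shape[0], (n_boot, a.shape[0]))].mean(axis=1)
    mb = b[rng.integers(0, b.shape[0], (n_boot, b.shape[0]))].mean(axis=1)
    cov = np.cov((ma - mb).T)
    return _ellipse_from_cov(a.mean(axis=0) - b.mean(axis=0), cov, level)
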