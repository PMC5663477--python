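"""dF/F traces -> firing-rate estimates -> probabilistic ON/OFF rasters.

The preprocessing chain is: low-pass Butterworth filter (normalized cutoff
0.16, order 2, zero-phase), inverse filtering of the 2 s single-exponential
indicator kernel, a noise floor at twice the s.d. of the deconvolved
trace's negative excursions, and a fixed scale factor of 78.4 converting
the deconvolved amplitude to spikes/s.  Rates are then aggregated to 1-s
bins and converted to ON probabilities under an inhomogeneous Poisson
model: p_on = 1 - exp(-lambda) with lambda the expected spike count in the
bin.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ActivityStatistics

__all__ = [
    "dff_to_rate",
    "rate_to_pon",
    "summary_stats",
    "CalciumBinarizer",
]

log = logging.getLogger(__name__)

RATE_SCALE_DEFAULT = 78.4  # spikes/s per unit deconvolved dF/F


def dff_to_rate(dff, frame_rate, butter_cutoff=0.16, butter_order=2,
                kernel_tau_s=2.0, rate_scale=RATE_SCALE_DEFAULT):
    """Estimate firing rates (spikes/s) per frame from dF/F traces.

    Parameters
    ----------
    dff : (n_neurons, n_frames) or (n_frames,) array of dF/F values
    frame_rate : imaging frame rate in Hz
    butter_cutoff : normalized low-pass cutoff (fraction of Nyquist)
    kernel_tau_s : time constant of the single-exponential indicator kernel

    The exponential kernel is inverted exactly by the first-order recursion
    y[n] - a*y[n-1] with a = exp(-1/(tau*fs)).  The noise floor is twice
    the s.d. of the deconvolved trace's negative points; everything below
    it is zeroed.  Traces with no negative deconvolved points get a floor
    of 0 (logged).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if not np.all(np.isfinite(dff)):
        raise ValueError("dF/F trace contains non-finite values")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")

    b, a = signal.butter(butter_order, butter_cutoff)
    smoothed = signal.filtfilt(b, a, dff, axis=1)

    decay = np.exp(-1.0 / (kernel_tau_s * frame_rate))
    deconv = smoothed.copy()
    deconv[:, 1:] = smoothed[:, 1:] - decay * smoothed[:, :-1]

    rates = np.zeros_like(deconv)
    for i, tr in enumerate(deconv):
        neg = tr[tr < 0]
        if neg.size == 0:
            floor = 0.0
            log.info("trace %d has no negative deconvolved points; "
                     "noise floor set to 0", i)
        else:
            floor = 2.0 * neg.std()
        kept = np.where(tr >= floor, tr, 0.0)
        rates[i] = rate_scale * kept
    return rates


def rate_to_pon(rates, frame_rate, bin_width_s=1.0):
    """Aggregate per-frame rates to 1-s bins and convert to ON probability.

    Rates are averaged within each bin, lambda = mean rate * bin width, and
    p_on = 1 - exp(-lambda) (the Poisson probability of >= 1 spike).
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    n_frames = rates.shape[1]
    n_bins = int(np.floor(n_frames / (frame_rate * bin_width_s)))
    if n_bins < 1:
        raise ValueError("trace shorter than one bin")
    edges = np.floor(np.arange(n_bins + 1) * frame_rate * bin_width_s).astype(int)
    lam = np.empty((rates.shape[0], n_bins))
    for b in range(n_bins):
        lam[:, b] = rates[:, edges[b]:edges[b + 1]].mean(axis=1) * bin_width_s
    return 1.0 - np.exp(-lam)


def summary_stats(p_on) -> ActivityStatistics:
    """The three population statistics of an ON-probability raster.

    Mean over neurons of time-averaged p_on; s.d. across neurons of the
    time-averaged p_on; mean Pearson correlation of p_on time series over
    all unordered pairs (constant series are skipped and counted in
    ``corr_flagged_pairs``; an all-constant raster yields NaN mean_corr).
    """
    p = np.atleast_2d(np.asarray(p_on, dtype=float))
    n_neurons, n_bins = p.shape
    if n_neurons < 2 or n_bins < 2:
        raise ValueError("need >= 2 neurons and >= 2 bins")
    rates = p.mean(axis=1)
    sd = float(rates.std(ddof=1))
    sds = p.std(axis=1)
    good = np.nonzero(sds > 1e-12)[0]   # constant series carry no correlation
    total_pairs = n_neurons * (n_neurons - 1) // 2
    if good.size >= 2:
        c = np.corrcoef(p[good])
        iu = np.triu_indices_from(c, k=1)
        mean_corr = float(c[iu].mean())
        flagged = total_pairs - len(iu[0])
    else:
        mean_corr = np.nan
        flagged = total_pairs
    return ActivityStatistics(mean_rate=float(rates.mean()), sd_rate=sd,
                              mean_corr=mean_corr, n_neurons=n_neurons,
                              n_bins=n_bins, corr_flagged_pairs=flagged)


class CalciumBinarizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: dF/F traces -> ON-probability raster.

    ``transform(X)`` expects X of shape (n_neurons, n_frames) and returns
    the (n_neurons, n_bins) ON-probability raster.  Stateless; ``fit`` only
    validates input.
    """

    def __init__(self, frame_rate=3.9, butter_cutoff=0.16, butter_order=2,
                 kernel_tau_s=2.0, rate_scale=RATE_SCALE_DEFAULT,
                 bin_width_s=1.0):
        self.frame_rate = frame_rate
        self.butter_cutoff = butter_cutoff
        self.butter_order = butter_order
        self.kernel_tau_s = kernel_tau_s
        self.rate_scale = rate_scale
        self.bin_width_s = bin_width_s

    def fit(self, X, y=None):
        np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        rates = dff_to_rate(X, self.frame_rate, self.butter_cutoff,
                            self.butter_order, self.kernel_tau_s,
                            self.rate_scale)
        return rate_to_pon(rates, self.frame_rate, self.bin_width_s)
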