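"""Ground-truth-known synthetic rasters and dF/F-like traces.

Emulates the statistical structure the analysis assumes: each neuron gets a
(threshold, slope) pair drawn once from the population 2D Gaussian, every
1-s time bin gets a shared standard-normal input drive, the neuron's ON
probability follows the logistic curve, and spikes are conditionally
independent Bernoulli draws given that probability.  A forward fluorescence
model (spike -> 2 s exponential kernel at 3.9 Hz + Gaussian noise) exists to
exercise the calcium-binarization stage; it makes no claim about indicator
photophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .logistic import Q_THRESH_DEFAULT, q_from_threshold
from .datatypes import ActivityStatistics
from .population import PopulationLogisticParams

__all__ = [
    "FluorescenceOpts",
    "GroundTruthSpec",
    "sample_raster",
    "gen_fluorescence",
    "binary_summary_stats",
]


@dataclass
class FluorescenceOpts:
    """Forward dF/F model: exponential kernel plus i.i.d. Gaussian noise.

    ``unit_amplitude`` is the peak dF/F contributed by a single spike; the
    per-spike amplitude of the calcium indicator is not pinned down by the
    deconvolution convention, so it is a configuration knob with a
    plausible single-spike default.
    """

    frame_rate_hz: float = 3.9
    kernel_tau_s: float = 2.0
    unit_amplitude: float = 0.10
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.frame_rate_hz <= 0 or self.kernel_tau_s <= 0:
            raise ValueError("frame rate and kernel tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruthSpec:
    """Specification for one synthetic animal-equivalent recording."""

    pop_params: PopulationLogisticParams
    n_neurons: int = 100
    n_bins: int = 2000
    fluorescence_opts: FluorescenceOpts = field(default_factory=FluorescenceOpts)
    q_thresh: float = Q_THRESH_DEFAULT
    seed: int | None = None

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        cov = self.pop_params.covariance
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise ValueError("population covariance must be positive "
                             "semi-definite")


def sample_raster(spec: GroundTruthSpec):
    """Sample (ON-probability raster, binary raster), each neurons x bins.

    Per-neuron (threshold, slope) is drawn once (neuron identity is fixed
    across time); the drive f_t ~ N(0,1) is i.i.d. across 1-s bins; the
    binary raster is conditionally independent Bernoulli given the
    probabilities.  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    thresh, slope = spec.pop_params.sample(spec.n_neurons, rng)
    f = rng.standard_normal(spec.n_bins)
    q = q_from_threshold(f[None, :], slope[:, None], thresh[:, None],
                         spec.q_thresh)
    binary = (rng.random(q.shape) < q).astype(np.int8)
    return q, binary


def gen_fluorescence(binary, spec: GroundTruthSpec):
    """Forward model from a binary raster to dF/F-like traces.

    Each spike is placed uniformly at random within its 1-s bin on the
    frame grid, convolved with a unit-amplitude exponential kernel
    exp(-t/tau), and i.i.d. Gaussian noise is added.  Output has
    floor(n_bins * frame_rate) frames per neuron.  The trace is generated
    already baselined (zero-mean noise around zero resting level).
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValueError("binary raster must be 2D (neurons x bins)")
    opts = spec.fluorescence_opts
    fs, tau = opts.frame_rate_hz, opts.kernel_tau_s
    n_neurons, n_bins = binary.shape
    n_frames = int(np.floor(n_bins * fs))
    # spike placement uses a seeded stream independent of the raster draw
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(1)[0] if spec.seed is not None
        else None)

    kernel_len = min(n_frames, int(np.ceil(10 * tau * fs)) + 1)
    kernel = opts.unit_amplitude * np.exp(-np.arange(kernel_len) / (tau * fs))

    # frame edges of the 1-s bins, shared with the rate aggregation step
    edges = np.floor(np.arange(n_bins + 1) * fs).astype(int)
    traces = np.zeros((n_neurons, n_frames))
    for i in range(n_neurons):
        bins = np.nonzero(binary[i])[0]
        if bins.size:
            lo, hi = edges[bins], edges[bins + 1]
            frames = lo + np.floor(rng.random(bins.size)
                                   * np.maximum(hi - lo, 1)).astype(int)
            frames = frames[frames < n_frames]
            impulses = np.zeros(n_frames)
            np.add.at(impulses, frames, 1.0)
            traces[i] = np.convolve(impulses, kernel)[:n_frames]
    if opts.noise_sd > 0:
        traces += rng.normal(0.0, opts.noise_sd, traces.shape)
    return traces


def binary_summary_stats(binary) -> ActivityStatistics:
    """Mean/s.d. of per-neuron rates and mean pairwise Pearson correlation
    computed on a hard binary raster (used by fit validation)."""
    binary = np.asarray(binary, dtype=float)
    n_neurons, n_bins = binary.shape
    rates = binary.mean(axis=1)
    sd = float(rates.std(ddof=1)) if n_neurons > 1 else 0.0
    sds = binary.std(axis=1)
    good = sds > 0
    flagged = 0
    if good.sum() >= 2:
        c = np.corrcoef(binary[good])
        iu = np.triu_indices_from(c, k=1)
        mean_corr = float(c[iu].mean())
        flagged = int(n_neurons * (n_neurons - 1) // 2 - len(iu[0]))
    else:
        mean_corr, flagged = np.nan, n_neurons * (n_neurons - 1) // 2
    return ActivityStatistics(mean_rate=float(rates.mean()), sd_rate=sd,
                              mean_corr=mean_corr, n_neurons=n_neurons,
                              n_bins=n_bins, corr_flagged_pairs=flagged)
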