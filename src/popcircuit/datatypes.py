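"""Shared lightweight containers used across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class ActivityStatistics:
    """Three summary statistics of binary population activity.

    mean_rate : mean per-bin ON probability across neurons, in [0, 1]
    sd_rate   : s.d. across neurons of per-neuron mean ON probability
    mean_corr : mean pairwise correlation over all neuron pairs
    """

    mean_rate: float
    sd_rate: float
    mean_corr: float
    n_neurons: int | None = None
    n_bins: int | None = None
    corr_flagged_pairs: int = 0

    def __post_init__(self):
        if not (0.0 <= self.mean_rate <= 1.0):
            raise ValueError("mean_rate must lie in [0, 1]")
        if self.sd_rate < 0:
            raise ValueError("sd_rate must be >= 0")
        if not (-1.0 <= self.mean_corr <= 1.0) and np.isfinite(self.mean_corr):
            raise ValueError("mean_corr must lie in [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_rate, self.sd_rate, self.mean_corr])

    def to_dict(self) -> dict:
        return asdict(self)
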