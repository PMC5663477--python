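"""Plain-text file formats: TSV rasters with JSON sidecar metadata,
stats/fit JSON, and YAML configuration loading."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ActivityStatistics
from .population import PopulationLogisticParams
from .synth import FluorescenceOpts, GroundTruthSpec

__all__ = [
    "write_raster", "read_raster", "write_json", "read_json",
    "ground_truth_spec_from_dict", "load_ground_truth_spec",
]


def write_raster(path, matrix, meta: dict | None = None):
    """Write a neurons x bins matrix as TSV (+ optional .meta.json sidecar)."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(matrix))
    df.index.name = "neuron"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_raster(path):
    """Read a TSV raster; returns (array, metadata dict or None)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = None
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return df.to_numpy(), meta


def write_json(path, obj):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(type(o).__name__)
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def ground_truth_spec_from_dict(cfg: dict, seed=None) -> GroundTruthSpec:
    pop = PopulationLogisticParams(**cfg["pop_params"])
    fl = FluorescenceOpts(**cfg.get("fluorescence_opts", {}))
    return GroundTruthSpec(
        pop_params=pop,
        n_neurons=int(cfg.get("n_neurons", 100)),
        n_bins=int(cfg.get("n_bins", 2000)),
        fluorescence_opts=fl,
        seed=cfg.get("seed", seed))


def load_ground_truth_spec(path, seed=None) -> GroundTruthSpec:
    with open(path) as fh:
        return ground_truth_spec_from_dict(yaml.safe_load(fh), seed=seed)


def stats_to_json(path, stats: ActivityStatistics):
    write_json(path, stats.to_dict())
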