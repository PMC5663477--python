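"""Circuit parameter set for the L2/3 barrel-cortex model.

The default values (cell counts, intrinsic properties, synaptic statistics
and connectivity of the four L2/3 populations plus the L4 drive) are
shipped as ``data/circuit_defaults.yaml``.  This module also implements the +/-20%
single-parameter perturbation rules used by the sensitivity sweep:

* quantities that naturally start at zero (counts, probabilities, time
  constants, resistances, PSP amplitudes) move multiplicatively;
* resting voltage moves by the stated fraction of its gap to spike
  threshold; spike threshold moves by the same fraction of that gap away
  from rest; excitatory reversal scales its distance from rest; inhibitory
  reversals scale their distance from spike threshold;
* the mean and median of each log-normal PSP amplitude pair move in
  tandem.

Refractory periods and the six structurally absent connections are not
part of the sweep, leaving 76 perturbable parameters.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

log = logging.getLogger(__name__)

CELL_TYPES = ("E", "Ipv", "I5ht", "Isom")
PRE_TYPES = ("EL4",) + CELL_TYPES
#: connections absent from the circuit (kept at zero in the sweep)
ZERO_CONNECTIONS = frozenset({
    ("EL4", "I5ht"), ("Ipv", "Isom"), ("I5ht", "Isom"),
    ("Isom", "Ipv"), ("Isom", "I5ht"), ("Isom", "Isom"),
})
INHIBITORY_TYPES = frozenset({"Ipv", "I5ht", "Isom"})


@dataclass
class CellParams:
    n: int
    vrest: float
    vth: float
    rin: float
    tref: float
    taum: float
    tausyn_e: float
    tausyn_i: float
    erev_i: float


@dataclass
class ConnParams:
    pcon: float
    prel: float = 0.0
    w_mean: float = 0.0
    w_median: float = 0.0


@dataclass
class CircuitParams:
    cells: dict = field(default_factory=dict)         # type -> CellParams
    n_l4: int = 1500
    erev_e: float = 0.0
    connections: dict = field(default_factory=dict)   # (pre, post) -> ConnParams
    psp_cap: float = 8.0
    dt: float = 0.01
    trial_duration: float = 50.0
    l4_jitter_sd: float = 2.0
    l4_center: float = 25.0
    scale: float = 1.0
    scale_compensate: bool = True

    def validate(self):
        if self.dt <= 0 or self.trial_duration <= 0:
            raise ValueError("dt and trial duration must be > 0")
        if not (0 < self.scale <= 1.0):
            raise ValueError("scale must lie in (0, 1]")
        for t, c in self.cells.items():
            if c.rin <= 0 or c.taum <= 0 or c.tausyn_e <= 0 or c.tausyn_i <= 0:
                raise ValueError(f"time constants and Rin must be > 0 ({t})")
            if c.vrest >= c.vth:
                raise ValueError(f"Vrest must lie below Vth ({t})")
        for (pre, post), conn in self.connections.items():
            if not (0.0 <= conn.pcon <= 1.0 and 0.0 <= conn.prel <= 1.0):
                raise ValueError(f"probabilities out of [0,1] ({pre}->{post})")
            if conn.pcon > 0 and conn.w_mean < conn.w_median:
                raise ValueError(
                    f"log-normal requires |w| mean >= median ({pre}->{post})")
            if (pre, post) in ZERO_CONNECTIONS and conn.pcon != 0:
                raise ValueError(
                    f"structurally absent connection {pre}->{post} must stay 0")
        return self

    # -- scaled population sizes ------------------------------------------

    def n_of(self, t: str) -> int:
        if t == "EL4":
            return max(1, int(round(self.n_l4 * self.scale)))
        return max(1, int(round(self.cells[t].n * self.scale)))

    def weight_factor(self) -> float:
        """Amplitude compensation applied to PSP draws at reduced scale.

        Shrinking every population by ``scale`` shrinks each neuron's
        expected synaptic input by the same factor; multiplying amplitudes
        by 1/scale restores the mean-field drive (the fluctuations grow,
        which is the cost of the smaller network).
        """
        return 1.0 / self.scale if (self.scale_compensate and self.scale < 1) else 1.0

    def copy(self) -> "CircuitParams":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return asdict(self)


def default_params(scale=1.0, scale_compensate=True) -> CircuitParams:
    """Load the packaged default circuit configuration."""
    with resources.files("popcircuit.data").joinpath("circuit_defaults.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return params_from_dict(raw, scale=scale, scale_compensate=scale_compensate)


def params_from_dict(raw: dict, scale=1.0, scale_compensate=True) -> CircuitParams:
    cells = {t: CellParams(**raw["populations"][t]) for t in CELL_TYPES}
    conns = {}
    for pre, posts in raw["connections"].items():
        for post, cfg in posts.items():
            conns[(pre, post)] = ConnParams(**cfg)
    integ = raw.get("integration", {})
    p = CircuitParams(
        cells=cells, n_l4=int(raw["n_l4"]), erev_e=float(raw["erev_e"]),
        connections=conns, psp_cap=float(raw.get("psp_cap_mv", 8.0)),
        dt=float(integ.get("dt_ms", 0.01)),
        trial_duration=float(integ.get("trial_ms", 50.0)),
        l4_jitter_sd=float(integ.get("l4_jitter_sd_ms", 2.0)),
        l4_center=float(integ.get("l4_center_ms", 25.0)),
        scale=scale, scale_compensate=scale_compensate,
    )
    return p.validate()


def params_from_yaml(path, **kw) -> CircuitParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh), **kw)


# ---------------------------------------------------------------------------
# the 76-parameter sweep
# ---------------------------------------------------------------------------

def sweep_parameter_names() -> list[str]:
    """All 76 perturbable parameter identifiers."""
    names = ["N_EL4"] + [f"N_{t}" for t in CELL_TYPES]
    for t in CELL_TYPES:
        names += [f"Vrest_{t}", f"Vth_{t}", f"Rin_{t}", f"taum_{t}",
                  f"tausyn_{t}_e", f"tausyn_{t}_i", f"Erev_{t}_i"]
    names += ["Erev_e"]
    for pre in PRE_TYPES:
        for post in CELL_TYPES:
            if (pre, post) in ZERO_CONNECTIONS:
                continue
            if (pre, post) not in _ALL_CONNECTIONS:
                continue
            names += [f"pcon_{pre}{post}", f"prel_{pre}{post}", f"w_{pre}{post}"]
    return names


_ALL_CONNECTIONS = {
    ("EL4", "E"), ("EL4", "Ipv"), ("EL4", "Isom"),
    ("E", "E"), ("E", "Ipv"), ("E", "I5ht"), ("E", "Isom"),
    ("Ipv", "E"), ("Ipv", "Ipv"), ("Ipv", "I5ht"),
    ("I5ht", "E"), ("I5ht", "Ipv"), ("I5ht", "I5ht"),
    ("Isom", "E"),
}


def _split_conn(tag: str):
    for pre in PRE_TYPES:
        if tag.startswith(pre):
            post = tag[len(pre):]
            if post in CELL_TYPES:
                return pre, post
    raise KeyError(tag)


def perturb_params(params: CircuitParams, name: str | None,
                   direction: float) -> CircuitParams:
    """Return a copy of ``params`` with one parameter moved by +/-20%.

    ``direction`` is the signed fraction (+0.2 or -0.2); ``name=None`` (or
    ``"null"``) returns an unmodified copy, the null perturbation.
    Probabilities pushed above 1 are clamped with a logged warning.
    """
    p = params.copy()
    if name is None or name == "null":
        return p
    if name not in set(sweep_parameter_names()):
        raise KeyError(f"unknown or non-perturbable parameter: {name}")
    d = float(direction)

    if name == "N_EL4":
        p.n_l4 = max(1, int(round(p.n_l4 * (1 + d))))
    elif name.startswith("N_"):
        c = p.cells[name[2:]]
        c.n = max(1, int(round(c.n * (1 + d))))
    elif name.startswith("Vrest_"):
        c = p.cells[name[6:]]
        c.vrest = c.vrest + d * (c.vth - c.vrest)
    elif name.startswith("Vth_"):
        c = p.cells[name[4:]]
        c.vth = c.vth + d * (c.vth - c.vrest)
    elif name.startswith("Rin_"):
        p.cells[name[4:]].rin *= (1 + d)
    elif name.startswith("taum_"):
        p.cells[name[5:]].taum *= (1 + d)
    elif name.startswith("tausyn_"):
        t, kind = name[7:].rsplit("_", 1)
        if kind == "e":
            p.cells[t].tausyn_e *= (1 + d)
        else:
            p.cells[t].tausyn_i *= (1 + d)
    elif name == "Erev_e":
        vr = p.cells["E"].vrest
        p.erev_e = vr + (1 + d) * (p.erev_e - vr)
    elif name.startswith("Erev_"):
        t = name[5:-2]
        c = p.cells[t]
        c.erev_i = c.vth + (1 + d) * (c.erev_i - c.vth)
    elif name.startswith("pcon_"):
        conn = p.connections[_split_conn(name[5:])]
        new = conn.pcon * (1 + d)
        if new > 1.0:
            log.warning("pcon perturbation clamped to 1.0 (%s)", name)
            new = 1.0
        conn.pcon = new
    elif name.startswith("prel_"):
        conn = p.connections[_split_conn(name[5:])]
        new = conn.prel * (1 + d)
        if new > 1.0:
            log.warning("prel perturbation clamped to 1.0 (%s)", name)
            new = 1.0
        conn.prel = new
    elif name.startswith("w_"):
        conn = p.connections[_split_conn(name[2:])]
        conn.w_mean *= (1 + d)
        conn.w_median *= (1 + d)
    else:  # pragma: no cover
        raise KeyError(name)
    return p.validate()
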