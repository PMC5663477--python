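"""Conductance-based LIF network model of the L2/3 barrel circuit.

Four reciprocally connected populations (excitatory, PV, 5HT3aR and SOM
interneurons) are driven by a volley of single spikes from a fraction of
L4 excitatory cells.  Membrane voltage follows

    dV/dt = ( ge*(Erev_e - V) + gi*(Erev_i - V) - (V - Vrest) ) / taum

with synaptic conductances expressed in units of each neuron's leak
conductance (1/Rin), decaying exponentially between spikes and incremented
instantaneously on probabilistic (Bernoulli-release) synaptic events.
Connectivity is Bernoulli per connection class; per-synapse PSP amplitudes
are log-normal, constrained by the reported mean and median and capped at
8 mV, then converted to peak conductances analytically.

A trial integrates 50 ms with forward Euler at dt = 0.01 ms and scores
each neuron 1 if it crossed threshold at least once (extra spikes are
disregarded).  A neuron's ON probability q(f) is the fraction of
10 ON-subset permutations x 10 release repeats = 100 trials with a spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .logistic import LogisticFit, fit_logistic
from .params import (CELL_TYPES, INHIBITORY_TYPES, CircuitParams,
                     perturb_params, sweep_parameter_names)

__all__ = [
    "psp_to_conductance",
    "NetworkRealization",
    "build_network",
    "run_trial",
    "StimulusProtocol",
    "ResponseProbabilities",
    "response_curve",
    "fit_response_curves",
    "sweep_sensitivity",
    "default_f_levels",
]

IPSP_HOLDING_MV = -55.0


def psp_peak_per_unit_g(driving_mv, taum, tausyn):
    """Analytic PSP peak (mV) of the linearized single-synapse response per
    unit peak conductance (leak units).

    The voltage response to g(t) = exp(-t/tausyn) is bi-exponential with
    peak at t* = taum*tausyn*ln(taum/tausyn)/(taum-tausyn); in the
    degenerate limit tausyn == taum it collapses to the alpha function with
    peak driving/e.
    """
    if abs(taum - tausyn) < 1e-9 * taum:
        return driving_mv / np.e
    tstar = taum * tausyn * np.log(taum / tausyn) / (taum - tausyn)
    shape = tausyn / (taum - tausyn) * (np.exp(-tstar / taum)
                                        - np.exp(-tstar / tausyn))
    return driving_mv * shape


def psp_to_conductance(psp_mv, post_type, syn_kind, params: CircuitParams):
    """Peak conductance (in units of the target's leak conductance) that
    produces a PSP of ``psp_mv`` at the stated holding potential.

    EPSP driving force is evaluated at the target's resting potential;
    IPSP driving force at -55 mV.  Linear in ``psp_mv``.
    """
    if np.any(np.asarray(psp_mv) < 0):
        raise ValueError("psp_mv is a magnitude, must be >= 0")
    c = params.cells[post_type]
    if syn_kind == "e":
        driving = params.erev_e - c.vrest
        tausyn = c.tausyn_e
    elif syn_kind == "i":
        driving = IPSP_HOLDING_MV - c.erev_i   # magnitude of hyperpolarization
        tausyn = c.tausyn_i
    else:
        raise ValueError("syn_kind must be 'e' or 'i'")
    peak = psp_peak_per_unit_g(abs(driving), c.taum, tausyn)
    return np.asarray(psp_mv, dtype=float) / peak


@dataclass
class NetworkRealization:
    """One sampled connectivity realization in CSR-by-presynaptic form.

    Presynaptic index space is L4 cells (0..n_l4-1) followed by L2/3 cells
    (n_l4..n_l4+n_l23-1); targets index L2/3 cells only.
    """

    n_l4: int
    n_l23: int
    type_codes: np.ndarray        # (n_l23,) int8 index into CELL_TYPES
    indptr: np.ndarray
    targets: np.ndarray
    g: np.ndarray                 # peak conductances, leak units
    amp_mv: np.ndarray            # drawn PSP amplitudes (pre-conversion)
    prel: np.ndarray
    inh: np.ndarray               # uint8, 1 if the synapse is inhibitory
    build_seed: int | None = None
    class_counts: dict = field(default_factory=dict)

    @property
    def type_slices(self):
        out, start = {}, 0
        for ti, t in enumerate(CELL_TYPES):
            n = int((self.type_codes == ti).sum())
            out[t] = slice(start, start + n)
            start += n
        return out


def build_network(params: CircuitParams, seed=None) -> NetworkRealization:
    """Sample Bernoulli connectivity and log-normal synaptic amplitudes.

    Log-normal location is ln(median) and ln-scale variance
    2*ln(mean/median); amplitudes are capped at ``psp_cap`` before
    conductance conversion.  Deterministic per seed.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    counts = {t: params.n_of(t) for t in CELL_TYPES}
    n_l4 = params.n_of("EL4")
    n_l23 = sum(counts.values())
    type_codes = np.concatenate([
        np.full(counts[t], ti, dtype=np.int8)
        for ti, t in enumerate(CELL_TYPES)])
    offsets = {}
    start = 0
    for t in CELL_TYPES:
        offsets[t] = start
        start += counts[t]

    wf = params.weight_factor()
    pre_lists: list = [[] for _ in range(n_l4 + n_l23)]
    class_counts = {}
    for (pre, post), conn in params.connections.items():
        if conn.pcon <= 0:
            class_counts[(pre, post)] = 0
            continue
        if conn.w_mean < conn.w_median:
            raise ValueError("log-normal pair needs mean >= median")
        n_pre = n_l4 if pre == "EL4" else counts[pre]
        n_post = counts[post]
        pre_base = 0 if pre == "EL4" else n_l4 + offsets[pre]
        post_base = offsets[post]
        mask = rng.random((n_pre, n_post)) < conn.pcon
        if pre == post:
            np.fill_diagonal(mask, False)   # no self-synapses
        pre_idx, post_idx = np.nonzero(mask)
        n_syn = pre_idx.size
        class_counts[(pre, post)] = int(n_syn)
        if n_syn == 0:
            continue
        sigma2 = 2.0 * np.log(conn.w_mean / conn.w_median) \
            if conn.w_mean > conn.w_median else 0.0
        if sigma2 > 0:
            amps = rng.lognormal(np.log(conn.w_median * wf),
                                 np.sqrt(sigma2), size=n_syn)
        else:
            amps = np.full(n_syn, conn.w_median * wf)
        amps = np.minimum(amps, params.psp_cap)
        kind = "i" if pre in INHIBITORY_TYPES else "e"
        g = psp_to_conductance(amps, post, kind, params)
        is_inh = 1 if kind == "i" else 0
        for s in range(n_syn):
            pre_lists[pre_base + pre_idx[s]].append(
                (post_base + post_idx[s], g[s], amps[s], conn.prel, is_inh))

    total = sum(len(l) for l in pre_lists)
    indptr = np.zeros(n_l4 + n_l23 + 1, dtype=np.int64)
    targets = np.empty(total, dtype=np.int64)
    gvals = np.empty(total, dtype=np.float64)
    amp = np.empty(total, dtype=np.float64)
    prel = np.empty(total, dtype=np.float64)
    inh = np.empty(total, dtype=np.uint8)
    pos = 0
    for i, lst in enumerate(pre_lists):
        for (tgt, gv, av, pr, ih) in lst:
            targets[pos], gvals[pos], amp[pos] = tgt, gv, av
            prel[pos], inh[pos] = pr, ih
            pos += 1
        indptr[i + 1] = pos
    return NetworkRealization(
        n_l4=n_l4, n_l23=n_l23, type_codes=type_codes, indptr=indptr,
        targets=targets, g=gvals, amp_mv=amp, prel=prel, inh=inh,
        build_seed=seed, class_counts=class_counts)


@njit(cache=True)
def _simulate(n_steps, dt, vrest, vth, taum, tref_steps, dec_e, dec_i,
              erev_e, erev_i, indptr, targets, gvals, prels, inh,
              l4_steps, l4_ids, n_l4, seed, v0):
    np.random.seed(seed)
    n = vrest.shape[0]
    V = v0.copy()
    ge = np.zeros(n)
    gi = np.zeros(n)
    refr = np.zeros(n, np.int64)
    spiked = np.zeros(n, np.uint8)
    new_spikes = np.empty(n, np.int64)
    ptr = 0
    n_events = l4_steps.shape[0]
    for step in range(n_steps):
        n_new = 0
        for i in range(n):
            ge[i] *= dec_e[i]
            gi[i] *= dec_i[i]
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = vrest[i]
                continue
            dv = (ge[i] * (erev_e - V[i]) + gi[i] * (erev_i[i] - V[i])
                  - (V[i] - vrest[i])) / taum[i]
            V[i] += dt * dv
            if V[i] >= vth[i]:
                spiked[i] = 1
                V[i] = vrest[i]
                refr[i] = tref_steps[i]
                new_spikes[n_new] = i
                n_new += 1
        # L4 volley events scheduled for this step
        while ptr < n_events and l4_steps[ptr] == step:
            pre = l4_ids[ptr]
            ptr += 1
            for s in range(indptr[pre], indptr[pre + 1]):
                if np.random.random() < prels[s]:
                    t = targets[s]
                    if inh[s] == 1:
                        gi[t] += gvals[s]
                    else:
                        ge[t] += gvals[s]
        # recurrent spikes from this step
        for j in range(n_new):
            pre = n_l4 + new_spikes[j]
            for s in range(indptr[pre], indptr[pre + 1]):
                if np.random.random() < prels[s]:
                    t = targets[s]
                    if inh[s] == 1:
                        gi[t] += gvals[s]
                    else:
                        ge[t] += gvals[s]
    return spiked, V


def _neuron_arrays(net: NetworkRealization, params: CircuitParams):
    tc = net.type_codes
    def per_type(attr):
        vals = np.array([getattr(params.cells[t], attr) for t in CELL_TYPES])
        return vals[tc]
    dt = params.dt
    vrest = per_type("vrest")
    vth = per_type("vth")
    taum = per_type("taum")
    tref_steps = np.round(per_type("tref") / dt).astype(np.int64)
    dec_e = np.exp(-dt / per_type("tausyn_e"))
    dec_i = np.exp(-dt / per_type("tausyn_i"))
    erev_i = per_type("erev_i")
    return vrest, vth, taum, tref_steps, dec_e, dec_i, erev_i


def run_trial(net: NetworkRealization, l4_active, params: CircuitParams,
              seed, l4_times_ms=None, v_init=None):
    """Integrate one 50 ms trial; returns the binary spike indicator.

    ``l4_active`` indexes the L4 cells emitting one spike each; spike times
    default to N(l4_center, l4_jitter_sd) draws clipped into the trial
    window (drawn from ``seed``; pass ``l4_times_ms`` to pin them).  The
    release Bernoulli stream is also derived from ``seed``.
    """
    l4_active = np.asarray(l4_active, dtype=np.int64)
    if l4_active.size and (l4_active.min() < 0 or l4_active.max() >= net.n_l4):
        raise ValueError("l4_active must index L4 cells")
    n_steps = int(round(params.trial_duration / params.dt))
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if l4_times_ms is None:
        l4_times_ms = rng.normal(params.l4_center, params.l4_jitter_sd,
                                 l4_active.size)
    l4_steps = np.clip(np.round(np.asarray(l4_times_ms) / params.dt),
                       0, n_steps - 1).astype(np.int64)
    order = np.argsort(l4_steps, kind="stable")
    release_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))
    vrest, vth, taum, tref_steps, dec_e, dec_i, erev_i = \
        _neuron_arrays(net, params)
    v0 = vrest.copy() if v_init is None else np.asarray(v_init, dtype=float)
    spiked, _ = _simulate(
        n_steps, params.dt, vrest, vth, taum, tref_steps, dec_e, dec_i,
        params.erev_e, erev_i, net.indptr, net.targets, net.g, net.prel,
        net.inh, l4_steps[order], l4_active[order], net.n_l4,
        release_seed, v0)
    return spiked.astype(bool)


def relax_voltages(net: NetworkRealization, params: CircuitParams, v_init,
                   duration_ms):
    """Passive relaxation (no input) from ``v_init``; returns final V.

    Exposes the leak dynamics for validation against the closed form."""
    n_steps = int(round(duration_ms / params.dt))
    vrest, vth, taum, tref_steps, dec_e, dec_i, erev_i = \
        _neuron_arrays(net, params)
    _, V = _simulate(
        n_steps, params.dt, vrest, vth + 1e6, taum, tref_steps, dec_e, dec_i,
        params.erev_e, erev_i, net.indptr, net.targets, net.g, net.prel,
        net.inh, np.empty(0, np.int64), np.empty(0, np.int64), net.n_l4,
        1, np.asarray(v_init, dtype=float))
    return V


def default_f_levels(n_levels=13):
    """Default L4 activation fractions: an even grid over [0, 1].

    The q(f) transition of the default circuit sits at intermediate L4
    fractions, so the grid spans the full range to bracket it at any
    population scale."""
    return np.linspace(0.0, 1.0, n_levels)


@dataclass
class StimulusProtocol:
    l4_fractions: np.ndarray = field(default_factory=default_f_levels)
    n_permutations: int = 10
    n_release_repeats: int = 10
    seed: int | None = None

    def __post_init__(self):
        f = np.asarray(self.l4_fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fractions must be sorted and unique")
        self.l4_fractions = f


@dataclass
class ResponseProbabilities:
    f_levels: np.ndarray
    q: np.ndarray                 # (n_neurons, n_levels)
    type_codes: np.ndarray
    n_trials: int

    def for_type(self, t: str):
        return self.q[self.type_codes == CELL_TYPES.index(t)]


def response_curve(net: NetworkRealization, protocol: StimulusProtocol,
                   params: CircuitParams) -> ResponseProbabilities:
    """ON probability per neuron per L4 activation level.

    For each level, ``n_permutations`` random ON-subsets of L4 are drawn
    (with fresh spike-time jitter per subset) and each is simulated
    ``n_release_repeats`` times with independent release noise; q is the
    fraction of those trials with >= 1 spike.
    """
    f = protocol.l4_fractions
    n_trials = protocol.n_permutations * protocol.n_release_repeats
    q = np.zeros((net.n_l23, f.size))
    root = np.random.SeedSequence(protocol.seed)
    level_seeds = root.spawn(f.size)
    for li, frac in enumerate(f):
        n_on = int(round(frac * net.n_l4))
        acc = np.zeros(net.n_l23)
        for ss in level_seeds[li].spawn(protocol.n_permutations):
            rng = np.random.default_rng(ss)
            subset = rng.choice(net.n_l4, size=n_on, replace=False)
            times = rng.normal(params.l4_center, params.l4_jitter_sd, n_on)
            rep_seeds = ss.generate_state(protocol.n_release_repeats,
                                          np.uint32) % (2**31 - 1)
            for rs in rep_seeds:
                acc += run_trial(net, subset, params, int(rs),
                                 l4_times_ms=times)
        q[:, li] = acc / n_trials
    return ResponseProbabilities(f_levels=f, q=q, type_codes=net.type_codes,
                                 n_trials=n_trials)


def fit_response_curves(resp: ResponseProbabilities) -> list[LogisticFit]:
    """Per-neuron logistic fits of q(f), flagged where degenerate."""
    counts = np.round(resp.q * resp.n_trials).astype(int)
    trials = np.full(resp.f_levels.size, resp.n_trials)
    return [fit_logistic(resp.f_levels, counts[i], trials,
                         domain="l4_fraction")
            for i in range(resp.q.shape[0])]


def _mean_slope_thresh(fits, mask):
    sel = [f for f, m in zip(fits, mask) if m and f.valid
           and np.isfinite(f.f_thresh)]
    if not sel:
        return np.nan, np.nan, 0
    return (float(np.mean([f.beta for f in sel])),
            float(np.mean([f.f_thresh for f in sel])), len(sel))


def sweep_sensitivity(params: CircuitParams, names, protocol=None,
                      n_seeds=3, directions=(0.2, -0.2),
                      master_seed=0) -> pd.DataFrame:
    """Mean (slope, threshold) shift of excitatory neurons per perturbation.

    For each parameter and direction the network is rebuilt and restimulated
    with the *same* seeds as the default run (variance reduction), each
    neuron refit, and the shift of the excitatory-population mean reported,
    averaged over ``n_seeds`` independent seed pairs.  ``names`` may include
    ``None`` (the null perturbation).  Degenerate fits are excluded and
    counted.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    valid = set(sweep_parameter_names())
    for nm in names:
        if nm not in (None, "null") and nm not in valid:
            raise KeyError(nm)

    seed_pairs = [(int(s.generate_state(1)[0] % (2**31 - 1)),
                   int(s.generate_state(2)[1] % (2**31 - 1)))
                  for s in np.random.SeedSequence(master_seed).spawn(n_seeds)]

    base = []
    for bs, ps in seed_pairs:
        net = build_network(params, seed=bs)
        proto = StimulusProtocol(protocol.l4_fractions,
                                 protocol.n_permutations,
                                 protocol.n_release_repeats, seed=ps)
        fits = fit_response_curves(response_curve(net, proto, params))
        is_e = net.type_codes == 0
        base.append(_mean_slope_thresh(fits, is_e))

    rows = []
    for nm in names:
        for d in directions:
            d_slopes, d_threshs, n_valids = [], [], []
            for (bs, ps), (b_slope, b_thresh, _) in zip(seed_pairs, base):
                p2 = perturb_params(params, nm, d)
                net2 = build_network(p2, seed=bs)
                proto = StimulusProtocol(protocol.l4_fractions,
                                         protocol.n_permutations,
                                         protocol.n_release_repeats, seed=ps)
                fits2 = fit_response_curves(response_curve(net2, proto, p2))
                s2, t2, nv = _mean_slope_thresh(fits2,
                                                net2.type_codes == 0)
                d_slopes.append(s2 - b_slope)
                d_threshs.append(t2 - b_thresh)
                n_valids.append(nv)
            rows.append({
                "param": "null" if nm in (None, "null") else nm,
                "direction": d,
                "d_slope": float(np.nanmean(d_slopes)),
                "d_thresh": float(np.nanmean(d_threshs)),
                "d_slope_sd": float(np.nanstd(d_slopes, ddof=1))
                if len(d_slopes) > 1 else np.nan,
                "d_thresh_sd": float(np.nanstd(d_threshs, ddof=1))
                if len(d_threshs) > 1 else np.nan,
                "n_valid_neurons": float(np.mean(n_valids)),
                "n_seeds": n_seeds,
            })
    return pd.DataFrame(rows)
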