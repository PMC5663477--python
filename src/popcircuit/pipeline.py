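"""End-to-end synthetic-cohort pipeline.

Generates ground-truth-known rasters for several animal-equivalents per
group (e.g. genotype x age), computes per-animal activity statistics, fits
the population logistic model, evaluates local sensitivities and entropy,
and runs bootstrap group comparisons with confidence ellipses.  Every
stochastic stage receives a seed derived deterministically from the master
seed, so a rerun reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calcium import CalciumBinarizer, summary_stats
from .datatypes import ActivityStatistics
from .group_stats import bootstrap_mean_diff, mean_diff_ellipse
from .io import write_json
from .logistic import local_sensitivity
from .population import PopulationLogisticModel, PopulationLogisticParams
from .poptrack import entropy_vs_N
from .synth import (FluorescenceOpts, GroundTruthSpec, binary_summary_stats,
                    gen_fluorescence, sample_raster)

log = logging.getLogger(__name__)

__all__ = ["GroupSpec", "CohortSpec", "run_cohort"]

DEFAULT_STAGES = ("raster", "stats", "popfit", "sensitivity")
ALL_STAGES = ("raster", "stats", "calcium", "popfit", "sensitivity",
              "entropy")


@dataclass
class GroupSpec:
    label: str
    n_animals: int
    pop_params: PopulationLogisticParams
    n_neurons: int = 100
    n_bins: int = 2000
    fluorescence_opts: FluorescenceOpts = field(default_factory=FluorescenceOpts)


@dataclass
class CohortSpec:
    groups: list
    master_seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


def _animal_seed(master_seed, gi, ai):
    ss = np.random.SeedSequence(master_seed, spawn_key=(gi, ai))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_cohort(spec: CohortSpec, stages=DEFAULT_STAGES, outdir=None,
               fit_kwargs=None, entropy_kwargs=None,
               n_boot=10_000) -> dict:
    """Execute the selected stages for every animal, then group statistics.

    Stage failures isolate the affected animal (logged, recorded in its
    result) and the run continues.  Returns the results bundle; if
    ``outdir`` is given, per-animal and group JSON files plus a manifest
    are written there.
    """
    for st in stages:
        if st not in ALL_STAGES:
            raise ValueError(f"unknown stage: {st}")
    fit_kwargs = dict(fit_kwargs or {})
    entropy_kwargs = dict(entropy_kwargs or {})

    animals = []
    for gi, group in enumerate(spec.groups):
        for ai in range(group.n_animals):
            seed = _animal_seed(spec.master_seed, gi, ai)
            rec = {"group": group.label, "animal": ai, "seed": seed}
            try:
                gt = GroundTruthSpec(
                    pop_params=group.pop_params, n_neurons=group.n_neurons,
                    n_bins=group.n_bins,
                    fluorescence_opts=group.fluorescence_opts, seed=seed)
                q_raster = binary = None
                if "raster" in stages:
                    q_raster, binary = sample_raster(gt)
                if "stats" in stages and binary is not None:
                    rec["stats"] = binary_summary_stats(binary).to_dict()
                if "calcium" in stages and binary is not None:
                    dff = gen_fluorescence(binary, gt)
                    pon = CalciumBinarizer(
                        frame_rate=gt.fluorescence_opts.frame_rate_hz,
                        kernel_tau_s=gt.fluorescence_opts.kernel_tau_s,
                    ).fit(dff).transform(dff)
                    rec["calcium_stats"] = summary_stats(pon).to_dict()
                if "popfit" in stages and "stats" in rec:
                    target = ActivityStatistics(
                        rec["stats"]["mean_rate"], rec["stats"]["sd_rate"],
                        rec["stats"]["mean_corr"])
                    model = PopulationLogisticModel(
                        random_state=seed, **fit_kwargs).fit(target)
                    rec["popfit"] = model.report()
                if "sensitivity" in stages and "popfit" in rec:
                    pf = rec["popfit"]["params"]
                    if pf["mu_slope"] > 0:
                        rec["sensitivity"] = local_sensitivity(
                            pf["mu_slope"], pf["mu_thresh"])
                if "entropy" in stages and binary is not None:
                    curve = entropy_vs_N(binary, seed=seed, **entropy_kwargs)
                    rec["entropy"] = {
                        "sizes": curve.sizes.tolist(),
                        "h_per_neuron": curve.h_per_neuron.tolist(),
                        "fit": list(curve.fit) if curve.fit else None,
                        "h100": curve.h100,
                        "converged": curve.converged,
                    }
            except Exception as exc:   # stage failure isolates the animal
                log.error("animal %s/%d failed: %s", group.label, ai, exc)
                rec["error"] = f"{type(exc).__name__}: {exc}"
                rec["traceback"] = traceback.format_exc()
            animals.append(rec)

    comparisons = []
    if len(spec.groups) >= 2 and "stats" in stages:
        labels = [g.label for g in spec.groups]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                comparisons.append(_compare_groups(
                    animals, labels[i], labels[j], stages, n_boot,
                    seed=_animal_seed(spec.master_seed, 10_000 + i, j)))

    manifest = {
        "package_version": __version__,
        "master_seed": spec.master_seed,
        "stages": list(stages),
        "groups": [{"label": g.label, "n_animals": g.n_animals,
                    "n_neurons": g.n_neurons, "n_bins": g.n_bins,
                    "pop_params": g.pop_params.to_dict()}
                   for g in spec.groups],
        "animal_seeds": [{"group": a["group"], "animal": a["animal"],
                          "seed": a["seed"]} for a in animals],
        "n_animal_records": len(animals),
        "n_group_comparisons": len(comparisons),
    }
    bundle = {"manifest": manifest, "animals": animals,
              "comparisons": comparisons}
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "animals").mkdir(parents=True, exist_ok=True)
        for a in animals:
            write_json(outdir / "animals" / f"{a['group']}_{a['animal']}.json",
                       a)
        write_json(outdir / "group_comparisons.json", comparisons)
        write_json(outdir / "manifest.json", manifest)
    return bundle


def _collect(animals, label, path):
    out = []
    for a in animals:
        if a["group"] != label or "error" in a:
            continue
        cur = a
        ok = True
        for key in path:
            if key not in cur:
                ok = False
                break
            cur = cur[key]
        if ok and cur is not None and np.all(np.isfinite(cur)):
            out.append(cur)
    return out


def _compare_groups(animals, label1, label2, stages, n_boot, seed):
    comp = {"group1": label1, "group2": label2, "tests": {}}
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in ss.spawn(16))
    metrics = [("mean_rate", ("stats", "mean_rate")),
               ("sd_rate", ("stats", "sd_rate")),
               ("mean_corr", ("stats", "mean_corr"))]
    if "entropy" in stages:
        metrics.append(("h100", ("entropy", "h100")))
    for name, path in metrics:
        g1 = _collect(animals, label1, path)
        g2 = _collect(animals, label2, path)
        if g1 and g2:
            r = bootstrap_mean_diff(g1, g2, n_boot=n_boot, seed=next(seeds))
            comp["tests"][name] = {"delta_obs": r.delta_obs,
                                   "p_value": r.p_value,
                                   "n1": r.n1, "n2": r.n2}
    if "popfit" in stages:
        pts1 = [[a["popfit"]["params"]["mu_slope"],
                 a["popfit"]["params"]["mu_thresh"]]
                for a in animals
                if a["group"] == label1 and "popfit" in a]
        pts2 = [[a["popfit"]["params"]["mu_slope"],
                 a["popfit"]["params"]["mu_thresh"]]
                for a in animals
                if a["group"] == label2 and "popfit" in a]
        if len(pts1) >= 2 and len(pts2) >= 2:
            ell = mean_diff_ellipse(np.array(pts2), np.array(pts1),
                                    n_boot=min(n_boot, 20_000),
                                    seed=next(seeds))
            comp["slope_thresh_shift_ellipse"] = ell.to_dict()
    return comp
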