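"""End-to-end pipeline: synthesize inputs, then run every analysis stage.

One global seed in the config is split deterministically per stage via
``numpy.random.SeedSequence``, so a rerun with the same config produces
bit-identical outputs; the run directory carries a provenance manifest
(config hash, per-file SHA-256) to verify this.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import community as cs
from . import geochip as gc
from . import io as cio
from . import mend
from . import networks as net
from . import synthetic as syn
from . import traits as tr

__all__ = ["run_pipeline", "load_config", "demo_config", "STAGES"]

STAGES = ("synth", "traits", "geochip", "stats", "network", "mend-sim",
          "calibrate", "warming-effects")
_REQUIRES = {
    "synth": (),
    "traits": ("synth",),
    "geochip": ("synth",),
    "stats": ("synth",),
    "network": ("synth",),
    "mend-sim": ("synth",),
    "calibrate": ("mend-sim",),
    "warming-effects": ("calibrate",),
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def demo_config() -> dict:
    """Small self-contained configuration exercising every stage."""
    return {
        "seed": 1,
        "stages": list(STAGES),
        "community": {"n_taxa": 120, "n_samples_per_group": 12,
                      "depth": 5000, "dispersion_scale": 1.5,
                      "enrichment": {"n_taxa": 20, "fold": 2.0,
                                     "target": "litterbag"}},
        "traits": {"match_fraction": 0.2156},
        "probe": {"n_probes": 200, "detection_rate": 0.8,
                  "effect_map": {"endoglucanase": 1.5, "cellobiase": 1.4,
                                 "axe": 1.3}},
        "stats": {"permutations": 199, "tnst_null_reps": 100},
        "network": {"min_prevalence": 6, "threshold": 0.8},
        "forcing": {"n_days": 730},
        "calibration": {"calibrated": ["Vd", "Ec"], "max_evals": 120,
                        "n_complexes": 2, "substeps_per_day": 1},
    }


def _stage_seed(seed_seq_children, index: int) -> int:
    return int(seed_seq_children[index].generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, outdir=None) -> Path:
    """Run the configured stages; returns the run directory.

    Stage dependencies are validated before any computation.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = list(config.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
        for dep in _REQUIRES[s]:
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires {dep!r} in the run")
    outdir = Path(outdir or config.get("outdir", "cellumend_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    stage_seed = {s: _stage_seed(children, i) for i, s in enumerate(STAGES)}
    ctx: dict = {}

    if "synth" in stages:
        _run_synth(config, ctx, outdir, stage_seed["synth"])
    if "traits" in stages:
        _run_traits(config, ctx, outdir)
    if "geochip" in stages:
        _run_geochip(config, ctx, outdir)
    if "stats" in stages:
        _run_stats(config, ctx, outdir, stage_seed["stats"])
    if "network" in stages:
        _run_network(config, ctx, outdir)
    if "mend-sim" in stages:
        _run_mend_sim(config, ctx, outdir, stage_seed["mend-sim"])
    if "calibrate" in stages:
        _run_calibrate(config, ctx, outdir, stage_seed["calibrate"])
    if "warming-effects" in stages:
        _run_warming(config, ctx, outdir)

    canonical = json.dumps(config, sort_keys=True, default=str)
    files = sorted(p for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "stages": stages,
        "stage_seeds": stage_seed,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir


def _community_design(config, seed) -> syn.SyntheticDesign:
    c = dict(config.get("community", {}))
    enrich = c.pop("enrichment", None)
    n_taxa = c.get("n_taxa", 500)
    effects = ()
    if enrich:
        k = int(enrich.get("n_taxa", 20))
        taxa = tuple(f"zOTU{i + 1}" for i in range(min(k, n_taxa)))
        effects = (syn.EnrichmentEffect(taxa=taxa,
                                        fold=float(enrich.get("fold", 2.0)),
                                        target=enrich.get("target",
                                                          "litterbag")),)
    return syn.SyntheticDesign(seed=seed, enrichment_effects=effects, **c)


def _run_synth(config, ctx, outdir, seed) -> None:
    design = _community_design(config, seed)
    table = syn.gen_paired_communities(design)
    ref = syn.gen_trait_reference(
        design, **config.get("traits", {}))
    probe_cfg = dict(config.get("probe", {}))
    probes = syn.gen_probe_table(
        n_probes=probe_cfg.pop("n_probes", 200), seed=seed + 1,
        n_samples_per_group=design.n_samples_per_group, **probe_cfg)
    fdesign = syn.ForcingDesign(seed=seed + 2, **config.get("forcing", {}))
    forcing_c = syn.gen_forcing(fdesign, warmed=False)
    forcing_w = syn.gen_forcing(fdesign, warmed=True)
    ctx.update(table=table, ref=ref, probes=probes,
               forcing_c=forcing_c, forcing_w=forcing_w, design=design)
    cio.write_community_table(table, outdir / "community.tsv")
    cio.write_trait_reference(ref, outdir / "trait_reference.tsv")
    cio.write_probe_table(probes, outdir / "probes.tsv")
    cio.write_forcing(forcing_c, outdir / "forcing_control.csv")
    cio.write_forcing(forcing_w, outdir / "forcing_warmed.csv")


def _run_traits(config, ctx, outdir) -> None:
    res = tr.community_traits(ctx["table"], ctx["ref"])
    res.to_csv(outdir / "community_traits.tsv", sep="\t")
    ctx["trait_results"] = res


def _run_geochip(config, ctx, outdir) -> None:
    probes = ctx["probes"]
    groups = {g: [s for s in probes.samples if s.startswith(g + "_")]
              for g in syn.GROUPS}
    filtered = gc.filter_probes(probes, groups, min_detect=3)
    normalized = gc.normalize_probes(filtered)
    rr = gc.response_ratio_table(normalized, treatment=groups["WL"],
                                 control=groups["CL"])
    rr.to_csv(outdir / "response_ratios.tsv", sep="\t")
    ctx["probes_normalized"] = normalized
    ctx["rr"] = rr


def _run_stats(config, ctx, outdir, seed) -> None:
    scfg = config.get("stats", {})
    perms = int(scfg.get("permutations", 199))
    table = ctx["table"]
    d = cs.bray_curtis(table)
    pd.DataFrame(d.data, index=d.ids, columns=d.ids).to_csv(
        outdir / "bray_curtis.tsv", sep="\t")
    groups = {g: table.group_samples(g) for g in syn.GROUPS}
    disp = cs.group_dispersion(d, groups, permutations=perms, seed=seed)
    rows = [{"group": g, "mean_dist_to_centroid": m}
            for g, m in disp.group_means.items()]
    nst_reps = int(scfg.get("tnst_null_reps", 100))
    nst = {g: cs.tnst(table, groups[g], null_reps=nst_reps,
                      seed=seed + i, group=g).tnst
           for i, g in enumerate(syn.GROUPS)}
    summary = {"dispersion_F": disp.f_stat, "dispersion_p": disp.p_value,
               "tnst": nst}
    pd.DataFrame(rows).to_csv(outdir / "dispersion.tsv", sep="\t",
                              index=False)
    (outdir / "assembly_stats.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    ctx["bray_curtis"] = d
    ctx["tnst"] = nst


def _run_network(config, ctx, outdir) -> None:
    ncfg = config.get("network", {})
    table = ctx["table"]
    rows = []
    for g in syn.GROUPS:
        sub = table.counts.loc[table.group_samples(g)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        graph = net.build_network(
            sub, min_prevalence=int(ncfg.get("min_prevalence", 6)),
            threshold=ncfg.get("threshold", 0.8))
        props = net.topology_properties(graph)
        rows.append({"group": g, **props.__dict__})
        edges = [(u, v, d["weight"], d["sign"])
                 for u, v, d in graph.edges(data=True)]
        pd.DataFrame(edges, columns=["node1", "node2", "r", "sign"]).to_csv(
            outdir / f"network_{g}.tsv", sep="\t", index=False)
    pd.DataFrame(rows).set_index("group").to_csv(
        outdir / "network_properties.tsv", sep="\t")
    ctx["network_props"] = rows


def _run_mend_sim(config, ctx, outdir, seed) -> None:
    params = mend.MendParams(**config.get("mend_params", {}))
    init = mend.MendState(**config.get("mend_init", {}))
    ccfg = config.get("calibration", {})
    sub = int(ccfg.get("substeps_per_day", 2))
    obs = {}
    for label, forcing in (("control", ctx["forcing_c"]),
                           ("warmed", ctx["forcing_w"])):
        traj = mend.simulate(params, init, forcing, substeps_per_day=sub)
        df = pd.DataFrame(traj.pools, columns=mend.POOL_NAMES)
        df.to_csv(outdir / f"trajectory_{label}.csv", index_label="day")
        obs[label] = syn.gen_observations(params, init, forcing, seed=seed,
                                          substeps_per_day=sub)
        cio.write_observations(obs[label],
                               outdir / f"observations_{label}.csv")
    ctx.update(true_params=params, init=init, observations=obs)


def _run_calibrate(config, ctx, outdir, seed) -> None:
    ccfg = config.get("calibration", {})
    calibrated = tuple(ccfg.get("calibrated", cal.DEFAULT_CALIBRATED))
    max_evals = int(ccfg.get("max_evals", 500))
    n_complexes = int(ccfg.get("n_complexes", 2))
    sub = int(ccfg.get("substeps_per_day", 2))
    init = ctx["init"]
    results = {}
    for label in ("control", "warmed"):
        forcing = ctx["forcing_c"] if label == "control" else ctx["forcing_w"]
        obs = ctx["observations"][label]
        for spec in (cal.ObjectiveSpec(w3=0.0), cal.ObjectiveSpec(w3=1.0)):
            objective = cal.MendObjective(obs, init, forcing, spec,
                                          calibrated=calibrated,
                                          substeps_per_day=sub)
            res = cal.sce_optimize(objective, objective.bounds(),
                                   n_complexes=n_complexes,
                                   max_evals=max_evals, seed=seed)
            cofi = cal.cofi_uncertainty(
                res.history_x, res.history_J, p=len(calibrated),
                n=cal.n_observations(obs, spec),
                parameter_names=list(calibrated))
            key = f"{label}_{spec.mode}"
            results[key] = {"best": dict(zip(calibrated,
                                             map(float, res.best_x))),
                            "J": res.best_J, "n_evals": res.n_evals,
                            "J_critical": cofi.J_critical,
                            "cv": dict(zip(calibrated, map(float, cofi.cv)))}
            hist = pd.DataFrame(res.history_x, columns=list(calibrated))
            hist["J"] = res.history_J
            hist.to_csv(outdir / f"history_{key}.csv", index=False)
    (outdir / "calibration.json").write_text(
        json.dumps(results, indent=2, sort_keys=True))
    ctx["calibration"] = results


def _run_warming(config, ctx, outdir) -> None:
    params = ctx["true_params"]
    init = ctx["init"]
    ccfg = config.get("calibration", {})
    sub = int(ccfg.get("substeps_per_day", 2))
    summaries = {}
    for label, forcing in (("control", ctx["forcing_c"]),
                           ("warmed", ctx["forcing_w"])):
        traj = mend.simulate(params, init, forcing, substeps_per_day=sub)
        years = traj.n_days // 365
        per_year = {k: [] for k in ("Rh", "MB", "MBA", "active_fraction",
                                    "CUE", "k_P1", "k_P2", "k_M")}
        for y in range(max(years, 1)):
            w = slice(365 * y, min(365 * (y + 1), traj.n_days))
            summary = mend.derive_outputs(traj, window=w)
            for k, v in summary.items():
                per_year[k].append(v)
        summaries[label] = per_year
    table = cal.warming_effect_table(summaries["control"],
                                     summaries["warmed"])
    table.to_csv(outdir / "warming_effects.tsv", sep="\t")
    ctx["warming_effects"] = table
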