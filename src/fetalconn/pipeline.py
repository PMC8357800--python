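"""End-to-end orchestration.

Runs the full analytic chain on a cohort (read from disk or generated
synthetically): stress factor -> connectome -> communities -> enrichment ->
WQS mixtures -> delivery-age models -> confound screen.  Every stage writes
its intermediate artifacts under the output directory, stage seeds are
derived from one master seed via ``numpy.random.SeedSequence`` spawning,
and a manifest records the configuration hash and all seeds so any stage
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .communities import consensus, detect_communities
from .connectome import (default_density_grid, exclude_short_edges,
                         fc_from_timeseries, group_average, threshold_stack)
from .enrichment import (edgewise_correlation, permutation_null,
                         significant_edge_lists, stack_fc)
from .outcomes import confound_screen, delivery_table
from .stress_factor import fit_one_factor, residualize_on_ga, split_half_efa
from .synthetic import (HEALTH_COLUMNS, SCALE_COLUMNS, GeneratorConfig,
                        SyntheticCohort, generate_cohort, read_cohort,
                        write_cohort)
from .wqs import pair_summaries, support_factor_analysis, wqs_fit, wqs_moderation

log = logging.getLogger("fetalconn")

_STAGES = ("split", "communities", "permutation", "support", "wqs")


@dataclass
class PipelineConfig:
    out_dir: str = "fetalconn_out"
    cohort_dir: str | None = None           # read a persisted cohort ...
    generator: GeneratorConfig | None = None  # ... or generate one
    edge_alpha: float = 0.05
    densities: list | None = None           # default: 1..10% by 0.1%
    min_distance_mm: float = 10.0
    window: int = 5
    infomap_trials: int = 100
    n_permutations: int = 1000
    q: int = 4
    n_boot: int = 100
    split: float = 0.4
    seed: int = 0
    force: bool = False

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(c.generate_state(1)[0] % (2 ** 31))
                for name, c in zip(_STAGES, children)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["stress_coupled_pairs"] = [list(p) for p in self.generator.stress_coupled_pairs]
            g["loading_vector"] = list(self.generator.loading_vector)
            d["generator"] = g
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            gen["stress_coupled_pairs"] = tuple(tuple(p) for p in gen.get("stress_coupled_pairs", ()))
            gen["loading_vector"] = tuple(gen.get("loading_vector", (0.8, 0.8, 0.7, 0.7, 0.6)))
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _validate_inputs(config: PipelineConfig) -> SyntheticCohort:
    if config.cohort_dir is not None:
        src = Path(config.cohort_dir)
        if not src.is_dir():
            raise FileNotFoundError(f"cohort directory not found: {src}")
        if not (src / "cohort.csv").exists():
            raise FileNotFoundError(f"missing cohort.csv under {src}")
        if not (src / "timeseries.npz").exists() and not (src / "timeseries").is_dir():
            raise FileNotFoundError(f"missing timeseries under {src}")
        cohort = read_cohort(src)
    elif config.generator is not None:
        cohort = generate_cohort(config.generator)
    else:
        raise ValueError("config needs either cohort_dir or generator")
    missing = [c for c in SCALE_COLUMNS + ["ga_scan", "ga_delivery"]
               if c not in cohort.subjects.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if not cohort.timeseries:
        raise ValueError("cohort has no timeseries")
    return cohort


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the consolidated report dictionary."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output dir {out} not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: dict = {"config_hash": _config_hash(config), "seeds": seeds,
                    "version": __version__, "stages": {}}
    t_all = time.time()

    cohort = _validate_inputs(config)
    subjects = cohort.subjects
    ids = list(subjects["id"])
    if config.generator is not None and config.cohort_dir is None:
        write_cohort(cohort, out / "cohort")

    # --- stage 1: stress factor ------------------------------------------
    t0 = time.time()
    scales = subjects[SCALE_COLUMNS]
    efa = split_half_efa(scales, seed=seeds["split"])
    sol = fit_one_factor(scales)
    nas_resid = residualize_on_ga(sol.scores, subjects["ga_scan"].to_numpy())
    nas_df = pd.DataFrame({"id": ids, "nas": sol.scores, "nas_resid": nas_resid})
    nas_df.to_csv(out / "nas.csv", index=False)
    with open(out / "stress_factor.json", "w") as fh:
        json.dump({"cfa": sol.to_dict(), "efa_chosen_k": efa["chosen_k"],
                   "efa_1factor_fit": {k: v for k, v in efa["efa_fit_1factor"].items()
                                       if not isinstance(v, np.ndarray)}}, fh, indent=2)
    report["stages"]["stress_factor"] = {
        "chosen_k": efa["chosen_k"], "cfa_fit": sol.fit, "n_used": sol.n_used,
        "loadings": sol.loadings.tolist(), "wall_s": time.time() - t0}
    log.info("stress_factor done (%.1fs)", time.time() - t0)

    # --- stage 2: connectome ---------------------------------------------
    t0 = time.time()
    fc_list = [fc_from_timeseries(cohort.timeseries[sid],
                                  roi_ids=list(cohort.roi_meta["roi_id"]),
                                  subject_id=sid) for sid in ids]
    group = group_average(fc_list)
    eligible, excluded = exclude_short_edges(group, cohort.roi_meta,
                                             min_mm=config.min_distance_mm)
    densities = config.densities or default_density_grid()
    stack = threshold_stack(group, eligible_mask=eligible, densities=densities,
                            excluded_edges=excluded)
    np.savetxt(out / "group_fc.csv", group.matrix, delimiter=",")
    report["stages"]["connectome"] = {
        "n_roi": group.n_roi, "n_eligible_pairs": stack.n_eligible,
        "n_excluded_pairs": len(excluded), "n_thresholds": len(stack.thresholds),
        "wall_s": time.time() - t0}
    log.info("connectome done (%.1fs)", time.time() - t0)

    # --- stage 3: communities --------------------------------------------
    t0 = time.time()
    partitions = [detect_communities(m, seed=seeds["communities"] + k,
                                     trials=config.infomap_trials, threshold=d)
                  for k, (d, m) in enumerate(zip(stack.thresholds, stack.matrices))]
    median_adj = stack.matrices[len(stack.matrices) // 2]
    model = consensus(partitions, median_adj, window=config.window)
    labels = model.final.labels
    names = [f"N{c + 1:02d}" for c in range(model.n_networks)]
    pd.DataFrame({"roi_id": group.roi_ids, "network_id": labels}).to_csv(
        out / "partition.tsv", sep="\t", index=False)
    report["stages"]["communities"] = {
        "n_networks": model.n_networks,
        "final_threshold": model.final.threshold,
        "consensus_modularity": model.final.quality.get("consensus_modularity"),
        "wall_s": time.time() - t0}
    log.info("communities done: %d networks (%.1fs)", model.n_networks, time.time() - t0)

    # --- stage 4: enrichment ---------------------------------------------
    t0 = time.time()
    X, ei, ej, roi_ids = stack_fc(fc_list, eligible)
    edge_stats = edgewise_correlation(X, nas_resid, (ei, ej, roi_ids),
                                      edge_alpha=config.edge_alpha)
    table = permutation_null(X, nas_resid, labels, B=config.n_permutations,
                             seed=seeds["permutation"], edge_alpha=config.edge_alpha,
                             eligible_mask=(ei, ej, roi_ids), network_names=names,
                             force=config.force)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    enriched = table[table["enriched"]]
    report["stages"]["enrichment"] = {
        "n_pairs": len(table), "n_enriched": int(table["enriched"].sum()),
        "enriched_pairs": list(enriched["network_pair"]),
        "edge_sig_fraction": float(edge_stats.significant.mean()),
        "wall_s": time.time() - t0}
    log.info("enrichment done: %d/%d pairs (%.1fs)",
             len(enriched), len(table), time.time() - t0)

    # --- stage 5: WQS mixtures -------------------------------------------
    t0 = time.time()
    health_cols = [c for c in HEALTH_COLUMNS if c in subjects.columns]
    wqs_report = {"skipped": True}
    moderation = None
    comps = None
    fit = None
    if len(enriched) >= 1:
        pairs = list(zip(enriched["net_a"], enriched["net_b"]))
        comps = pair_summaries(X, edge_stats, labels, pairs, network_names=names)
        comps.insert(0, "id", ids)
        comps.to_csv(out / "pair_summaries.csv", index=False)
        support = support_factor_analysis(subjects[health_cols], seed=seeds["support"],
                                          n_resamples=200)
        fit = wqs_fit(comps.drop(columns="id"), nas_resid, q=config.q,
                      n_boot=config.n_boot, split=config.split, seed=seeds["wqs"])
        moderation = wqs_moderation(fit, support["scores"], nas_resid)
        moderation.to_csv(out / "moderation.tsv", sep="\t", index=False)
        with open(out / "wqs.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        wqs_report = {"skipped": False, "weights": dict(zip(fit.component_names,
                                                            fit.weights.tolist())),
                      "beta": fit.beta, "p": fit.p,
                      "support_n_factors": support["n_factors"],
                      "moderation": moderation.to_dict(orient="records")}
    wqs_report["wall_s"] = time.time() - t0
    report["stages"]["wqs"] = wqs_report
    log.info("wqs done (%.1fs)", time.time() - t0)

    # --- stage 6: delivery-age models and confound screen ----------------
    t0 = time.time()
    ga_del = subjects["ga_delivery"].to_numpy()
    predictors = pd.DataFrame({"NAS": nas_resid})
    fam = []
    if comps is not None:
        for c in comps.columns.drop("id"):
            predictors[c] = comps[c]
            fam.append(c)
        predictors["WQS"] = fit.index
    tab2 = delivery_table(ga_del, predictors, holm_family=fam or None)
    tab2.to_csv(out / "delivery_models.tsv", sep="\t", index=False)
    screen = confound_screen(subjects, nas_resid,
                             wqs_index=None if fit is None else fit.index)
    screen.to_csv(out / "confound_screen.tsv", sep="\t", index=False)
    report["stages"]["outcomes"] = {
        "delivery_models": tab2.to_dict(orient="records"),
        "confound_flags": int(screen["flagged"].sum()),
        "wall_s": time.time() - t0}
    report["wall_s"] = time.time() - t_all

    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": config.to_dict(), "config_hash": report["config_hash"],
                   "seeds": seeds, "version": __version__}, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    _write_markdown(report, out / "report.md")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_markdown(report: dict, path) -> None:
    s = report["stages"]
    lines = ["# fetalconn pipeline report", "",
             f"- config hash: `{report['config_hash']}`",
             f"- package version: {report['version']}", ""]
    lines += [f"- CFA fit: {s['stress_factor']['cfa_fit']}",
              f"- networks: {s['communities']['n_networks']}",
              f"- enriched pairs: {s['enrichment']['enriched_pairs']}"]
    if not s["wqs"].get("skipped", True):
        lines += [f"- WQS beta (validation, standardized): {s['wqs']['beta']:.3f} "
                  f"(p = {s['wqs']['p']:.3g})"]
    lines += ["", "## Delivery-age models", "",
              "| predictor | beta | se | t | p | holm_p |", "|---|---|---|---|---|---|"]
    for row in s["outcomes"]["delivery_models"]:
        hp = "" if row["holm_p"] is None else f"{row['holm_p']:.3g}"
        lines.append(f"| {row['predictor']} | {row['beta']:.3f} | {row['se']:.3f} | "
                     f"{row['t']:.2f} | {row['p']:.3g} | {hp} |")
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = ["PipelineConfig", "run_all"]
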