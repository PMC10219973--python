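"""End-to-end pipeline: simulate/load -> filter -> normalize -> diff ->
sexbias -> integrate -> classify, driven by one YAML config.

Every stochastic stage derives its randomness from the single config seed,
so a re-run with the same config is byte-identical.  The run directory gets
a ``manifest.json`` with the parameter hash, per-stage feature counts (the
filtering funnel) and the artifact list.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, filtering, integrate, normalize, plgem, sexbias, simulate
from .data import (IntensityMatrix, SampleTable, read_annotation, read_matrix,
                   write_annotation, write_matrix)
from .errors import UromicsError, ValidationError

log = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "normalize", "diff", "sexbias", "integrate",
          "classify"]

DEFAULTS = {
    "min_count": 3,
    "posterior": 0.95,
    "pseudo": None,
    "alpha": 0.05,
    "fd": 2.0,
    "n_iter": 500,
    "network_threshold": 0.62,
    "n_components": 2,
    "n_trees": 1000,
    "min_importance": 0.1,
    "quantile_normalize_proteins": False,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    missing = [k for k in ("seed", "out_dir") if k not in cfg]
    if "simulate" not in cfg and "inputs" not in cfg:
        missing.append("simulate or inputs")
    if "inputs" in cfg:
        for key in ("protein", "volatile", "annotation"):
            if key not in cfg["inputs"]:
                missing.append(f"inputs.{key}")
    if missing:
        raise ValidationError(f"config missing keys: {missing}")
    return cfg


def parameter_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config_path, skip=()) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **{k: v for k, v in cfg.items()
                             if k not in ("inputs", "simulate", "out_dir")}}
    manifest = {"parameter_hash": parameter_hash(cfg), "seed": seed,
                "stages": {}, "artifacts": []}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["artifacts"].append(name)

    # -- stage: obtain inputs ---------------------------------------------
    if "simulate" in cfg and "simulate" not in skip:
        sim_cfg = simulate.SimConfig(**{**(cfg.get("simulate") or {}), "seed": seed})
        protein, volatile, ann, truth = simulate.simulate_dataset(sim_cfg)
        emit("protein.tsv", lambda p: write_matrix(protein, p))
        emit("volatile.tsv", lambda p: write_matrix(volatile, p))
        emit("annotation.csv", lambda p: write_annotation(ann, p))
        emit("truth.csv", lambda p: simulate.truth_report(truth).to_csv(p, index=False))
        manifest["stages"]["simulate"] = {
            "n_proteins": protein.n_features, "n_volatiles": volatile.n_features,
            "n_samples": len(ann)}
    else:
        inputs = cfg["inputs"]
        protein = read_matrix(inputs["protein"], kind="protein")
        volatile = read_matrix(inputs["volatile"], kind="volatile")
        ann = read_annotation(inputs["annotation"])

    groups = ann.groups()

    # -- stage: filter -----------------------------------------------------
    if "filter" not in skip:
        vol_f, vol_report, fit = filtering.filter_pipeline(
            volatile, ann, min_count=params["min_count"],
            posterior_threshold=params["posterior"], pseudo=params["pseudo"])
        prot_f, prot_report, _ = filtering.filter_pipeline(
            protein, ann, min_count=params["min_count"])
        emit("filter_report_volatile.csv", lambda p: vol_report.to_csv(p))
        emit("filter_report_protein.csv", lambda p: prot_report.to_csv(p))
        emit("volatile_filtered.tsv", lambda p: write_matrix(vol_f, p))
        emit("protein_filtered.tsv", lambda p: write_matrix(prot_f, p))
        manifest["stages"]["filter"] = {
            "volatile": vol_report.stage_counts(),
            "protein": prot_report.stage_counts(),
            "mixture": None if fit is None else
            {"lambda": fit.lam, "mu1": fit.mu1, "mu2": fit.mu2,
             "converged": bool(fit.converged)},
            "implied_fd_cutoff": vol_report.implied_fd_cutoff,
            "implied_li_cutoff": vol_report.implied_li_cutoff,
        }
        if fit is not None:
            x, _ = filtering.blank_fold_difference(volatile.subset_features(
                [f for f in vol_report.records.loc[
                    vol_report.records["drop_reason"].isin(["none", "mixture"]),
                    "feature_id"] if f in volatile.feature_ids]), ann,
                params["pseudo"])
            filtering.plot_mixture(x, fit, out / "mixture_fit.png")
    else:
        vol_f, prot_f = volatile, protein

    # -- stage: normalize --------------------------------------------------
    if "normalize" not in skip:
        vol_n = normalize.quantile_normalize(vol_f)
        prot_n = normalize.quantile_normalize(prot_f) \
            if params["quantile_normalize_proteins"] else prot_f
        emit("volatile_normalized.tsv", lambda p: write_matrix(vol_n, p))
        emit("protein_normalized.tsv", lambda p: write_matrix(prot_n, p))
        manifest["stages"]["normalize"] = {
            "volatile_quantile": True,
            "protein_quantile": bool(params["quantile_normalize_proteins"])}
    else:
        vol_n, prot_n = vol_f, prot_f

    spec_ids = [s for s in vol_n.sample_ids if s in set(ann.specimen_ids())]
    vol_spec = vol_n.subset_samples(spec_ids)
    prot_spec = prot_n.subset_samples([s for s in prot_n.sample_ids
                                       if s in set(ann.specimen_ids())])

    # -- stage: differential abundance ------------------------------------
    diffs: dict[tuple[str, str], pd.DataFrame] = {}
    if "diff" not in skip:
        counts = {}
        for layer, mat in (("volatile", vol_spec), ("protein", prot_spec)):
            for g in groups:
                table = plgem.differential_by_sex(
                    mat, ann, g, alpha=params["alpha"],
                    fd_threshold=params["fd"], n_iter=params["n_iter"],
                    seed=seed + 101)
                diffs[(layer, g)] = table
                name = f"diff_{layer}_{g}.csv"
                emit(name, lambda p, t=table: t.to_csv(p, index=False))
                counts[f"{layer}_{g}_significant"] = int(table["significant"].sum())
        manifest["stages"]["diff"] = counts

    # -- stage: sex-bias ---------------------------------------------------
    if "sexbias" not in skip and diffs:
        stage = {}
        for g in groups:
            table = sexbias.bias_counts(diffs[("volatile", g)], diffs[("protein", g)])
            result = sexbias.fisher_exact(table)
            stage[g] = {"table": table.tolist(), "odds_ratio": result.odds_ratio,
                        "p": result.p}
        for sex_dir in ("male_biased", "female_biased"):
            for layer in ("volatile", "protein"):
                sets = {g: sexbias.biased_ids(diffs[(layer, g)], sex_dir)
                        for g in groups}
                if len(groups) >= 2:
                    inter = sexbias.intersections(sets)
                    emit(f"intersections_{layer}_{sex_dir}.csv",
                         lambda p, t=inter: t.to_csv(p, index=False))
        manifest["stages"]["sexbias"] = stage

    # -- stage: integrate --------------------------------------------------
    if "integrate" not in skip:
        sex_labels = ann.labels_for(spec_ids, "sex")
        log_prot = normalize.log_transform(prot_spec, pseudo=1.0)
        log_vol = normalize.log_transform(vol_spec, pseudo=1.0)
        tb = integrate.two_block_pls(log_prot, log_vol,
                                     n_components=params["n_components"])
        pls_v = integrate.plsda(log_vol, sex_labels,
                                n_components=params["n_components"])
        edges = integrate.correlation_network(
            log_prot, log_vol, r_threshold=params["network_threshold"])
        emit("network_edges.csv", lambda p: edges.to_csv(p, index=False))
        emit("block_scores_x.csv", lambda p: pd.DataFrame(
            tb.scores_x, index=spec_ids).to_csv(p))
        emit("block_scores_y.csv", lambda p: pd.DataFrame(
            tb.scores_y, index=spec_ids).to_csv(p))
        manifest["stages"]["integrate"] = {
            "component_correlation": [float(r) for r in tb.component_correlation],
            "plsda_auc": [float(a) for a in pls_v.auc_per_component()],
            "n_edges": int(len(edges))}

    # -- stage: classify ---------------------------------------------------
    if "classify" not in skip:
        stage = {}
        for g in groups:
            ids_g = [s for s in spec_ids
                     if ann.labels_for([s], "group")[0] == g]
            mat_g = vol_spec.subset_samples(ids_g)
            labels_g = ann.labels_for(ids_g, "sex")
            table = classify.rf_importance(mat_g, labels_g,
                                           n_trees=params["n_trees"],
                                           seed=seed + 7)
            emit(f"importance_volatile_{g}.csv",
                 lambda p, t=table: t.records.to_csv(p, index=False))
            tops = classify.top_features(table, params["min_importance"])
            stage[g] = {"oob_accuracy": table.oob_accuracy,
                        "n_top": len(tops), "top": tops[:10]}
        manifest["stages"]["classify"] = stage

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def report(run_dir) -> str:
    """Human-readable summary of a completed run; lists missing stages."""
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise UromicsError(f"{run_dir} has no manifest.json; incomplete run")
    manifest = json.loads(mpath.read_text())
    stages = manifest.get("stages", {})
    lines = [f"run {run_dir}", f"parameter hash {manifest['parameter_hash']}",
             f"seed {manifest['seed']}", ""]
    if "filter" in stages:
        lines.append("filter funnel (volatile):")
        for k, v in stages["filter"]["volatile"].items():
            lines.append(f"  {k:22s} {v}")
        lines.append("filter funnel (protein):")
        for k, v in stages["filter"]["protein"].items():
            lines.append(f"  {k:22s} {v}")
        lines.append("")
    if "diff" in stages:
        lines.append("significant sex-biased features:")
        for k, v in sorted(stages["diff"].items()):
            lines.append(f"  {k:30s} {v}")
        lines.append("")
    if "sexbias" in stages:
        lines.append("bias-direction x layer exact tests:")
        for g, d in sorted(stages["sexbias"].items()):
            lines.append(f"  {g}: table {d['table']}, OR {d['odds_ratio']:.3g}, "
                         f"p {d['p']:.3g}")
        lines.append("")
    if "integrate" in stages:
        d = stages["integrate"]
        corr = ", ".join(f"{r:.3f}" for r in d["component_correlation"])
        lines.append(f"two-block component correlations: {corr}")
        lines.append(f"PLS-DA per-component AUC: "
                     + ", ".join(f"{a:.3f}" for a in d["plsda_auc"]))
        lines.append(f"network edges above threshold: {d['n_edges']}")
        lines.append("")
    if "classify" in stages:
        lines.append("random-forest importance (volatiles, sex):")
        for g, d in sorted(stages["classify"].items()):
            lines.append(f"  {g}: OOB accuracy {d['oob_accuracy']:.3f}, "
                         f"{d['n_top']} features above the importance cut")
        lines.append("")
    missing = [s for s in STAGES if s not in stages and s != "simulate"]
    if missing:
        lines.append(f"stages not run: {', '.join(missing)}")
    return "\n".join(lines)
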