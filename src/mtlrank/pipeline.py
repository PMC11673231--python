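"""End-to-end orchestration: simulate/load -> train -> interpret -> stratify.

A run is driven by a config dict (YAML/JSON on disk) and produces a manifest
recording the config snapshot, seeds, input fingerprints and the paths of
every stage output, so deterministic stages reproduce bit-for-bit from the
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import attribute, fit_patterns, select_endpoint_nodes
from .cohort_io import load_cohort, load_gmt
from .enrichment import combine_sets, enrich_cohort, gsva_score
from .network import HyperParams, combined_train, cross_validate, train, tune
from .simulate import ModuleSpec, SimulationConfig, decoy_gene_sets, simulate_cohort
from .stratification import plot_km, stratify

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "mtlrank_run",
    "loss": "nmtlr_rank",
    "simulate": {"enabled": True, "n": 300, "p": 200},
    "expression": None,  # path, with "orientation"
    "survival": None,
    "gene_sets": None,  # GMT path; None -> decoys from simulation ground truth
    "tune": {"enabled": False, "budget": 10},
    "cv": {"k": 5, "repeats": 2, "n_time_bins": 4},
    "hyperparams": {},
    "auxiliaries": [],  # list of {expression, survival, orientation, label}
    "attribution": {"endpoints_days": [372.0, 1919.0], "root": "psi"},
    "enrichment": {"alpha": 0.05, "n_perm": 200, "min_frequency": 0.05},
    "stratification": {"low_risk_fraction": 0.30, "high_score_low_risk": True},
}


def _deep_update(base: dict, other: dict) -> dict:
    out = dict(base)
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    return _deep_update(DEFAULT_CONFIG, cfg)


def _fingerprint(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Stages: simulate (optional) -> load/normalize -> cross-validate ->
    refit on all samples -> attribute at the configured endpoints ->
    per-patient enrichment -> combined-set activity score -> quantile
    stratification with Kaplan-Meier/log-rank.  Any stage failure leaves a
    manifest recording the partial state.
    """
    cfg = _deep_update(DEFAULT_CONFIG, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seed": seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def _stage(name):
        t0 = _time.time()
        logger.info("stage=%s seed=%d start", name, seed)
        manifest["stages"].append({"stage": name, "t_start": t0})
        return t0

    def _done(name, t0):
        manifest["stages"][-1]["wall_s"] = _time.time() - t0
        logger.info("stage=%s wall=%.2fs", name, _time.time() - t0)

    try:
        # ------------------------------------------------ data
        t0 = _stage("data")
        membership = None
        if cfg["simulate"]["enabled"]:
            sim = cfg["simulate"]
            modules = [
                ModuleSpec(**m) for m in sim.get(
                    "modules", [{"name": "RISK_MODULE", "size": 25, "effect": 1.0, "within_correlation": 0.6}]
                )
            ]
            sc = SimulationConfig(
                n=sim.get("n", 300), p=sim.get("p", 200), modules=modules,
                censoring_fraction_target=sim.get("censoring_fraction_target", 0.62),
                seed=seed,
            )
            cohort, membership, _, _ = simulate_cohort(sc, "simulated")
            cohort.to_files(outdir / "expression.tsv", outdir / "survival.tsv")
            manifest["outputs"]["expression"] = str(outdir / "expression.tsv")
        else:
            cohort = load_cohort(
                cfg["expression"]["path"], cfg["survival"]["path"],
                orientation=cfg["expression"].get("orientation", "samples_rows"),
            )
            for key in ("expression", "survival"):
                manifest["inputs"][key] = _fingerprint(Path(cfg[key]["path"]))
        auxiliaries = [
            load_cohort(a["expression"], a["survival"],
                        orientation=a.get("orientation", "samples_rows"),
                        cohort_label=a.get("label", f"aux{i}"))
            for i, a in enumerate(cfg["auxiliaries"])
        ]
        _done("data", t0)

        hp = HyperParams(**{**{"epochs": 256, "width": 32}, **cfg["hyperparams"], "seed": seed})
        loss_name = cfg["loss"]

        # ------------------------------------------------ tune (optional)
        if cfg["tune"]["enabled"]:
            t0 = _stage("tune")
            rng = np.random.default_rng(seed)
            idx = rng.permutation(cohort.n)
            n_val = max(cohort.n // 4, 1)
            val_sub, train_sub = cohort.subset(idx[:n_val]), cohort.subset(idx[n_val:])
            hp, trial_log = tune(train_sub, val_sub, budget=int(cfg["tune"]["budget"]),
                                 seed=seed, loss_name=loss_name)
            trial_log.to_csv(outdir / "tuning_trials.tsv", sep="\t", index=False)
            manifest["outputs"]["tuning_trials"] = str(outdir / "tuning_trials.tsv")
            _done("tune", t0)

        # ------------------------------------------------ cross-validation
        t0 = _stage("cross_validate")
        cv_cfg = cfg["cv"]
        metrics = cross_validate(
            cohort, hp, loss_name, k=int(cv_cfg["k"]), repeats=int(cv_cfg["repeats"]),
            n_time_bins=int(cv_cfg["n_time_bins"]), seed=seed,
            auxiliaries=auxiliaries or None,
        )
        metrics.to_csv(outdir / "cv_metrics.tsv", sep="\t", index=False)
        manifest["outputs"]["cv_metrics"] = str(outdir / "cv_metrics.tsv")
        _done("cross_validate", t0)

        # ------------------------------------------------ refit on all samples
        t0 = _stage("refit")
        if auxiliaries:
            model = combined_train(cohort, auxiliaries, hp, loss_name)
        else:
            model = train(cohort, hp, loss_name)
        model.save(outdir / "model")
        manifest["outputs"]["model"] = str(outdir / "model")
        _done("refit", t0)

        # ------------------------------------------------ attribution
        t0 = _stage("attribute")
        att_cfg = cfg["attribution"]
        patterns = fit_patterns(model, cohort.X[:, [cohort.genes.index(g) for g in model.genes]])
        nodes = select_endpoint_nodes(model.grid, att_cfg["endpoints_days"])
        attributions = {}
        Xm = cohort.X[:, [cohort.genes.index(g) for g in model.genes]]
        for days, node in zip(att_cfg["endpoints_days"], nodes):
            att = attribute(model, patterns, Xm, node, root=att_cfg.get("root", "psi"))
            att.subject_ids = list(cohort.subject_ids)
            attributions[days] = att
            path = outdir / f"attributions_{int(days)}d.tsv"
            att.to_frame().to_csv(path, sep="\t")
            (outdir / f"attributions_{int(days)}d.json").write_text(json.dumps(
                {"endpoint_days": days, "output_node": att.output_node, "root": att.root}
            ))
            manifest["outputs"][f"attributions_{int(days)}d"] = str(path)
        _done("attribute", t0)

        # ------------------------------------------------ enrichment
        t0 = _stage("enrich")
        enr_cfg = cfg["enrichment"]
        if cfg["gene_sets"]:
            collection = load_gmt(cfg["gene_sets"])
            manifest["inputs"]["gene_sets"] = _fingerprint(Path(cfg["gene_sets"]))
        elif membership is not None:
            collection = decoy_gene_sets(cohort.genes, membership, seed=seed)
        else:
            raise ValueError("gene_sets path required when not simulating")
        freq_frames = {}
        last_days = max(attributions)
        for days, att in attributions.items():
            res = enrich_cohort(att, collection, alpha=float(enr_cfg["alpha"]),
                                n_perm=int(enr_cfg["n_perm"]), seed=seed)
            freq_frames[days] = res.frequency
            res.table.to_csv(outdir / f"enrichment_{int(days)}d.tsv", sep="\t", index=False)
        freq_table = pd.DataFrame(freq_frames)
        freq_table.columns = [f"{int(d)}d" for d in freq_frames]
        freq_table.to_csv(outdir / "pathway_frequency.tsv", sep="\t")
        manifest["outputs"]["pathway_frequency"] = str(outdir / "pathway_frequency.tsv")
        _done("enrich", t0)

        # ------------------------------------------------ activity score + stratification
        t0 = _stage("stratify")
        last_freq = freq_frames[last_days]
        if (last_freq > float(enr_cfg["min_frequency"])).any():
            combined = combine_sets(collection, min_frequency=float(enr_cfg["min_frequency"]),
                                    freq_table=last_freq)
        else:  # nothing clears the threshold: fall back to the top set
            logger.warning("no gene set above frequency threshold; using the top set")
            combined = combine_sets(collection, names=[last_freq.idxmax()])
        scores = gsva_score(cohort.X, cohort.genes, combined)
        pd.DataFrame({"sample": cohort.subject_ids, "score": scores}).to_csv(
            outdir / "activity_scores.tsv", sep="\t", index=False
        )
        st_cfg = cfg["stratification"]
        result = stratify(
            scores, cohort.time, cohort.event,
            low_risk_fraction=float(st_cfg["low_risk_fraction"]),
            high_score_low_risk=bool(st_cfg["high_score_low_risk"]),
        )
        pd.DataFrame({"sample": cohort.subject_ids, "label": result.labels}).to_csv(
            outdir / "risk_labels.tsv", sep="\t", index=False
        )
        (outdir / "stratification.json").write_text(json.dumps({
            "cutoff": result.cutoff,
            "low_risk_fraction": result.low_risk_fraction,
            "logrank_chi2": result.logrank_chi2,
            "logrank_p": result.logrank_p,
        }))
        plot_km(cohort.time, cohort.event, result.labels, path=outdir / "km_curves.svg")
        manifest["outputs"]["stratification"] = str(outdir / "stratification.json")
        _done("stratify", t0)
        manifest["status"] = "complete"
    except Exception as exc:  # record partial state, then re-raise
        manifest["status"] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
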