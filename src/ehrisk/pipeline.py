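"""End-to-end orchestration from one JSON run configuration.

Stages: simulate-or-ingest -> delirium masking + cohort labeling ->
augmentation -> patient-level 8:1:1 split -> (target substitution for
target-focused runs) -> vocabulary + encoding -> model training ->
evaluation (full model plus requested code-type ablations) ->
perturbation/RC analysis -> delimiter-separated reports plus a JSON run
manifest with per-stage counts. All randomness flows from the declared
seeds; one config re-run reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import cohort as coh
from . import contrib, encoding, models, synthetic, targets
from .events import MED, TARGET, read_stream, write_stream


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"[{stage}] {reason}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    has_sim = "simulation" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError(
            "config must contain exactly one of 'simulation' / 'inputs'"
        )
    seeds = cfg.get("seeds", [0])
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    if cfg.get("method", "drug") not in ("drug", "target"):
        raise ValueError("method must be 'drug' or 'target'")


def _sim_config(block: dict, seed: int) -> synthetic.SimulationConfig:
    catalog = [
        synthetic.CodeSpec(c["code"], c["code_type"], float(c["prevalence"]))
        for c in block["codes"]
    ]
    return synthetic.SimulationConfig(
        n_patients=int(block["n_patients"]),
        code_catalog=catalog,
        effects={k: float(v) for k, v in block.get("effects", {}).items()},
        baseline_logit=float(block.get("baseline_logit", -1.4)),
        observation_days=int(block.get("observation_days", 540)),
        outcome_window_days=int(block.get("outcome_window_days", 90)),
        visits_per_patient=float(block.get("visits_per_patient", 12.0)),
        order_effects=[tuple(t) for t in block.get("order_effects", [])],
        seed=seed,
    )


def _load_or_simulate(cfg: dict, seed: int):
    if "simulation" in cfg:
        sim = _sim_config(cfg["simulation"], seed)
        stream, truth = synthetic.generate_cohort_stream(sim)
        dtmap = None
        dt_block = cfg["simulation"].get("drug_target")
        if dt_block:
            dtmap = synthetic.generate_drug_target_map(
                int(dt_block["n_drugs"]), int(dt_block["n_targets"]),
                float(dt_block.get("mean_targets_per_drug", 1.5)), seed=seed,
            )
            truth.target_effects = synthetic.target_effects_from_map(
                truth.code_effects, dtmap
            )
        return stream, truth, dtmap
    inputs = cfg["inputs"]
    stream = read_stream(inputs["event_stream"])
    dtmap = (
        targets.DrugTargetMap.from_tsv(inputs["drug_target"])
        if inputs.get("drug_target") else None
    )
    return stream, None, dtmap


def _model_config(cfg: dict, seed: int) -> models.ModelConfig:
    block = dict(cfg.get("model", {}))
    block.setdefault("model_kind", "RETAIN")
    block["seed"] = seed
    return models.ModelConfig(**block)


def _encode_split(split, vocab):
    return [encoding.encode_sample(s, vocab) for s in split]


def run_single(cfg: dict, seed: int, outdir: Path) -> dict:
    """One seeded end-to-end run; returns its manifest fragment."""
    manifest: dict = {"seed": seed, "stages": {}}
    method = cfg.get("method", "drug")

    stream, truth, dtmap = _load_or_simulate(cfg, seed)
    manifest["stages"]["input"] = {
        "n_patients": int(stream["patient_id"].nunique()),
        "n_events": int(len(stream)),
    }

    spec = coh.CohortSpec(**cfg.get("cohort", {}))
    result = coh.build_cohort(stream, spec)
    if not result.samples:
        raise PipelineError("cohort", "no labeled samples produced")
    manifest["stages"]["cohort"] = {
        "cases": len(result.cases),
        "controls": len(result.controls),
        "excluded": len(result.exclusions),
    }

    samples = coh.augment_cases(result.samples, spec, seed=seed)
    train_s, val_s, test_s = coh.split_cohort(samples, seed=seed)
    split_of = {}
    for name, part in (("train", train_s), ("validation", val_s), ("test", test_s)):
        for s in part:
            split_of[s.patient_id] = name
    manifest["stages"]["split"] = {
        "train": len(train_s), "validation": len(val_s), "test": len(test_s),
    }

    if method == "target":
        if dtmap is None:
            raise PipelineError("encode", "target method requires a drug-target map")
        def sub(split):
            return [
                coh.LabeledSample(
                    s.patient_id, s.index_date, s.label,
                    targets.substitute_targets(s.sequence, dtmap),
                    provenance=s.provenance,
                )
                for s in split
            ]
        train_s, val_s, test_s = sub(train_s), sub(val_s), sub(test_s)

    enc_block = cfg.get("encoding", {})
    vocab = encoding.build_vocabulary(
        train_s,
        lab_top_k=int(enc_block.get("lab_top_k", 89)),
        max_size=int(enc_block.get("max_size", 30_000)),
    )
    train_e = _encode_split(train_s, vocab)
    val_e = _encode_split(val_s, vocab)
    test_e = _encode_split(test_s, vocab)
    manifest["stages"]["encode"] = {"vocab_size": len(vocab)}

    mcfg = _model_config(cfg, seed)
    model = models.train(mcfg.model_kind, train_e, val_e, mcfg, len(vocab))
    evals = {"full": dataclasses.asdict(models.evaluate(model, test_e))}
    for drop in cfg.get("ablations", []):
        abl_cfg = dataclasses.replace(mcfg)
        abl_model = models.train(
            mcfg.model_kind,
            encoding.ablate(train_e, drop, vocab),
            encoding.ablate(val_e, drop, vocab),
            abl_cfg, len(vocab),
        )
        evals[f"no_{drop}"] = dataclasses.asdict(
            models.evaluate(abl_model, encoding.ablate(test_e, drop, vocab))
        )
    manifest["stages"]["evaluate"] = evals

    # contribution analysis over the primary (non-augmented) samples
    primary = [s for s in (train_s + val_s + test_s) if s.provenance.split(":")[0]
               in ("primary", "case_anchor", "latest_encounter")]
    primary_e = _encode_split(primary, vocab)
    focus_type = TARGET if method == "target" else MED
    feat_idx = [
        i for i in range(len(vocab))
        if vocab.type_of(i) == focus_type
        and vocab.tokens[i][1] not in cfg.get("exclude_features", [])
    ]
    cf = cfg.get("crossfit", {})
    fc = contrib.crossfit_fc_table(
        mcfg.model_kind, primary_e, vocab, mcfg,
        n_folds=int(cf.get("n_folds", 2)),
        ensemble=int(cf.get("ensemble", 1)),
        seed=seed, features=feat_idx,
    )
    min_support = int(cfg.get("min_support", 10))
    q_cutoff = float(cfg.get("q_cutoff", 0.05))
    results, skipped = contrib.analyze_contributions(fc, min_support=min_support)
    report = contrib.rc_report(
        results, q_cutoff=q_cutoff, dtmap=dtmap if method == "target" else None
    )
    report.to_csv(outdir / f"rc_{method}_seed{seed}.csv", index=False)
    manifest["stages"]["contribute"] = {
        "features_tested": len(results),
        "features_skipped": len(skipped),
        "significant": int(len(report)),
    }

    if method == "drug" and dtmap is not None:
        pooled_rows = targets.pool_fc_by_target(fc.rows, dtmap)
        pooled = contrib.FCTable(pooled_rows, fc.patients, fc.all_zero_patients)
        pooled_results, _ = contrib.analyze_contributions(
            pooled, min_support=min_support
        )
        contrib.rc_report(pooled_results, q_cutoff=q_cutoff, dtmap=dtmap).to_csv(
            outdir / f"rc_pooled_seed{seed}.csv", index=False
        )

    coh.cohort_manifest(result, split_of).to_csv(
        outdir / f"cohort_seed{seed}.csv", index=False
    )
    if truth is not None:
        truth.to_json(outdir / f"ground_truth_seed{seed}.json")
    return manifest


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run every declared seed and write the aggregate manifest."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest: dict = {"config_hash": cfg_hash, "runs": [], "status": "incomplete"}
    try:
        for seed in cfg.get("seeds", [0]):
            manifest["runs"].append(run_single(cfg, seed, outdir))
        aucs = [r["stages"]["evaluate"]["full"]["auroc"] for r in manifest["runs"]]
        manifest["auroc_mean"] = float(np.mean(aucs))
        manifest["auroc_sd"] = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
        manifest["status"] = "complete"
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def simulate_to_files(cfg: dict, seed: int, outdir) -> None:
    """Write the simulated stream, ground truth and drug-target map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stream, truth, dtmap = _load_or_simulate(cfg, seed)
    write_stream(stream, outdir / "events.csv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
    if dtmap is not None:
        dtmap.to_tsv(outdir / "drug_target.tsv")
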