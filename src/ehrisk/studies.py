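"""Canned simulation studies: the package's reference experiments.

Each study wires the synthetic generator, cohort rules, encoders, models
and contribution statistics into one reproducible experiment with fixed
study conditions, returning plain dicts of computed quantities. They are
used by the test suite and by ``scripts/acceptance.py``; problem sizes are
chosen for single-CPU desk-scale runs (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from . import cohort as coh
from . import contrib, encoding, models, synthetic, targets
from .events import DIAG, LAB_ABN, MED, TARGET

RISK_CODES = ("C00", "C01", "C02")
PROTECTIVE_CODES = ("C03", "C04", "C05")


def standard_catalog(n_codes: int = 30, prevalence: float = 0.17):
    """30-code catalog: 15 diagnoses, 10 medications, 5 abnormal labs."""
    specs = []
    for i in range(n_codes):
        ctype = DIAG if i < n_codes // 2 else (
            MED if i < n_codes - max(1, n_codes // 6) else LAB_ABN)
        specs.append(synthetic.CodeSpec(f"C{i:02d}", ctype, prevalence))
    return specs


def _encode_cohort(samples, vocab):
    return [encoding.encode_sample(s, vocab) for s in samples]


def _retain_config(seed: int, **overrides) -> models.ModelConfig:
    base = dict(model_kind="RETAIN", embedding_dim=16, hidden_dim=16,
                dropout=0.2, n_layers=1, max_epochs=30, patience=5,
                learning_rate=3e-3, weight_decay=3e-2, seed=seed)
    base.update(overrides)
    return models.ModelConfig(**base)


def _simulate_samples(sim: synthetic.SimulationConfig):
    stream, truth = synthetic.generate_cohort_stream(sim)
    result = coh.build_cohort(stream, coh.CohortSpec())
    return result, truth


def planted_effect_recovery(seed: int, n_patients: int = 2000) -> dict:
    """Train a RETAIN-style model on a cohort with three planted risk codes
    (beta = +1) and three protective codes (beta = -1) among 24 nulls, then
    check that cross-fitted RC analysis recovers every planted direction at
    FDR 0.05 with few null false flags."""
    effects = {c: 1.0 for c in RISK_CODES}
    effects.update({c: -1.0 for c in PROTECTIVE_CODES})
    sim = synthetic.SimulationConfig(
        n_patients=n_patients, code_catalog=standard_catalog(),
        effects=effects, baseline_logit=-1.1, seed=seed,
    )
    result, truth = _simulate_samples(sim)
    samples = result.samples
    vocab = encoding.build_vocabulary(samples)
    enc = _encode_cohort(samples, vocab)
    catalog_codes = {s.code for s in sim.code_catalog}
    feat_idx = [i for i in range(len(vocab)) if vocab.tokens[i][1] in catalog_codes]
    fc = contrib.crossfit_fc_table(
        "RETAIN", enc, vocab, _retain_config(seed),
        n_folds=3, ensemble=3, seed=seed, features=feat_idx,
    )
    results, _ = contrib.analyze_contributions(fc, min_support=10)
    by_feat = {r.feature: r for r in results}
    null_feats = [c for c in sorted(catalog_codes) if c not in effects]
    null_flagged = [c for c in null_feats
                    if c in by_feat and by_feat[c].q_fdr <= 0.05]

    def recovered(code: str, want_risk: bool) -> bool:
        r = by_feat.get(code)
        return (r is not None and np.isfinite(r.rc) and r.q_fdr <= 0.05
                and (r.rc > 1) == want_risk)

    risk_ok = sum(recovered(c, True) for c in RISK_CODES)
    prot_ok = sum(recovered(c, False) for c in PROTECTIVE_CODES)
    return {
        "risk_codes_recovered": risk_ok,
        "protective_codes_recovered": prot_ok,
        "all_planted_recovered": risk_ok == 3 and prot_ok == 3,
        "null_flag_fraction": len(null_flagged) / len(null_feats),
        "case_rate": truth.case_rate,
        "rc": {c: by_feat[c].rc if c in by_feat else np.nan for c in effects},
        "q": {c: by_feat[c].q_fdr if c in by_feat else np.nan for c in effects},
    }


def null_calibration(base_seed: int, n_cohorts: int = 20,
                     n_patients: int = 1000) -> dict:
    """All-null simulations: the pooled fraction of features flagged at
    q <= 0.05 should stay near the nominal level."""
    flagged = tested = 0
    for k in range(n_cohorts):
        seed = base_seed + 101 * k
        sim = synthetic.SimulationConfig(
            n_patients=n_patients, code_catalog=standard_catalog(),
            effects={}, baseline_logit=-1.1, seed=seed,
        )
        result, _ = _simulate_samples(sim)
        vocab = encoding.build_vocabulary(result.samples)
        enc = _encode_cohort(result.samples, vocab)
        feat_idx = [i for i in range(len(vocab))
                    if vocab.tokens[i][1].startswith("C")]
        fc = contrib.crossfit_fc_table(
            "RETAIN", enc, vocab, _retain_config(seed, max_epochs=10, patience=3),
            n_folds=2, ensemble=1, seed=seed, features=feat_idx,
        )
        results, _ = contrib.analyze_contributions(fc, min_support=10)
        tested += len(results)
        flagged += sum(r.q_fdr <= 0.05 for r in results)
    fraction = flagged / tested if tested else 0.0
    # binomial MC standard error at the nominal level
    bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / tested) if tested else 1.0
    return {"flag_fraction": fraction, "bound": bound, "n_tests": tested}


def _train_eval(kind, tr, va, te, cfg, vocab_size):
    model = models.train(kind, tr, va, cfg, vocab_size)
    return models.evaluate(model, te).auroc


def strong_effect_discrimination(seed: int, n_patients: int = 5000) -> dict:
    """With strong, dense planted effects (|beta| = 2 on every catalog
    code) the sequence models should reach high test AUROC."""
    catalog = standard_catalog(60, prevalence=0.25)
    effects = {f"C{i:02d}": (2.0 if i % 2 == 0 else -2.0) for i in range(60)}
    sim = synthetic.SimulationConfig(
        n_patients=n_patients, code_catalog=catalog, effects=effects,
        baseline_logit=-1.3, visits_per_patient=6.0, seed=seed,
    )
    result, truth = _simulate_samples(sim)
    tr, va, te = coh.split_cohort(result.samples, seed=seed)
    vocab = encoding.build_vocabulary(tr)
    enc = lambda ss: _encode_cohort(ss, vocab)  # noqa: E731
    tr_e, va_e, te_e = enc(tr), enc(va), enc(te)
    out = {"case_rate": truth.case_rate}
    settings = {
        "TLSTM": dict(embedding_dim=64, hidden_dim=64, learning_rate=1e-3),
        "RETAIN": dict(embedding_dim=48, hidden_dim=48, learning_rate=3e-3),
        "LR": {},
    }
    for kind, overrides in settings.items():
        cfg = _retain_config(seed, model_kind=kind, max_epochs=40, patience=6,
                             weight_decay=3e-3, batch_size=32, **overrides)
        out[f"auroc_{kind.lower()}"] = _train_eval(kind, tr_e, va_e, te_e,
                                                   cfg, len(vocab))
    return out


def order_signal_gap(seed: int, n_patients: int = 3000) -> dict:
    """Outcome driven by the temporal order of two codes: presence-bag LR
    is blind to it, sequence models are not."""
    catalog = standard_catalog(10, prevalence=0.15)
    catalog[0] = synthetic.CodeSpec("C00", DIAG, 0.30)
    catalog[1] = synthetic.CodeSpec("C01", DIAG, 0.30)
    sim = synthetic.SimulationConfig(
        n_patients=n_patients, code_catalog=catalog, effects={},
        baseline_logit=-1.0, order_effects=[("C00", "C01", 2.0)], seed=seed,
    )
    result, _ = _simulate_samples(sim)
    tr, va, te = coh.split_cohort(result.samples, seed=seed)
    vocab = encoding.build_vocabulary(tr)
    enc = lambda ss: _encode_cohort(ss, vocab)  # noqa: E731
    tr_e, va_e, te_e = enc(tr), enc(va), enc(te)
    out = {}
    for kind in ("LR", "TLSTM", "RETAIN"):
        cfg = _retain_config(seed, model_kind=kind, max_epochs=20, patience=4)
        out[f"auroc_{kind.lower()}"] = _train_eval(kind, tr_e, va_e, te_e,
                                                   cfg, len(vocab))
    return out


def ablation_ordering(seed: int, n_patients: int = 2000) -> dict:
    """Diagnosis codes carry 70% of the planted |beta| mass; removing them
    should cost the most AUROC among the three single-type ablations."""
    catalog = (
        [synthetic.CodeSpec(f"D{i}", DIAG, 0.17) for i in range(10)]
        + [synthetic.CodeSpec(f"M{i}", MED, 0.17) for i in range(8)]
        + [synthetic.CodeSpec(f"L{i}", LAB_ABN, 0.17) for i in range(8)]
    )
    effects = {"D0": 1.4, "D1": 1.4, "D2": -1.4, "D3": -1.4,
               "M0": 0.6, "M1": -0.6, "L0": 0.6, "L1": -0.6}
    sim = synthetic.SimulationConfig(
        n_patients=n_patients, code_catalog=catalog, effects=effects,
        baseline_logit=-1.1, seed=seed,
    )
    result, _ = _simulate_samples(sim)
    tr, va, te = coh.split_cohort(result.samples, seed=seed)
    vocab = encoding.build_vocabulary(tr)
    enc = lambda ss: _encode_cohort(ss, vocab)  # noqa: E731
    tr_e, va_e, te_e = enc(tr), enc(va), enc(te)
    cfg = _retain_config(seed, max_epochs=20, patience=4)
    full = _train_eval("RETAIN", tr_e, va_e, te_e, cfg, len(vocab))
    out = {"auroc_full": full}
    for drop in (DIAG, MED, LAB_ABN):
        auroc = _train_eval(
            "RETAIN",
            encoding.ablate(tr_e, drop, vocab),
            encoding.ablate(va_e, drop, vocab),
            encoding.ablate(te_e, drop, vocab),
            cfg, len(vocab),
        )
        out[f"drop_{drop}"] = full - auroc
    return out


def pooling_power(base_seed: int, n_replicates: int = 10,
                  n_patients: int = 600) -> dict:
    """Ten rare drugs sharing one protein target, each with beta = +1:
    pooling patients on the shared target (target-focused analysis) should
    detect the signal at least as often as the best single-drug test."""
    drugs = [f"DB{i:05d}" for i in range(10)]
    dtmap = targets.DrugTargetMap({d: frozenset({"PRT0001"}) for d in drugs})
    drug_detect = {d: 0 for d in drugs}
    target_detect = 0
    for r in range(n_replicates):
        seed = base_seed + 37 * r
        catalog = (
            [synthetic.CodeSpec(f"N{i}", DIAG, 0.15) for i in range(10)]
            + [synthetic.CodeSpec(d, MED, 0.004) for d in drugs]
        )
        sim = synthetic.SimulationConfig(
            n_patients=n_patients, code_catalog=catalog,
            effects={d: 1.0 for d in drugs}, baseline_logit=-0.85, seed=seed,
        )
        result, _ = _simulate_samples(sim)
        samples = result.samples
        cfg = models.ModelConfig(model_kind="LR", seed=seed)

        # drug-focused: contributions on drug tokens
        vocab = encoding.build_vocabulary(samples)
        enc = _encode_cohort(samples, vocab)
        feat_idx = [i for i in range(len(vocab)) if vocab.type_of(i) == MED]
        fc = contrib.crossfit_fc_table("LR", enc, vocab, cfg, n_folds=2,
                                       seed=seed, features=feat_idx)
        results, _ = contrib.analyze_contributions(fc, min_support=3)
        for res in results:
            if res.feature in drug_detect and res.q_fdr <= 0.05:
                drug_detect[res.feature] += 1

        # target-focused: substitute before vocabulary construction
        sub = [
            coh.LabeledSample(s.patient_id, s.index_date, s.label,
                              targets.substitute_targets(s.sequence, dtmap),
                              provenance=s.provenance)
            for s in samples
        ]
        vocab_t = encoding.build_vocabulary(sub)
        enc_t = _encode_cohort(sub, vocab_t)
        feat_t = [i for i in range(len(vocab_t)) if vocab_t.type_of(i) == TARGET]
        fc_t = contrib.crossfit_fc_table("LR", enc_t, vocab_t, cfg, n_folds=2,
                                         seed=seed, features=feat_t)
        results_t, _ = contrib.analyze_contributions(fc_t, min_support=3)
        for res in results_t:
            if res.feature == "PRT0001" and res.q_fdr <= 0.05:
                target_detect += 1

    best_drug_power = max(drug_detect.values()) / n_replicates
    return {
        "target_power": target_detect / n_replicates,
        "best_single_drug_power": best_drug_power,
        "drug_detections": drug_detect,
    }
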