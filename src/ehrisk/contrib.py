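"""Perturbation-based feature contributions and the relative-contribution
(RC) statistic.

For a fitted risk model, the contribution of one token occurrence is the
drop in predicted outcome probability when that single occurrence is
occluded from the otherwise intact sequence. A patient's feature
contribution (FC) is the sum over that feature's occurrences; per-patient
FCs are then normalized by the patient's total absolute contribution so
heavy utilizers do not dominate. The relative contribution of a feature is

    RC = median(normalized FC | event patients)
         / median(normalized FC | non-event patients)

with RC > 1 read as risk and RC < 1 as protective. Group medians and the
Wilcoxon rank-sum comparison are taken over *all* patients in the analyzed
cohort, with unexposed patients contributing zeros: differential exposure
between events and non-events is part of the signal, not a nuisance.
Significance is Wilcoxon rank-sum, corrected by Benjamini-Hochberg FDR
(the reporting cutoff) and Bonferroni (reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .encoding import EncodedSequence, OOV_INDEX, Vocabulary
from .models import FittedModel, predict_proba

FC_COLUMNS = ["patient_id", "feature", "fc_raw", "fc_normalized", "label"]


@dataclass
class FCTable:
    """Sparse per-(patient, feature) contributions plus the cohort registry.

    ``rows`` holds one row per (patient, feature) pair where the feature
    occurs; ``patients`` registers every analyzed patient with its label so
    statistics can treat unexposed patients as exact zeros.
    ``all_zero_patients`` flags patients whose every contribution was zero
    (their normalized values stay zero)."""

    rows: pd.DataFrame
    patients: pd.DataFrame  # columns: patient_id, label
    all_zero_patients: list[str]


def _occlusion_variants(sample: EncodedSequence, feature_idx: int):
    """One variant sequence per occurrence of the feature, each with that
    single occurrence removed from the intact sequence."""
    variants = []
    for vi, (idxs, _) in enumerate(sample.visits):
        if feature_idx not in idxs:
            continue
        cum = 0
        new_visits = []
        prev_cum = None
        for vj, (idxs_j, delta_j) in enumerate(sample.visits):
            cum += delta_j
            kept = idxs_j - {feature_idx} if vj == vi else idxs_j
            if not kept:
                continue
            gap = 0 if prev_cum is None else cum - prev_cum
            new_visits.append((frozenset(kept), gap))
            prev_cum = cum
        variants.append(EncodedSequence(new_visits, sample.label, sample.patient_id))
    return variants


def occlusion_fc(model: FittedModel, sample: EncodedSequence,
                 feature_idx: int) -> float:
    """Per-patient raw FC of one feature: occurrence-wise occlusion summed.

    A feature absent from the sample costs no model calls and returns 0."""
    variants = _occlusion_variants(sample, feature_idx)
    if not variants:
        return 0.0
    p_full = predict_proba(model, [sample])[0]
    p_occ = predict_proba(model, variants)
    return float(np.sum(p_full - p_occ))


def compute_fc_table(
    model: FittedModel,
    samples: list[EncodedSequence],
    vocab: Vocabulary,
    features: list[int] | None = None,
) -> FCTable:
    """Raw + normalized FCs for every analyzed feature over a cohort.

    ``features`` defaults to every non-OOV vocabulary index. All occlusion
    variants of one patient are scored in a single batched forward pass."""
    if features is None:
        features = [i for i in range(len(vocab)) if i != OOV_INDEX]
    feature_names = {i: vocab.tokens[i][1] for i in features}

    recs: list[tuple] = []
    reg: list[tuple] = []
    for sample in samples:
        reg.append((sample.patient_id, sample.label))
        plan: list[tuple[int, int]] = []  # (feature_idx, n_variants)
        variants: list[EncodedSequence] = []
        for fi in features:
            fv = _occlusion_variants(sample, fi)
            if fv:
                plan.append((fi, len(fv)))
                variants.extend(fv)
        if not variants:
            continue
        probs = predict_proba(model, [sample] + variants)
        p_full, p_occ = probs[0], probs[1:]
        pos = 0
        for fi, k in plan:
            fc = float(np.sum(p_full - p_occ[pos : pos + k]))
            pos += k
            recs.append((sample.patient_id, feature_names[fi], fc, sample.label))

    rows = pd.DataFrame(recs, columns=["patient_id", "feature", "fc_raw", "label"])
    patients = pd.DataFrame(reg, columns=["patient_id", "label"])
    rows["fc_normalized"] = 0.0
    table = FCTable(rows[FC_COLUMNS], patients, [])
    return normalize_fc(table)


def crossfit_fc_table(
    model_kind: str,
    samples: list[EncodedSequence],
    vocab: Vocabulary,
    config,
    n_folds: int = 3,
    ensemble: int = 1,
    seed: int = 0,
    features: list[int] | None = None,
) -> FCTable:
    """Cross-fitted contributions: every patient is scored only by models
    that never saw them during training.

    A model fitted and perturbed on the same patients leaks its fit noise
    into the contributions — the sign of a null feature's FC then tracks
    the training labels and inflates the Wilcoxon false-positive rate at
    desk-scale n. Patients are therefore split into ``n_folds`` disjoint
    folds; fold *k* is scored by models trained on the other folds (with a
    20% patient-level validation carve-out for early stopping). With
    ``ensemble`` > 1, several differently-initialised models score each
    fold and their FCs are averaged, damping initialisation noise in the
    per-feature signs. Requires one sample per patient."""
    import dataclasses

    from .models import train as train_model

    pids = sorted({s.patient_id for s in samples})
    if len(pids) != len(samples):
        raise ValueError("cross-fitted FC needs exactly one sample per patient")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(pids))
    frames: list[pd.DataFrame] = []
    registries: list[pd.DataFrame] = []
    for k in range(n_folds):
        hold_ids = set(order[k::n_folds])
        hold = [s for s in samples if s.patient_id in hold_ids]
        fit = [s for s in samples if s.patient_id not in hold_ids]
        rng.shuffle(fit)
        n_val = max(1, len(fit) // 5)
        val, tr = fit[:n_val], fit[n_val:]
        tables = []
        for e in range(ensemble):
            cfg = dataclasses.replace(config, seed=seed + k + 1000 * e)
            model = train_model(model_kind, tr, val, cfg, len(vocab))
            tables.append(compute_fc_table(model, hold, vocab, features=features))
        rows = (
            pd.concat([t.rows for t in tables])
            .groupby(["patient_id", "feature"], as_index=False)
            .agg(fc_raw=("fc_raw", "mean"), fc_normalized=("fc_normalized", "mean"),
                 label=("label", "first"))
        )
        frames.append(rows[FC_COLUMNS] if not rows.empty else rows)
        registries.append(tables[0].patients)
    all_rows = pd.concat(frames, ignore_index=True)
    if all_rows.empty:
        all_rows = pd.DataFrame(columns=FC_COLUMNS)
    return FCTable(all_rows, pd.concat(registries, ignore_index=True), [])


def normalize_fc(table: FCTable) -> FCTable:
    """Scale each patient's FCs by the patient's total |FC|.

    After normalization the absolute normalized contributions of a patient
    sum to 1 (when anything is nonzero); all-zero patients keep zeros and
    are flagged. This is the visit-frequency scaling hook: it stops
    frequently-seen patients from dominating group medians."""
    rows = table.rows.copy()
    if rows.empty:
        return FCTable(rows, table.patients, [])
    denom = rows.groupby("patient_id")["fc_raw"].transform(
        lambda v: np.abs(v).sum()
    )
    rows["fc_normalized"] = np.where(denom > 0, rows["fc_raw"] / denom, 0.0)
    zero_patients = sorted(
        rows.loc[denom == 0, "patient_id"].unique().tolist()
    )
    return FCTable(rows[FC_COLUMNS], table.patients, zero_patients)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (n_x + n_y <= 12),
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class RCResult:
    feature: str
    rc: float  # nan when the non-event median is exactly zero
    p_wilcoxon: float
    q_fdr: float
    p_bonferroni: float
    n_event_patients: int  # exposed patients per group
    n_nonevent_patients: int
    direction: str  # "risk" (rc > 1) or "protective" (rc < 1)
    flag: str | None = None  # UNDEFINED / INDETERMINATE_SIGN


def _group_values(table: FCTable, feature: str):
    """Normalized FCs per label group over the full patient registry,
    unexposed patients entering as zeros. Returns (event values,
    non-event values, exposed-event count, exposed-non-event count)."""
    sub = table.rows[table.rows["feature"] == feature]
    fc_of = dict(zip(sub["patient_id"], sub["fc_normalized"]))
    ev, nev = [], []
    for pid, label in zip(table.patients["patient_id"], table.patients["label"]):
        (ev if label == 1 else nev).append(fc_of.get(pid, 0.0))
    n_ev_exposed = int((sub["label"] == 1).sum())
    n_nev_exposed = int((sub["label"] == 0).sum())
    return np.asarray(ev), np.asarray(nev), n_ev_exposed, n_nev_exposed


def compute_rc(table: FCTable, feature: str) -> RCResult:
    """Median-ratio RC for one feature (rc, direction and counts only;
    p/q fields are filled by :func:`analyze_contributions`)."""
    ev, nev, n_ev, n_nev = _group_values(table, feature)
    med_ev = float(np.median(ev)) if ev.size else np.nan
    med_nev = float(np.median(nev)) if nev.size else np.nan
    flag = None
    if med_nev == 0.0 or np.isnan(med_nev):
        rc = np.nan
        flag = "UNDEFINED"
        direction = "risk"
    else:
        rc = med_ev / med_nev
        if rc < 0:
            flag = "INDETERMINATE_SIGN"
        direction = "risk" if rc > 1 else "protective"
    return RCResult(feature, rc, np.nan, np.nan, np.nan, n_ev, n_nev,
                    direction, flag)


def analyze_contributions(
    table: FCTable,
    features: list[str] | None = None,
    min_support: int = 10,
) -> tuple[list[RCResult], dict[str, str]]:
    """RC + Wilcoxon + FDR/Bonferroni for every feature with enough exposed
    patients per group.

    Features below ``min_support`` exposed patients in either label group
    are reported in the skip map, never silently dropped. The multiplicity
    family is the set of tested features in this call."""
    if features is None:
        features = sorted(table.rows["feature"].unique().tolist())
    results: list[RCResult] = []
    skipped: dict[str, str] = {}
    pvals: list[float] = []
    for feature in features:
        ev, nev, n_ev, n_nev = _group_values(table, feature)
        if min(n_ev, n_nev) < min_support:
            skipped[feature] = (
                f"support {n_ev} event / {n_nev} non-event exposed patients "
                f"below min_support={min_support}"
            )
            continue
        res = compute_rc(table, feature)
        res.p_wilcoxon = wilcoxon_rank_sum(ev, nev)
        pvals.append(res.p_wilcoxon)
        results.append(res)
    if results:
        qs = adjust_fdr(pvals)
        bons = bonferroni(pvals)
        for res, q, b in zip(results, qs, bons):
            res.q_fdr = float(q)
            res.p_bonferroni = float(b)
    return results, skipped


def rc_report(
    results: list[RCResult],
    q_cutoff: float = 0.05,
    dtmap=None,
) -> pd.DataFrame:
    """Significant features sorted ascending by RC (protective end first).

    With a drug-target map, each (protein) feature row carries the list of
    drugs hitting that target — the target-focused report shape."""
    keep = [r for r in results if np.isfinite(r.q_fdr) and r.q_fdr <= q_cutoff]
    keep.sort(key=lambda r: (np.inf if np.isnan(r.rc) else r.rc, r.feature))
    rows = []
    for r in keep:
        row = {
            "feature": r.feature,
            "relative_contribution": r.rc,
            "wilcoxon_p": r.p_wilcoxon,
            "fdr_q": r.q_fdr,
            "bonferroni_p": r.p_bonferroni,
            "direction": r.direction,
            "n_event_patients": r.n_event_patients,
            "n_nonevent_patients": r.n_nonevent_patients,
            "flag": r.flag or "",
        }
        if dtmap is not None:
            row["drug_ids"] = ";".join(sorted(dtmap.drugs_of(r.feature)))
        rows.append(row)
    return pd.DataFrame(rows)
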