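"""Case/control cohort construction from a longitudinal event stream.

Implements the clinical cohort rules for 3-month psychosis onset after an
AD diagnosis:

* a **case** is anchored at the latest encounter that (i) follows an AD
  diagnosis, (ii) has a full look-back year of record behind it, (iii) has
  no psychosis diagnosis or antipsychotic order on or before it, and (iv)
  is followed by the patient's first such outcome event within the outcome
  window;
* a **control** is anchored at the latest encounter satisfying (i)-(iii)
  with no outcome event in the window after it;
* everyone else is excluded with a machine-readable reason.

Windows are half-open: the look-back covers ``[index - lookback, index)``
and the outcome window ``(index, index + window]``, so the anchoring
encounter's own codes belong to neither — the anchor cannot leak its label.
Psychosis diagnoses recorded on the same calendar day as a delirium
diagnosis are masked out first (transient delirium-driven psychosis is not
the outcome of interest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    AD_CODE,
    ANTIPSYCHOTIC_CODE,
    DELIRIUM_CODE,
    PSYCHOSIS_CODE,
    validate_stream,
)

# Exclusion reasons
NO_AD = "NO_AD"
INSUFFICIENT_HISTORY = "INSUFFICIENT_HISTORY"
PRIOR_PSYCHOSIS = "PRIOR_PSYCHOSIS"
PRIOR_ANTIPSYCHOTIC = "PRIOR_ANTIPSYCHOTIC"
NO_ELIGIBLE_ENCOUNTER = "NO_ELIGIBLE_ENCOUNTER"

CASE, CONTROL = 1, 0


@dataclass
class CohortSpec:
    ad_codes: frozenset = frozenset({AD_CODE})
    psychosis_codes: frozenset = frozenset({PSYCHOSIS_CODE})
    antipsychotic_codes: frozenset = frozenset({ANTIPSYCHOTIC_CODE})
    delirium_codes: frozenset = frozenset({DELIRIUM_CODE})
    lookback_days: int = 365
    outcome_window_days: int = 90
    augmentation_max_per_case: int = 0

    def __post_init__(self) -> None:
        if set(self.psychosis_codes) & set(self.delirium_codes):
            raise ValueError("psychosis and delirium code sets must be disjoint")
        if self.lookback_days < 1 or self.outcome_window_days < 1:
            raise ValueError("look-back and outcome windows must be >= 1 day")

    @property
    def outcome_codes(self) -> frozenset:
        return frozenset(self.psychosis_codes) | frozenset(self.antipsychotic_codes)


@dataclass
class LabeledSample:
    patient_id: str
    index_date: pd.Timestamp
    label: int  # 1 = case, 0 = control
    sequence: list  # ordered (date, frozenset[(code_type, code)]) in look-back
    provenance: str = "primary"
    _timeline: pd.DataFrame | None = field(default=None, repr=False, compare=False)


@dataclass
class Exclusion:
    patient_id: str
    reason: str


def mask_delirium_psychosis(stream: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Drop psychosis diagnoses that share a calendar day with a delirium
    diagnosis for the same patient; everything else passes through."""
    validate_stream(stream)
    if stream.empty:
        return stream.copy()
    delirium = stream[stream["code"].isin(spec.delirium_codes)]
    if delirium.empty:
        return stream.copy()
    del_days = set(zip(delirium["patient_id"], delirium["date"].values.astype("datetime64[D]")))
    is_psych = stream["code"].isin(spec.psychosis_codes).to_numpy()
    same_day = np.array(
        [
            (pid, day) in del_days
            for pid, day in zip(
                stream["patient_id"], stream["date"].values.astype("datetime64[D]")
            )
        ]
    )
    return stream[~(is_psych & same_day)].reset_index(drop=True)


def _timeline_days(timeline: pd.DataFrame) -> np.ndarray:
    return timeline["date"].values.astype("datetime64[D]").astype(int)


def _eligible_anchor_days(timeline: pd.DataFrame, spec: CohortSpec):
    """Encounter days with an AD diagnosis strictly before them, a full
    look-back of record, and no outcome on or before them. Returns
    (anchors, first_outcome_day, first_outcome_is_antipsychotic, reason)
    where `reason` is set when no anchor exists."""
    days = _timeline_days(timeline)
    codes = timeline["code"].to_numpy()
    encounters = np.unique(days)
    first_day = encounters[0]

    ad_days = days[np.isin(codes, list(spec.ad_codes))]
    if ad_days.size == 0:
        return None, None, None, NO_AD
    first_ad = ad_days.min()

    out_mask = np.isin(codes, list(spec.outcome_codes))
    t_out = int(days[out_mask].min()) if out_mask.any() else None
    out_is_antipsych = None
    if t_out is not None:
        first_out_codes = set(codes[out_mask & (days == t_out)])
        # same-day tie between psychosis dx and antipsychotic order reads
        # as psychosis for exclusion-reason reporting
        out_is_antipsych = not (first_out_codes & set(spec.psychosis_codes))

    hist_ok = encounters - first_day >= spec.lookback_days
    if not hist_ok.any():
        return None, t_out, out_is_antipsych, INSUFFICIENT_HISTORY
    cands = encounters[hist_ok & (encounters > first_ad)]
    if cands.size == 0:
        return None, t_out, out_is_antipsych, NO_ELIGIBLE_ENCOUNTER
    if t_out is not None:
        cands = cands[cands < t_out]
        if cands.size == 0:
            reason = PRIOR_ANTIPSYCHOTIC if out_is_antipsych else PRIOR_PSYCHOSIS
            return None, t_out, out_is_antipsych, reason
    return cands, t_out, out_is_antipsych, None


def _build_sequence(timeline: pd.DataFrame, index_day: int, spec: CohortSpec):
    days = _timeline_days(timeline)
    in_window = (days >= index_day - spec.lookback_days) & (days < index_day)
    window = timeline[in_window]
    seq = []
    for date, grp in window.groupby(window["date"].values.astype("datetime64[D]")):
        seq.append(
            (pd.Timestamp(date), frozenset(zip(grp["code_type"], grp["code"])))
        )
    seq.sort(key=lambda item: item[0])
    return seq


def _day_to_ts(day: int) -> pd.Timestamp:
    return pd.Timestamp(np.datetime64(int(day), "D"))


def label_patient(timeline: pd.DataFrame, spec: CohortSpec):
    """Classify one patient's sorted timeline as case, control or excluded."""
    if timeline.empty:
        raise ValueError("empty patient timeline")
    dates = timeline["date"].to_numpy()
    if not (dates[:-1] <= dates[1:]).all():
        raise ValueError("patient timeline must be sorted by date")
    pid = str(timeline["patient_id"].iloc[0])

    cands, t_out, _, reason = _eligible_anchor_days(timeline, spec)
    if reason is not None:
        return Exclusion(pid, reason)

    if t_out is not None:
        case_anchors = cands[t_out <= cands + spec.outcome_window_days]
        if case_anchors.size:
            index_day = int(case_anchors.max())
            return LabeledSample(
                pid,
                _day_to_ts(index_day),
                CASE,
                _build_sequence(timeline, index_day, spec),
                provenance=f"case_anchor:{_day_to_ts(index_day).date()}",
                _timeline=timeline,
            )
        # outcome exists but falls beyond the window after every anchor:
        # the latest anchor is outcome-free for 90 days -> control
    index_day = int(cands.max())
    return LabeledSample(
        pid,
        _day_to_ts(index_day),
        CONTROL,
        _build_sequence(timeline, index_day, spec),
        provenance=f"latest_encounter:{_day_to_ts(index_day).date()}",
        _timeline=timeline,
    )


@dataclass
class CohortResult:
    samples: list[LabeledSample]
    exclusions: list[Exclusion]

    @property
    def cases(self):
        return [s for s in self.samples if s.label == CASE]

    @property
    def controls(self):
        return [s for s in self.samples if s.label == CONTROL]


def build_cohort(stream: pd.DataFrame, spec: CohortSpec) -> CohortResult:
    """Mask delirium-coincident psychosis, then label every patient."""
    masked = mask_delirium_psychosis(stream, spec)
    samples: list[LabeledSample] = []
    exclusions: list[Exclusion] = []
    for _, timeline in masked.groupby("patient_id", sort=True):
        timeline = timeline.sort_values(
            ["date", "code_type", "code"], kind="mergesort"
        ).reset_index(drop=True)
        result = label_patient(timeline, spec)
        if isinstance(result, Exclusion):
            exclusions.append(result)
        else:
            samples.append(result)
    return CohortResult(samples, exclusions)


def augment_cases(
    samples: list[LabeledSample], spec: CohortSpec, seed: int = 0
) -> list[LabeledSample]:
    """Multi-anchor case augmentation.

    Each case contributes up to ``augmentation_max_per_case`` extra samples
    anchored at distinct *earlier* encounters that still satisfy every case
    criterion (anchors are taken latest-first, so augmented windows stay
    closest to the outcome). Controls pass through untouched; no events are
    fabricated. ``seed`` is part of the stable interface; anchor choice is
    deterministic."""
    del seed
    out: list[LabeledSample] = []
    for sample in samples:
        out.append(sample)
        if sample.label != CASE or spec.augmentation_max_per_case <= 0:
            continue
        if sample._timeline is None:
            continue
        cands, t_out, _, reason = _eligible_anchor_days(sample._timeline, spec)
        if reason is not None or t_out is None:
            continue
        index_day = int(
            sample.index_date.to_datetime64().astype("datetime64[D]").astype(int)
        )
        extra = cands[(t_out <= cands + spec.outcome_window_days) & (cands < index_day)]
        for day in sorted(extra, reverse=True)[: spec.augmentation_max_per_case]:
            out.append(
                LabeledSample(
                    sample.patient_id,
                    _day_to_ts(int(day)),
                    CASE,
                    _build_sequence(sample._timeline, int(day), spec),
                    provenance=f"augmented:{_day_to_ts(int(day)).date()}",
                    _timeline=sample._timeline,
                )
            )
    return out


def split_cohort(samples: list[LabeledSample], seed: int = 0):
    """Partition *patients* 8:1:1 into train/validation/test.

    All samples from one patient land in one partition (augmented copies can
    never leak across splits)."""
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 10:
        raise ValueError("need at least 10 distinct patients to split 8:1:1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n = len(patients)
    n_test = max(1, round(0.1 * n))
    n_val = max(1, round(0.1 * n))
    test_p = set(order[:n_test])
    val_p = set(order[n_test : n_test + n_val])
    train = [s for s in samples if s.patient_id not in test_p | val_p]
    val = [s for s in samples if s.patient_id in val_p]
    test = [s for s in samples if s.patient_id in test_p]
    return train, val, test


def cohort_manifest(
    result: CohortResult, split_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Flat per-sample manifest (plus excluded patients) for audit output."""
    rows = []
    for s in result.samples:
        rows.append(
            {
                "patient_id": s.patient_id,
                "index_date": s.index_date.date().isoformat(),
                "label": "case" if s.label == CASE else "control",
                "split": (split_of or {}).get(s.patient_id, ""),
                "n_events_in_window": sum(len(codes) for _, codes in s.sequence),
                "provenance": s.provenance,
            }
        )
    for e in result.exclusions:
        rows.append(
            {
                "patient_id": e.patient_id,
                "index_date": "",
                "label": f"excluded:{e.reason}",
                "split": "",
                "n_events_in_window": 0,
                "provenance": "",
            }
        )
    return pd.DataFrame(rows)
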