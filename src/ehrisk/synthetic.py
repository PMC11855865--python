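"""Seeded synthetic EHR cohort generator with planted ground-truth effects.

Emulates the shape of a longitudinal claims/EMR extract: each patient has a
Poisson number of encounter dates spread over an observation period, each
encounter carries diagnosis / medication / abnormal-lab tokens drawn
independently per-code at configurable per-visit prevalences, and a binary
90-day outcome is generated from a logistic model over the codes the
patient carried in a one-year look-back window before a randomly chosen
anchor encounter. Cases get a psychosis-diagnosis or antipsychotic-order
event appended inside the outcome window, so the downstream cohort rules
can re-derive the labels from the stream alone.

Determinism: one global seed; per-patient generators are spawned from a
``numpy.random.SeedSequence`` so the stream is reproducible byte-for-byte
and insensitive to patient-count-preserving refactors of the loop body.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import sigmoid
from .events import (
    AD_CODE,
    ANTIPSYCHOTIC_CODE,
    CODE_TYPES,
    DIAG,
    MED,
    PSYCHOSIS_CODE,
    STREAM_COLUMNS,
    empty_stream,
)
from .targets import DrugTargetMap

EPOCH = np.datetime64("2010-01-01")


@dataclass
class CodeSpec:
    code: str
    code_type: str
    prevalence: float  # per-visit carry probability


@dataclass
class SimulationConfig:
    n_patients: int
    code_catalog: list[CodeSpec]
    effects: dict[str, float] = field(default_factory=dict)
    baseline_logit: float = -1.4
    observation_days: int = 540
    lookback_days: int = 365
    outcome_window_days: int = 90
    visits_per_patient: float = 12.0
    order_effects: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.observation_days < self.lookback_days + self.outcome_window_days:
            raise ValueError(
                "observation_days must cover look-back plus outcome window"
            )
        if self.visits_per_patient <= 0:
            raise ValueError("visits_per_patient must be positive")
        for spec in self.code_catalog:
            if not (0.0 < spec.prevalence < 1.0):
                raise ValueError(
                    f"prevalence for code {spec.code!r} must lie in (0, 1), "
                    f"got {spec.prevalence}"
                )
            if spec.code_type not in CODE_TYPES:
                raise ValueError(f"unknown code_type for {spec.code!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    code_effects: dict[str, float]
    case_rate: float  # realized fraction; nan for an empty cohort
    target_effects: dict[str, float] = field(default_factory=dict)
    anchor_day: dict[str, int] = field(default_factory=dict)
    outcome_day: dict[str, int] = field(default_factory=dict)  # cases only

    def to_json(self, path) -> None:
        payload = {
            "code_effects": self.code_effects,
            "case_rate": self.case_rate,
            "target_effects": self.target_effects,
            "anchor_day": self.anchor_day,
            "outcome_day": self.outcome_day,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _patient_visits(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Encounter day offsets: Poisson count (floor 2), guaranteed to span
    the look-back so at least one eligible anchor exists."""
    n_visits = max(2, int(rng.poisson(cfg.visits_per_patient)))
    n_visits = min(n_visits, cfg.observation_days)
    days = rng.choice(cfg.observation_days, size=n_visits, replace=False)
    days.sort()
    days[0] = 0
    if days[-1] < cfg.lookback_days:
        days[-1] = int(rng.integers(cfg.lookback_days, cfg.observation_days))
    return np.unique(days)


def generate_cohort_stream(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the event stream and return it with its ground truth."""
    config.validate()
    if config.n_patients <= 0:
        truth = GroundTruth(code_effects=dict(config.effects), case_rate=float("nan"))
        return empty_stream(), truth

    codes = [s.code for s in config.code_catalog]
    ctypes = [s.code_type for s in config.code_catalog]
    prev = np.array([s.prevalence for s in config.code_catalog])
    beta = np.array([config.effects.get(c, 0.0) for c in codes])

    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    rows_pid: list[str] = []
    rows_day: list[int] = []
    rows_type: list[str] = []
    rows_code: list[str] = []
    truth = GroundTruth(code_effects={c: config.effects.get(c, 0.0) for c in codes},
                        case_rate=0.0)
    n_cases = 0

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i:05d}"
        days = _patient_visits(rng, config)
        carried = rng.random((len(days), len(prev))) < prev  # visits x codes

        for vi, day in enumerate(days):
            for ci in np.flatnonzero(carried[vi]):
                rows_pid.append(pid)
                rows_day.append(int(day))
                rows_type.append(ctypes[ci])
                rows_code.append(codes[ci])
        # AD diagnosis planted at the first encounter
        rows_pid.append(pid)
        rows_day.append(int(days[0]))
        rows_type.append(DIAG)
        rows_code.append(AD_CODE)

        # anchor at the latest eligible encounter, mirroring the cohort
        # rule's "latest encounter" indexing so the generative look-back
        # window coincides with the window the cohort builder will extract
        anchors = days[days >= days[0] + config.lookback_days]
        anchor = int(anchors.max())
        truth.anchor_day[pid] = anchor

        in_window = (days >= anchor - config.lookback_days) & (days < anchor)
        exposed = carried[in_window].any(axis=0)
        z = config.baseline_logit + float(beta @ exposed)
        for code_a, code_b, b_order in config.order_effects:
            z += _order_term(days[in_window], carried[in_window],
                             codes, code_a, code_b, b_order)
        if rng.random() < sigmoid(z):
            n_cases += 1
            outcome_day = anchor + int(rng.integers(1, config.outcome_window_days + 1))
            truth.outcome_day[pid] = outcome_day
            if rng.random() < 0.5:
                out_type, out_code = DIAG, PSYCHOSIS_CODE
            else:
                out_type, out_code = MED, ANTIPSYCHOTIC_CODE
            rows_pid.append(pid)
            rows_day.append(outcome_day)
            rows_type.append(out_type)
            rows_code.append(out_code)

    truth.case_rate = n_cases / config.n_patients
    stream = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "date": EPOCH + np.array(rows_day, dtype="timedelta64[D]"),
            "code_type": rows_type,
            "code": rows_code,
        }
    )
    stream = stream.sort_values(STREAM_COLUMNS, kind="mergesort").reset_index(drop=True)
    return stream, truth


def _order_term(days, carried, codes, code_a, code_b, beta_order) -> float:
    """Order-dependent logit term: fires when a's first occurrence in the
    look-back precedes b's."""
    try:
        ia, ib = codes.index(code_a), codes.index(code_b)
    except ValueError:
        return 0.0
    a_days = days[carried[:, ia]]
    b_days = days[carried[:, ib]]
    if len(a_days) and len(b_days) and a_days[0] < b_days[0]:
        return beta_order
    return 0.0


def generate_drug_target_map(
    n_drugs: int, n_targets: int, mean_targets_per_drug: float = 1.5,
    seed: int = 0,
) -> DrugTargetMap:
    """Random bipartite drug->protein map; every drug gets >= 1 target.

    With more drugs than targets, target sharing follows by pigeonhole,
    reproducing the many-drugs-per-protein structure of curated target
    databases.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    proteins = [f"PRT{j:04d}" for j in range(n_targets)]
    forward: dict[str, frozenset[str]] = {}
    for i in range(n_drugs):
        k = int(np.clip(rng.poisson(mean_targets_per_drug), 1, n_targets))
        chosen = rng.choice(n_targets, size=k, replace=False)
        forward[f"DB{i:05d}"] = frozenset(proteins[j] for j in chosen)
    return DrugTargetMap(forward)


def target_effects_from_map(
    code_effects: dict[str, float], dtmap: DrugTargetMap
) -> dict[str, float]:
    """Per-protein planted effect: mean beta of the drugs hitting it."""
    out = {}
    for prot in dtmap.proteins:
        drugs = dtmap.drugs_of(prot)
        out[prot] = float(np.mean([code_effects.get(d, 0.0) for d in drugs]))
    return out
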