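"""Vocabulary construction and integer encoding of visit sequences.

Tokens are ``(code_type, code)`` pairs. Lab tokens are capped to the
top-K most frequently abnormal tests (patient-level frequency, K = 89 by
default); the total vocabulary is capped at 30,000 with index 0 reserved
for out-of-vocabulary tokens. The vocabulary is built from the training
split only, so no test-set information leaks into the feature space.
Diagnosis codes can optionally be collapsed to 3-character ICD-10 groups
via a ICD-9 -> ICD-10 lookup.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .cohort import LabeledSample
from .events import CODE_TYPES, DIAG, LAB_ABN

log = logging.getLogger(__name__)

OOV_INDEX = 0
OOV_TOKEN = ("OOV", "OOV")

_ICD10_RE = re.compile(r"^[A-TV-Z][0-9][0-9A-Z]")
_CODE_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._-]*$")


@dataclass
class Vocabulary:
    index: dict[tuple[str, str], int]  # token -> dense index, OOV = 0
    lab_top_k: int = 89
    max_size: int = 30_000
    tokens: list[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.tokens = [OOV_TOKEN] * len(self)
        for tok, i in self.index.items():
            self.tokens[i] = tok

    def __len__(self) -> int:
        return max(self.index.values()) + 1 if self.index else 1

    def lookup(self, token: tuple[str, str]) -> int:
        return self.index.get(token, OOV_INDEX)

    def type_of(self, idx: int) -> str:
        return self.tokens[idx][0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("code\tindex\n")
            for tok in sorted(self.index, key=self.index.get):
                fh.write(f"{tok[0]}:{tok[1]}\t{self.index[tok]}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"code": str, "index": int})
        idx = {}
        for key, i in zip(df["code"], df["index"]):
            ctype, code = key.split(":", 1)
            idx[(ctype, code)] = int(i)
        idx.pop(OOV_TOKEN, None)
        return cls(idx)


@dataclass
class EncodedSequence:
    """Visit-level integer encoding: (index set, day gap to previous visit)."""

    visits: list[tuple[frozenset[int], int]]
    label: int
    patient_id: str = ""

    @property
    def length(self) -> int:
        return len(self.visits)


def load_icd_lookup(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def map_icd9_to_icd10(code: str, lookup: dict[str, str]) -> str:
    """Map a diagnosis code to its ICD-10 3-character group.

    ICD-9 codes go through the lookup; ICD-10 codes truncate to their
    3-character category; anything unmapped returns the OOV marker (logged
    once per code)."""
    if not isinstance(code, str) or not _CODE_RE.match(code or ""):
        raise ValueError(f"malformed diagnosis code: {code!r}")
    if code in lookup:
        return lookup[code]
    if _ICD10_RE.match(code):
        return code[:3]
    log.warning("diagnosis code %s not in ICD lookup; mapped to OOV", code)
    return OOV_TOKEN[1]


def group_diagnoses(
    sample: LabeledSample, lookup: dict[str, str]
) -> LabeledSample:
    """Collapse DIAG codes in a sample's sequence to diagnosis groups."""
    seq = []
    for date, codes in sample.sequence:
        seq.append(
            (
                date,
                frozenset(
                    (ct, map_icd9_to_icd10(c, lookup)) if ct == DIAG else (ct, c)
                    for ct, c in codes
                ),
            )
        )
    return LabeledSample(
        sample.patient_id, sample.index_date, sample.label, seq,
        provenance=sample.provenance,
    )


def build_vocabulary(
    train_samples: list[LabeledSample],
    lab_top_k: int = 89,
    max_size: int = 30_000,
) -> Vocabulary:
    """Frequency-capped vocabulary from the training split.

    Lab tokens are ranked by the number of distinct patients carrying them
    and only the top K kept; all retained tokens are then indexed by
    frequency (descending) with a lexicographic tie-break, capped at
    ``max_size`` including the reserved OOV slot."""
    if not train_samples:
        raise ValueError("cannot build a vocabulary from an empty training split")
    patient_counts: dict[tuple[str, str], set[str]] = {}
    for s in train_samples:
        for _, codes in s.sequence:
            for tok in codes:
                patient_counts.setdefault(tok, set()).add(s.patient_id)
    freq = {tok: len(pids) for tok, pids in patient_counts.items()}

    labs = sorted(
        (t for t in freq if t[0] == LAB_ABN), key=lambda t: (-freq[t], t)
    )[:lab_top_k]
    others = [t for t in freq if t[0] != LAB_ABN]
    retained = sorted(labs + others, key=lambda t: (-freq[t], t))[: max_size - 1]
    index = {tok: i + 1 for i, tok in enumerate(retained)}
    return Vocabulary(index, lab_top_k=lab_top_k, max_size=max_size)


def encode_sample(sample: LabeledSample, vocab: Vocabulary) -> EncodedSequence:
    """Render a labeled sample as an integer visit sequence with day gaps."""
    visits = []
    prev_date = None
    for date, codes in sorted(sample.sequence, key=lambda item: item[0]):
        idxs = frozenset(vocab.lookup(tok) for tok in codes)
        delta = 0 if prev_date is None else int((date - prev_date).days)
        if idxs:
            visits.append((idxs, delta))
            prev_date = date
    return EncodedSequence(visits, sample.label, sample.patient_id)


def decode_sample(enc: EncodedSequence, vocab: Vocabulary) -> list[frozenset]:
    """Per-visit token sets (OOV indices decode to the OOV token)."""
    return [frozenset(vocab.tokens[i] for i in idxs) for idxs, _ in enc.visits]


def ablate(
    samples: list[EncodedSequence], drop: str, vocab: Vocabulary
) -> list[EncodedSequence]:
    """Remove every index of one code type; drop visits that become empty.

    Day gaps of surviving visits are re-derived from cumulative time, so
    removing a visit merges its gap into the next one."""
    if drop not in CODE_TYPES:
        raise ValueError(f"unknown code_type {drop!r}")
    dropped = {i for i in range(len(vocab)) if vocab.type_of(i) == drop}
    out = []
    for s in samples:
        cum = 0
        kept: list[tuple[frozenset[int], int]] = []
        prev_cum = None
        for idxs, delta in s.visits:
            cum += delta
            remaining = frozenset(idxs - dropped)
            if not remaining:
                continue
            gap = 0 if prev_cum is None else cum - prev_cum
            kept.append((remaining, gap))
            prev_cum = cum
        out.append(EncodedSequence(kept, s.label, s.patient_id))
    return out


def write_jsonl(samples: list[EncodedSequence], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {
                        "patient_id": s.patient_id,
                        "label": s.label,
                        "visits": [[sorted(ix), d] for ix, d in s.visits],
                    }
                )
                + "\n"
            )


def read_jsonl(path) -> list[EncodedSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            out.append(
                EncodedSequence(
                    [(frozenset(ix), int(d)) for ix, d in obj["visits"]],
                    int(obj["label"]),
                    obj["patient_id"],
                )
            )
    return out
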