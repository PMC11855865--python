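"""Drug->protein-target layer.

Two complementary uses, mirroring the two repurposing analyses:

* **target substitution** (target-focused runs): before vocabulary
  construction, each mapped medication token in a patient sequence is
  replaced by the full set of its protein-target tokens, pooling patients
  across drugs that share a target and thereby raising per-feature support.
* **target pooling** (drug-focused runs): after perturbation analysis at the
  drug level, per-patient feature contributions of all drugs hitting a
  protein are summed into a per-patient protein contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .events import MED, TARGET


@dataclass
class DrugTargetMap:
    """Many-to-many drug -> protein relation with a derived inverse."""

    forward: dict[str, frozenset[str]]
    inverse: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        for drug, prots in self.forward.items():
            if not prots:
                raise ValueError(f"drug {drug!r} mapped to an empty target set")
        inv: dict[str, set[str]] = {}
        for drug, prots in self.forward.items():
            for p in prots:
                inv.setdefault(p, set()).add(drug)
        self.inverse = {p: frozenset(ds) for p, ds in inv.items()}

    def targets_of(self, drug: str) -> frozenset[str]:
        return self.forward.get(drug, frozenset())

    def drugs_of(self, protein: str) -> frozenset[str]:
        return self.inverse.get(protein, frozenset())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.forward)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.inverse)

    # -- I/O: two-column TSV, one (drug, protein) pair per row -------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\tprotein_id\n")
            for drug in sorted(self.forward):
                for prot in sorted(self.forward[drug]):
                    fh.write(f"{drug}\t{prot}\n")

    @classmethod
    def from_tsv(cls, path) -> "DrugTargetMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["drug_id", "protein_id"]:
            raise ValueError(
                "drug-target TSV must have columns drug_id, protein_id"
            )
        fwd: dict[str, set[str]] = {}
        for drug, prot in zip(df["drug_id"], df["protein_id"]):
            fwd.setdefault(drug, set()).add(prot)
        return cls({d: frozenset(ps) for d, ps in fwd.items()})


def substitute_targets(
    sequence: list[tuple], dtmap: DrugTargetMap
) -> list[tuple]:
    """Replace mapped medication tokens with their protein-target tokens.

    Operates on the decoded visit view: a list of ``(date, codeset)`` where
    each codeset holds ``(code_type, code)`` pairs. Unmapped medications and
    all non-medication tokens pass through unchanged.
    """
    out = []
    for date, codes in sequence:
        new_codes = set()
        for ctype, code in codes:
            prots = dtmap.targets_of(code) if ctype == MED else frozenset()
            if ctype == MED and prots:
                new_codes.update((TARGET, p) for p in prots)
            else:
                new_codes.add((ctype, code))
        out.append((date, frozenset(new_codes)))
    return out


def pool_fc_by_target(fc_table: "pd.DataFrame", dtmap: DrugTargetMap) -> pd.DataFrame:
    """Sum per-patient drug contributions onto shared protein targets.

    ``fc_table`` rows are (patient_id, feature, fc_raw, fc_normalized,
    label) at the drug level; the result has the same shape keyed by
    protein. A patient appears under a protein only if exposed to at least
    one mapped drug; additive pooling keeps the singleton-map identity
    (one drug per target => protein table equals the drug table).
    """
    rows = fc_table[fc_table["feature"].isin(dtmap.forward)]
    if rows.empty:
        return fc_table.iloc[0:0].copy()
    expanded = []
    for feature, sub in rows.groupby("feature", sort=True):
        for prot in sorted(dtmap.targets_of(feature)):
            block = sub.copy()
            block["feature"] = prot
            expanded.append(block)
    pooled = (
        pd.concat(expanded, ignore_index=True)
        .groupby(["patient_id", "feature"], as_index=False)
        .agg(fc_raw=("fc_raw", "sum"), fc_normalized=("fc_normalized", "sum"),
             label=("label", "first"))
    )
    return pooled[["patient_id", "feature", "fc_raw", "fc_normalized", "label"]]
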