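"""Contribution statistics: occlusion FC, normalization, RC, rank tests,
multiplicity corrections — with independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrisk.autodiff import sigmoid
from ehrisk.contrib import (
    FCTable,
    adjust_fdr,
    analyze_contributions,
    bonferroni,
    compute_fc_table,
    compute_rc,
    normalize_fc,
    occlusion_fc,
    rc_report,
    wilcoxon_rank_sum,
)
from ehrisk.encoding import EncodedSequence, Vocabulary
from ehrisk.events import DIAG, MED
from ehrisk.models import make_logistic_model


def make_table(event_fcs, nonevent_fcs, feature="F"):
    rows = []
    for i, v in enumerate(event_fcs):
        rows.append((f"e{i}", feature, v, v, 1))
    for i, v in enumerate(nonevent_fcs):
        rows.append((f"n{i}", feature, v, v, 0))
    df = pd.DataFrame(
        rows, columns=["patient_id", "feature", "fc_raw", "fc_normalized", "label"]
    )
    patients = df[["patient_id", "label"]].drop_duplicates()
    return FCTable(df, patients, [])


# -- exact oracles ----------------------------------------------------------

def enumerate_rank_sum_p(x, y):
    """Two-sided Wilcoxon p by full enumeration of all group assignments
    (tie-free data), using the 2*min(tail) convention."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = [
        sum(pi > pj for pi in combo for pj in pooled if pj not in combo)
        for combo in itertools.combinations(pooled, n1)
    ]
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(combo)]
        rest = np.delete(pooled, list(combo))
        us.append(sum(gi > rj for gi in grp for rj in rest))
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / (np.sum(p <= p[j])) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestWilcoxon:
    def test_textbook_example_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_full_enumeration_small_samples(self, rng):
        """Exact implementation agrees with brute-force enumeration for
        every partition size with n <= 8."""
        for n1 in range(1, 5):
            for n2 in range(1, 9 - n1):
                vals = rng.normal(size=n1 + n2)
                while np.unique(vals).size < vals.size:
                    vals = rng.normal(size=n1 + n2)
                x, y = vals[:n1], vals[n1:]
                assert wilcoxon_rank_sum(x, y) == pytest.approx(
                    enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            hits += wilcoxon_rank_sum(x, y) < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestMultiplicity:
    def test_bh_worked_example(self):
        q = adjust_fdr([0.001, 0.01, 0.02, 0.05])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0267, 0.05], atol=1e-4)

    def test_bh_single_p_identity(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_bh_all_ones(self):
        assert np.all(adjust_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_bh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=25))
    def test_bh_matches_brute_force(self, ps):
        np.testing.assert_allclose(adjust_fdr(ps), brute_force_bh(ps),
                                   atol=1e-12)

    def test_bonferroni_examples(self):
        np.testing.assert_allclose(bonferroni([0.01] * 4), [0.04] * 4)
        assert bonferroni([0.5] + [0.0] * 9)[0] == 1.0
        assert bonferroni([0.2])[0] == pytest.approx(0.2)


class TestOcclusionFC:
    def _vocab(self, size=6):
        return Vocabulary({(DIAG, f"C{i}"): i for i in range(1, size)})

    def test_absent_feature_zero_without_model_calls(self):
        model = make_logistic_model(np.ones(6), 0.0)
        s = EncodedSequence([(frozenset({1}), 0)], 1, "p")
        assert occlusion_fc(model, s, 5) == 0.0

    def test_logistic_single_occurrence_closed_form(self, rng):
        coef = rng.normal(size=6)
        model = make_logistic_model(coef, 0.3)
        s = EncodedSequence([(frozenset({1, 2}), 0), (frozenset({4}), 30)], 1, "p")
        z = coef[1] + coef[2] + coef[4] + 0.3
        expected = sigmoid(z) - sigmoid(z - coef[2])
        assert occlusion_fc(model, s, 2) == pytest.approx(float(expected),
                                                          abs=1e-12)

    def test_repeated_code_under_presence_bag_contributes_zero(self):
        # removing one of two occurrences leaves the presence bag intact
        model = make_logistic_model(np.ones(6), 0.0)
        s = EncodedSequence([(frozenset({2}), 0), (frozenset({2}), 10)], 1, "p")
        assert occlusion_fc(model, s, 2) == pytest.approx(0.0)

    def test_fc_table_matches_occlusion_fc(self, rng):
        vocab = self._vocab()
        coef = rng.normal(size=len(vocab))
        model = make_logistic_model(coef, -0.2)
        samples = []
        for i in range(5):
            visits = []
            for v in range(3):
                idxs = frozenset(int(j) for j in
                                 np.flatnonzero(rng.random(len(vocab)) < 0.4)
                                 if j != 0)
                if idxs:
                    visits.append((idxs, 10 * v))
            samples.append(EncodedSequence(visits, int(rng.random() < 0.5),
                                           f"p{i}"))
        table = compute_fc_table(model, samples, vocab)
        for _, row in table.rows.iterrows():
            s = next(x for x in samples if x.patient_id == row["patient_id"])
            idx = next(i for i, tok in enumerate(vocab.tokens)
                       if tok[1] == row["feature"])
            assert row["fc_raw"] == pytest.approx(
                occlusion_fc(model, s, idx), abs=1e-10)


class TestNormalization:
    def test_worked_example(self):
        table = make_table([], [])
        df = pd.DataFrame(
            [("p1", "A", 0.3, 0.0, 1), ("p1", "B", 0.1, 0.0, 1)],
            columns=["patient_id", "feature", "fc_raw", "fc_normalized", "label"],
        )
        out = normalize_fc(FCTable(df, df[["patient_id", "label"]].drop_duplicates(), []))
        vals = dict(zip(out.rows["feature"], out.rows["fc_normalized"]))
        assert vals == {"A": pytest.approx(0.75), "B": pytest.approx(0.25)}

    def test_single_negative_feature_normalizes_to_minus_one(self):
        df = pd.DataFrame(
            [("p1", "A", -0.2, 0.0, 1)],
            columns=["patient_id", "feature", "fc_raw", "fc_normalized", "label"],
        )
        out = normalize_fc(FCTable(df, df[["patient_id", "label"]], []))
        assert out.rows["fc_normalized"].item() == pytest.approx(-1.0)

    def test_all_zero_patient_flagged_and_kept_zero(self):
        df = pd.DataFrame(
            [("p1", "A", 0.0, 0.0, 1), ("p2", "A", 0.5, 0.0, 0)],
            columns=["patient_id", "feature", "fc_raw", "fc_normalized", "label"],
        )
        out = normalize_fc(FCTable(df, df[["patient_id", "label"]], []))
        assert out.all_zero_patients == ["p1"]
        assert out.rows.loc[out.rows.patient_id == "p1", "fc_normalized"].item() == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=1,
                    max_size=8))
    def test_absolute_normalized_mass_is_one(self, fcs):
        df = pd.DataFrame(
            [("p1", f"F{i}", v, 0.0, 1) for i, v in enumerate(fcs)],
            columns=["patient_id", "feature", "fc_raw", "fc_normalized", "label"],
        )
        out = normalize_fc(FCTable(df, df[["patient_id", "label"]].drop_duplicates(), []))
        total = out.rows["fc_normalized"].abs().sum()
        if any(v != 0 for v in fcs):
            assert total == pytest.approx(1.0)
        else:
            assert total == 0.0


class TestRelativeContribution:
    def test_median_ratio_worked_example(self):
        table = make_table([0.2, 0.4, 0.6], [0.1, 0.2, 0.3])
        r = compute_rc(table, "F")
        assert r.rc == pytest.approx(2.0)
        assert r.direction == "risk"

    def test_identical_groups_give_unit_rc(self):
        table = make_table([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert compute_rc(table, "F").rc == pytest.approx(1.0)

    def test_protective_direction(self):
        table = make_table([0.05, 0.1, 0.15], [0.1, 0.2, 0.3])
        r = compute_rc(table, "F")
        assert r.rc == pytest.approx(0.5)
        assert r.direction == "protective"

    def test_zero_denominator_flagged_undefined(self):
        table = make_table([0.2, 0.3, 0.4], [-0.1, 0.0, 0.1])
        r = compute_rc(table, "F")
        assert np.isnan(r.rc) and r.flag == "UNDEFINED"

    def test_negative_ratio_flagged_indeterminate(self):
        table = make_table([-0.2, -0.3, -0.4], [0.1, 0.2, 0.3])
        assert compute_rc(table, "F").flag == "INDETERMINATE_SIGN"

    def test_min_support_skips_with_reason(self):
        table = make_table([0.2] * 3, [0.1] * 20)
        results, skipped = analyze_contributions(table, min_support=5)
        assert results == [] and "below min_support" in skipped["F"]

    def test_unexposed_patients_enter_as_zeros(self):
        """Patients registered in the cohort but never exposed pull the
        group medians toward zero."""
        table = make_table([0.5] * 6, [0.5] * 6)
        extra = pd.DataFrame(
            {"patient_id": [f"x{i}" for i in range(8)],
             "label": [0] * 8}
        )
        table = FCTable(table.rows, pd.concat([table.patients, extra]), [])
        r = compute_rc(table, "F")
        # non-event median now sits in the zero block -> undefined ratio
        assert np.isnan(r.rc) and r.flag == "UNDEFINED"


class TestReport:
    def _results(self):
        table_rows = []
        results = []
        for feat, rc, q in [("ket", 1.96, 0.011), ("phe", 0.29, 0.001),
                            ("oxy", 0.52, 0.02), ("ns", 1.4, 0.3)]:
            from ehrisk.contrib import RCResult
            results.append(RCResult(feat, rc, q / 2, q, min(1.0, q * 10),
                                    20, 30, "risk" if rc > 1 else "protective"))
        return results

    def test_sorted_ascending_by_rc_protective_first(self):
        report = rc_report(self._results(), q_cutoff=0.05)
        assert list(report["feature"]) == ["phe", "oxy", "ket"]

    def test_all_insignificant_gives_empty_report(self):
        results = self._results()
        for r in results:
            r.q_fdr = 0.9
        assert rc_report(results).empty

    def test_duplicate_rc_breaks_ties_by_name(self):
        from ehrisk.contrib import RCResult
        results = [RCResult(f, 0.5, 0.01, 0.01, 0.04, 10, 10, "protective")
                   for f in ("b", "a")]
        assert list(rc_report(results)["feature"]) == ["a", "b"]

    def test_target_report_carries_drug_lists(self):
        from ehrisk.contrib import RCResult
        from ehrisk.targets import DrugTargetMap
        dtmap = DrugTargetMap({"d1": frozenset({"P1"}), "d2": frozenset({"P1"})})
        results = [RCResult("P1", 1.5, 0.01, 0.01, 0.02, 15, 15, "risk")]
        report = rc_report(results, dtmap=dtmap)
        assert report["drug_ids"].item() == "d1;d2"
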