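from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mbda.core import Cohort, MarkerConcentration, PatientRecord
from mbda.evaluate import (
    auroc,
    change_correlation,
    crp_contribution,
    evaluation_report,
    loocv_scores,
)


def auroc_pair_oracle(scores, labels):
    """Brute-force pair counting: concordant + half ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_spec_example(self):
        # pos scores {2,4}, neg {1,3}: 3 of 4 pairs concordant -> 0.75
        assert auroc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)
        assert auroc_pair_oracle([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_one_class_empty_raises(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_matches_oracle_enumeration_small_n(self):
        # exhaustive over score grid {0,1,2} and all label splits, n <= 5
        for n in range(2, 6):
            for scores in itertools.product([0.0, 1.0, 2.0], repeat=n):
                for labels in itertools.product([0, 1], repeat=n):
                    if 0 < sum(labels) < n:
                        assert auroc(scores, labels) == pytest.approx(
                            auroc_pair_oracle(scores, labels)
                        )

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_oracle_random_n8(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        assert auroc(scores, labels) == pytest.approx(auroc_pair_oracle(scores, labels))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.01, 50, allow_nan=False), min_size=4, max_size=12))
    def test_invariant_under_monotone_transform(self, scores):
        n = len(scores)
        labels = [i % 2 for i in range(n)]
        a = auroc(scores, labels)
        b = auroc(np.log(np.asarray(scores)), labels)
        c = auroc(np.asarray(scores) ** 3, labels)
        assert a == pytest.approx(b) == pytest.approx(c)


def _mean_trainer(train: Cohort):
    mean = np.mean([r.tjc28 for r in train])
    return lambda record: mean


class TestLoocv:
    def test_constant_outcome(self):
        records = [
            PatientRecord(patient_id=f"P{i}", tjc28=7, sjc28=0, pga=0, crp_mg_l=0)
            for i in range(5)
        ]
        out = loocv_scores(Cohort(records=records), _mean_trainer)
        assert np.allclose(out["prediction"], 7.0)

    def test_noiseless_linear_cohort_recovered(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(20):
            x = float(rng.uniform(1, 100))
            records.append(
                PatientRecord(
                    patient_id=f"P{i}",
                    markers={"IL6": MarkerConcentration("IL6", x)},
                    tjc28=int(np.clip(round(x / 5), 0, 28)),
                    sjc28=0, pga=0, crp_mg_l=0,
                )
            )
        truth = {r.patient_id: r.tjc28 for r in records}

        def trainer(train: Cohort):
            X = np.array([r.marker_value("IL6") for r in train])
            y = np.array([float(r.tjc28) for r in train])
            A = np.column_stack([np.ones(len(X)), X])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            return lambda rec: beta[0] + beta[1] * rec.marker_value("IL6")

        out = loocv_scores(Cohort(records=records), trainer)
        for _, row in out.iterrows():
            assert row["prediction"] == pytest.approx(
                truth[row["patient_id"]], abs=0.6
            )

    def test_patient_level_unit_multi_visit(self):
        # all visits of the held-out patient leave training together
        seen = []

        def spy_trainer(train: Cohort):
            seen.append({r.patient_id for r in train})
            return lambda rec: 0.0

        records = [
            PatientRecord(patient_id=f"P{i}", visit_id=str(v), tjc28=1,
                          sjc28=0, pga=0, crp_mg_l=0)
            for i in range(3)
            for v in range(2)
        ]
        loocv_scores(Cohort(records=records), spy_trainer)
        for pids in seen:
            assert len(pids) == 2  # one patient fully excluded per fold

    def test_trainer_failure_gives_na(self):
        def bad_trainer(train):
            raise RuntimeError("no fit")

        records = [
            PatientRecord(patient_id=f"P{i}", tjc28=1, sjc28=0, pga=0, crp_mg_l=0)
            for i in range(4)
        ]
        out = loocv_scores(Cohort(records=records), bad_trainer)
        assert out["prediction"].isna().all()

    def test_too_small_raises(self):
        records = [
            PatientRecord(patient_id="P1", tjc28=1, sjc28=0, pga=0, crp_mg_l=0)
        ]
        with pytest.raises(ValueError):
            loocv_scores(Cohort(records=records), _mean_trainer)


class TestChangeCorrelation:
    def test_identical_deltas(self):
        rho, _ = change_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        rho, _ = change_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_five_pairs(self):
        a = [0.3, -1.2, 2.0, 0.9, -0.4]
        b = [1.0, -0.5, 0.8, 2.2, -2.0]
        # brute-force Spearman: Pearson correlation of ranks
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        expected = np.corrcoef(ra, rb)[0, 1]
        rho, _ = change_correlation(a, b)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_unpaired_raises(self):
        with pytest.raises(ValueError):
            change_correlation([1, 2, 3], [1, 2])


class TestCrpContribution:
    def test_all_zero_crp(self):
        df = pd.DataFrame(
            {"crp_fraction": [0.0, 0.0], "crp_fraction_nonconstant": [0.0, 0.0]}
        )
        mean, sd = crp_contribution(df)
        assert mean == 0.0

    def test_half_share_construction(self):
        df = pd.DataFrame(
            {"crp_fraction": [0.25], "crp_fraction_nonconstant": [0.5]}
        )
        mean, _ = crp_contribution(df, include_constant=False)
        assert mean == pytest.approx(50.0)

    def test_overall_share_below_nonconstant_share(self, training_cohort, coeffs):
        from mbda.scoring import score_cohort

        df = score_cohort(training_cohort, coeffs)
        overall, _ = crp_contribution(df, include_constant=True)
        nonconstant, _ = crp_contribution(df, include_constant=False)
        assert overall < nonconstant


class TestEvaluationReport:
    def test_fields_and_ranges(self, training_cohort, coeffs):
        from mbda.indices import das28_crp4
        from mbda.scoring import score_cohort

        df = score_cohort(training_cohort, coeffs)
        das = np.array(
            [das28_crp4(r.tjc28, r.sjc28, r.crp_mg_l, r.pga * 10) for r in training_cohort]
        )
        rep = evaluation_report(df["pre_scale"].to_numpy(), das)
        assert rep["n"] == len(training_cohort)
        assert 0 <= rep["auroc_fixed"] <= 1
        assert 0 <= rep["auroc_median"] <= 1
        assert rep["threshold_fixed"] == 2.67
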