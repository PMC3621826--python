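from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from mbda.core import Cohort, MarkerConcentration, PatientRecord
from mbda.prioritize import (
    bh_adjust,
    combined_and_grand_ranks,
    competition_rank,
    multivariate_priorities,
    multivariate_score_and_rank,
    rank_table,
    univariate_rank,
    univariate_screen,
)


def bh_stepup_oracle(p_values, q):
    """Brute-force BH: largest k with p_(k) <= k*q/m; reject the k smallest."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


class TestBH:
    def test_spec_example_all_significant(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert (bh_adjust(p) < 0.2).all()
        assert bh_stepup_oracle(p, 0.2).all()

    @pytest.mark.parametrize("q", [0.05, 0.10, 0.20])
    def test_matches_oracle_on_grid(self, q):
        grid = [0.001, 0.01, 0.04, 0.049, 0.2, 0.5, 0.9]
        for m in range(1, 7):
            for p in itertools.combinations_with_replacement(grid, m):
                p = list(p)
                ours = bh_adjust(p) <= q  # adjusted-p rejection at level q
                oracle = bh_stepup_oracle(p, q)
                assert (ours == oracle).all(), (p, q)


class TestCompetitionRank:
    def test_simple(self):
        assert competition_rank({"A": 5, "B": 3, "C": 0}) == {"A": 1, "B": 2, "C": 3}

    def test_tie_1224(self):
        ranks = competition_rank({"A": 5, "B": 5, "C": 1})
        assert ranks["A"] == ranks["B"] == 1
        assert ranks["C"] == 3

    def test_total_tie(self):
        ranks = competition_rank({"A": 0, "B": 0, "C": 0})
        assert set(ranks.values()) == {1}

    def test_permutation_invariance(self):
        scores = {"A": 3.0, "B": 1.0, "C": 2.0, "D": 1.0}
        base = competition_rank(scores)
        for perm in itertools.permutations(scores):
            shuffled = {k: scores[k] for k in perm}
            assert competition_rank(shuffled) == base


def _screen_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        tjc = int(rng.integers(0, 29))
        crp = float(rng.lognormal(1.5, 1.0))
        markers = {
            # strongly related to disease activity (tracks tjc)
            "IL6": MarkerConcentration("IL6", float(np.exp(0.3 * tjc + rng.normal(0, 0.3)))),
            # pure noise
            "EGF": MarkerConcentration("EGF", float(rng.lognormal(2.0, 0.5))),
        }
        records.append(
            PatientRecord(
                patient_id=f"P{i}", markers=markers, tjc28=tjc,
                sjc28=int(rng.integers(0, 29)), pga=float(rng.uniform(0, 10)),
                crp_mg_l=crp, sex="F" if i % 2 else "M",
            )
        )
    return Cohort(records=records)


class TestUnivariateScreen:
    def test_marker_identical_to_endpoint_significant(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(30):
            tjc = int(rng.integers(0, 29))
            records.append(
                PatientRecord(
                    patient_id=f"P{i}",
                    markers={"IL6": MarkerConcentration("IL6", float(tjc))},
                    tjc28=tjc, sjc28=0, pga=0.0, crp_mg_l=0.0,
                )
            )
        res = univariate_screen(Cohort(records=records), ["tjc28"])
        pear = res[(res["corr_type"] == "pearson") & (res["analyte"] == "IL6")]
        assert pear["r"].iloc[0] == pytest.approx(1.0)
        assert pear["fdr_significant"].all()

    def test_independent_marker_near_zero(self):
        cohort = _screen_cohort(n=400, seed=2)
        res = univariate_screen(cohort, ["tjc28"])
        egf = res[(res["analyte"] == "EGF") & (res["corr_type"] == "pearson")]
        assert abs(egf["r"].iloc[0]) < 0.15

    def test_constant_marker_recorded_na(self):
        records = [
            PatientRecord(
                patient_id=f"P{i}",
                markers={"IL6": MarkerConcentration("IL6", 5.0)},
                tjc28=i % 28, sjc28=0, pga=0.0, crp_mg_l=1.0,
            )
            for i in range(20)
        ]
        res = univariate_screen(Cohort(records=records), ["tjc28"])
        assert res["r"].isna().all()
        assert not res["fdr_significant"].any()

    def test_subgroup_cells_present(self):
        res = univariate_screen(_screen_cohort(), ["tjc28"], subgroups=["sex"])
        assert {"all", "sex_F", "sex_M"} <= set(res["subgroup"])


class TestUnivariateRank:
    def test_counts_to_ranks(self):
        res = pd.DataFrame(
            {
                "analyte": ["A"] * 5 + ["B"] * 5 + ["C"] * 5,
                "fdr_significant": [True] * 5 + [True] * 3 + [False] * 2 + [False] * 5,
            }
        )
        table = univariate_rank(res)
        lookup = dict(zip(table["analyte"], table["univariate_rank"]))
        assert lookup == {"A": 1, "B": 2, "C": 3}

    def test_all_zero_counts_share_rank_1(self):
        res = pd.DataFrame(
            {"analyte": ["A", "B"], "fdr_significant": [False, False]}
        )
        table = univariate_rank(res)
        assert set(table["univariate_rank"]) == {1}


class TestMultivariatePriorities:
    def test_dominant_marker_enters_first(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(80):
            x1 = float(rng.lognormal(3, 0.5))
            x2 = float(rng.lognormal(3, 0.5))
            # noiseless y = x1^0.1 driven; x2 contributes weakly
            tjc = int(np.clip(round(10 * x1 ** 0.1 + 0.1 * x2 ** 0.1 - 10), 0, 28))
            records.append(
                PatientRecord(
                    patient_id=f"P{i}",
                    markers={
                        "IL6": MarkerConcentration("IL6", x1),
                        "EGF": MarkerConcentration("EGF", x2),
                    },
                    tjc28=tjc, sjc28=0, pga=0.0, crp_mg_l=0.0,
                )
            )
        prios = multivariate_priorities(
            Cohort(records=records), ["tjc28"], ["lasso"], select_size=False
        )
        first = prios[prios["priority"] == 1]["analyte"].iloc[0]
        assert first == "IL6"

    def test_scores_and_common_lowest_rank(self):
        prios = pd.DataFrame(
            {
                "analyte": ["A", "B", "A", "C", "B"],
                "endpoint": ["e"] * 5,
                "family": ["m1", "m1", "m2", "m2", "m2"],
                "priority": [1, 2, 1, 2, 3],
            }
        )
        table = multivariate_score_and_rank(prios, ["A", "B", "C", "D"])
        lookup = table.set_index("analyte")
        assert lookup.loc["A", "multivariate_score"] == pytest.approx(2.0)
        assert lookup.loc["B", "multivariate_score"] == pytest.approx(1 / 2 + 1 / 3)
        assert lookup.loc["A", "multivariate_rank"] == 1
        # D never entered: common lowest rank = ranked analytes + 1
        assert lookup.loc["D", "multivariate_rank"] == 4
        assert lookup.loc["D", "multivariate_score"] == 0.0

    def test_entered_first_and_third(self):
        prios = pd.DataFrame(
            {
                "analyte": ["A", "A"],
                "endpoint": ["e", "e"],
                "family": ["m1", "m2"],
                "priority": [1, 3],
            }
        )
        table = multivariate_score_and_rank(prios, ["A"])
        assert table["multivariate_score"].iloc[0] == pytest.approx(1 + 1 / 3)


class TestCombinedAndGrand:
    def test_combined_score_arithmetic(self):
        uni = pd.DataFrame({"analyte": ["A"], "pass_count": [3], "univariate_rank": [2]})
        multi = pd.DataFrame(
            {"analyte": ["A"], "multivariate_score": [1.0], "multivariate_rank": [4]}
        )
        table = rank_table(uni, multi)
        assert table["combined_score"].iloc[0] == pytest.approx(0.75)

    def test_grand_score_sums_inverse_combined_ranks(self):
        t = pd.DataFrame({"analyte": ["A"], "combined_rank": [1]})
        tables = {f"s{i}": t for i in range(4)}
        grand = combined_and_grand_ranks(tables)
        assert grand["grand_score"].iloc[0] == pytest.approx(4.0)

    def test_absent_analyte_contributes_zero(self):
        t1 = pd.DataFrame({"analyte": ["A", "B"], "combined_rank": [1, 2]})
        t2 = pd.DataFrame({"analyte": ["A"], "combined_rank": [1]})
        grand = combined_and_grand_ranks({"s1": t1, "s2": t2})
        lookup = grand.set_index("analyte")["grand_score"]
        assert lookup["A"] == pytest.approx(2.0)
        assert lookup["B"] == pytest.approx(0.5)
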