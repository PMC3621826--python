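"""Biomarker prioritization: univariate screening, entry-order priorities, ranks.

Candidate markers are ranked three ways within each study and then across
studies:

* univariate rank — how many (endpoint, subgroup, correlation-type) cells a
  marker passes at FDR < 20% (Benjamini-Hochberg within each cell family);
* multivariate rank — the sum over fitted models of the inverse of the
  marker's order of entry (first entrant gets priority 1);
* combined rank — descending sum of inverse univariate and multivariate
  ranks; across studies, inverse combined ranks sum into a grand rank.

Ties use competition ("1224") ranking throughout, and markers never entered
into any model share the common lowest multivariate rank.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mbda.core import Cohort
from mbda.indices import endpoint_vector
from mbda.train import nested_cv_select, stepwise_fit

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "competition_rank",
    "univariate_screen",
    "univariate_rank",
    "multivariate_priorities",
    "multivariate_score_and_rank",
    "combined_and_grand_ranks",
    "rank_table",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def competition_rank(scores: Mapping[str, float]) -> dict[str, int]:
    """Rank keys by descending score with competition ("1224") tie handling."""
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    ranks: dict[str, int] = {}
    for i, (key, score) in enumerate(items):
        if i > 0 and score == items[i - 1][1]:
            ranks[key] = ranks[items[i - 1][0]]
        else:
            ranks[key] = i + 1
    return ranks


def _subgroup_cells(cohort: Cohort, subgroups: Sequence[str]) -> dict[str, np.ndarray]:
    """Boolean masks for 'all' plus each requested subgroup split."""
    n = len(cohort)
    cells: dict[str, np.ndarray] = {"all": np.ones(n, dtype=bool)}
    recs = cohort.records
    for sg in subgroups:
        if sg == "serostatus":
            rf = np.array([r.rf_status for r in recs], dtype=object)
            for label, val in (("rf_pos", True), ("rf_neg", False)):
                mask = np.array([x is val for x in rf])
                if mask.any():
                    cells[label] = mask
        elif sg == "sex":
            sex = [r.sex for r in recs]
            for label in sorted({s for s in sex if s is not None}):
                cells[f"sex_{label}"] = np.array([s == label for s in sex])
        elif sg == "therapy":
            names = sorted({t for r in recs for t in r.therapy})
            for name in names:
                mask = np.array([r.therapy.get(name, False) for r in recs])
                if mask.any():
                    cells[f"therapy_{name}"] = mask
        else:
            raise ValueError(f"unknown subgroup {sg!r}")
    return cells


def _corr_with_p(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, float]:
    n = len(x)
    method = None
    if n < 10:
        # small-sample cells: permutation p-value (seeded, reproducible)
        method = stats.PermutationMethod(n_resamples=9999, rng=np.random.default_rng(0))
    if kind == "pearson":
        res = stats.pearsonr(x, y, method=method) if method else stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
        if method is not None:

            def _stat(xp):
                return stats.spearmanr(xp, y).statistic

            perm = stats.permutation_test(
                (x,), _stat, permutation_type="pairings",
                n_resamples=9999, rng=np.random.default_rng(0),
            )
            return float(res.statistic), float(perm.pvalue)
    return float(res.statistic), float(res.pvalue)


def univariate_screen(
    cohort: Cohort,
    endpoints: Sequence[str],
    subgroups: Sequence[str] = (),
    fdr_q: float = 0.20,
    analytes: Sequence[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson and Spearman screening of every marker against every endpoint.

    BH adjustment is applied within each endpoint x subgroup x correlation-type
    family (across analytes); a cell is significant iff its adjusted p-value
    is below ``fdr_q``. Degenerate (constant) variables are recorded as NA and
    excluded from the family.
    """
    if analytes is None:
        analytes = cohort.analytes
    markers = cohort.marker_matrix(analytes).reset_index(drop=True)
    cells = _subgroup_cells(cohort, subgroups)

    rows = []
    for endpoint in endpoints:
        y_all = endpoint_vector(cohort, endpoint)
        for cell_name, mask in cells.items():
            for kind in ("pearson", "spearman"):
                family_rows = []
                for analyte in analytes:
                    x = markers[analyte].to_numpy(dtype=float)[mask]
                    y = y_all[mask]
                    ok = np.isfinite(x) & np.isfinite(y)
                    x, y = x[ok], y[ok]
                    if len(x) < min_n or np.std(x) == 0 or np.std(y) == 0:
                        family_rows.append(
                            dict(
                                analyte=analyte, endpoint=endpoint, subgroup=cell_name,
                                corr_type=kind, n=len(x), r=np.nan, p=np.nan,
                            )
                        )
                        continue
                    r, p = _corr_with_p(x, y, kind)
                    family_rows.append(
                        dict(
                            analyte=analyte, endpoint=endpoint, subgroup=cell_name,
                            corr_type=kind, n=len(x), r=r, p=p,
                        )
                    )
                fam = pd.DataFrame(family_rows)
                valid = fam["p"].notna()
                fam["p_adj"] = np.nan
                if valid.any():
                    fam.loc[valid, "p_adj"] = bh_adjust(fam.loc[valid, "p"].to_numpy())
                fam["fdr_significant"] = fam["p_adj"] < fdr_q
                rows.append(fam)
    return pd.concat(rows, ignore_index=True)


def univariate_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte pass counts and competition ranks from screening results."""
    counts = (
        results.groupby("analyte")["fdr_significant"].sum().astype(int).to_dict()
    )
    ranks = competition_rank({a: float(c) for a, c in counts.items()})
    return pd.DataFrame(
        {
            "analyte": list(counts),
            "pass_count": [counts[a] for a in counts],
            "univariate_rank": [ranks[a] for a in counts],
        }
    ).sort_values("univariate_rank", ignore_index=True)


def multivariate_priorities(
    cohort: Cohort,
    endpoints: Sequence[str],
    model_families: Sequence[str] = ("ols", "lasso", "en"),
    analytes: Sequence[str] | None = None,
    max_size: int | None = None,
    select_size: bool = True,
    k: int = 10,
    seed: int = 0,
    exponent: float = 0.1,
) -> pd.DataFrame:
    """Order-of-entry priorities per (analyte, endpoint, model family).

    Each fitted model contributes priorities 1, 2, ... following its stepwise
    entry order, truncated at the nested-CV-selected size when
    ``select_size`` is true. Models that fail to fit are skipped and logged.
    """
    if analytes is None:
        analytes = [a for a in cohort.analytes if a != "CRP"]
    X = cohort.marker_matrix(analytes).pow(exponent).reset_index(drop=True)
    rows = []
    for endpoint in endpoints:
        y = endpoint_vector(cohort, endpoint)
        ok = np.isfinite(y) & X.notna().all(axis=1).to_numpy()
        Xo, yo = X[ok], y[ok]
        for family in model_families:
            try:
                if select_size:
                    size, _ = nested_cv_select(
                        Xo, yo, family, k=min(k, len(yo)), max_size=max_size, seed=seed
                    )
                else:
                    size = None
                path = stepwise_fit(Xo, yo, family, max_size=max_size)
            except Exception as exc:  # noqa: BLE001 - skip non-converging fits
                logger.warning("model %s/%s failed: %s", endpoint, family, exc)
                continue
            order = path.entry_order if size is None else path.entry_order[:size]
            for priority, analyte in enumerate(order, start=1):
                rows.append(
                    dict(
                        analyte=analyte, endpoint=endpoint, family=family,
                        priority=priority,
                    )
                )
    return pd.DataFrame(rows, columns=["analyte", "endpoint", "family", "priority"])


def multivariate_score_and_rank(
    priorities: pd.DataFrame, analytes: Sequence[str]
) -> pd.DataFrame:
    """Inverse-priority scores and competition ranks over a fixed analyte set.

    score = sum of 1/priority over all models that included the analyte.
    Analytes absent from every model share the common lowest rank, one past
    the number of ranked analytes.
    """
    scores: dict[str, float] = {}
    if len(priorities):
        for analyte, grp in priorities.groupby("analyte"):
            scores[str(analyte)] = float((1.0 / grp["priority"]).sum())
    ranked = competition_rank(scores)
    lowest = len(ranked) + 1
    rows = []
    for analyte in analytes:
        if analyte in scores:
            rows.append(
                dict(
                    analyte=analyte,
                    multivariate_score=scores[analyte],
                    multivariate_rank=ranked[analyte],
                )
            )
        else:
            rows.append(
                dict(analyte=analyte, multivariate_score=0.0, multivariate_rank=lowest)
            )
    return pd.DataFrame(rows)


def rank_table(uni: pd.DataFrame, multi: pd.DataFrame) -> pd.DataFrame:
    """Combine univariate and multivariate ranks into one per-study table.

    combined_score = 1/univariate_rank + 1/multivariate_rank, ranked
    descending (competition ranking).
    """
    table = uni.merge(multi, on="analyte", how="outer")
    table["combined_score"] = 1.0 / table["univariate_rank"] + 1.0 / table["multivariate_rank"]
    ranks = competition_rank(dict(zip(table["analyte"], table["combined_score"])))
    table["combined_rank"] = table["analyte"].map(ranks)
    return table.sort_values("combined_rank", ignore_index=True)


def combined_and_grand_ranks(study_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Grand ranks across studies: descending sum of inverse combined ranks.

    An analyte absent from a study contributes 0 to its grand score.
    """
    if not study_tables:
        raise ValueError("need at least one study table")
    analytes: list[str] = []
    for table in study_tables.values():
        for a in table["analyte"]:
            if a not in analytes:
                analytes.append(a)
    grand_scores = {a: 0.0 for a in analytes}
    per_study = {}
    for study, table in study_tables.items():
        lookup = dict(zip(table["analyte"], table["combined_rank"]))
        per_study[study] = lookup
        for a in analytes:
            if a in lookup:
                grand_scores[a] += 1.0 / lookup[a]
    ranks = competition_rank(grand_scores)
    out = pd.DataFrame(
        {
            "analyte": analytes,
            "grand_score": [grand_scores[a] for a in analytes],
            "grand_rank": [ranks[a] for a in analytes],
        }
    )
    for study, lookup in per_study.items():
        out[f"combined_rank_{study}"] = [lookup.get(a, np.nan) for a in analytes]
    return out.sort_values("grand_rank", ignore_index=True)
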