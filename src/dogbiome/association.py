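"""Microbiome-phenotype association scans with multiplicity correction.

Categorical phenotypes are scanned with rank tests (two-sided Mann-Whitney
for two groups, Kruskal-Wallis beyond, both tie-corrected); numeric pairs use
Pearson correlation with the t-transform p-value; demographic cross-tables
use chi-squared or, for sparse 2x2 tables, Fisher's exact test. One scan
(one phenotype against all features) forms one multiple-testing family and is
corrected by Bonferroni (study level 0.15) or Benjamini-Hochberg FDR (study
levels 0.15 and 0.05 depending on the scan) — the correction method is a
required argument since the source analyses used both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_GROUP_MAX = 8  # exact Mann-Whitney enumeration up to this group size


@dataclass
class AssociationRecord:
    feature: str
    phenotype: str
    test: str  # mann_whitney | kruskal_wallis | pearson | chi_squared | fisher_exact
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjusted_p: float | None = None
    correction: str | None = None
    level: float | None = None
    significant: bool | None = None


def records_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _groups(values: pd.Series, grouping: pd.Series) -> list[np.ndarray]:
    df = pd.DataFrame({"y": values, "g": grouping}).dropna()
    out = []
    for _, sub in df.groupby("g", observed=True, sort=True):
        if len(sub) >= 2:
            out.append(sub["y"].to_numpy(dtype=float))
    return out


def rank_test_scan(
    features: pd.DataFrame, metadata: pd.DataFrame, phenotype: str
) -> list[AssociationRecord]:
    """Rank-test every feature against a categorical phenotype.

    Two groups use a two-sided Mann-Whitney U (exact enumeration when both
    groups have at most 8 samples and no ties; normal approximation with tie
    and continuity correction otherwise); more groups use Kruskal-Wallis.
    Groups with fewer than 2 non-missing samples are dropped; features left
    with fewer than two groups are skipped with a logged reason.
    """
    grouping = metadata.loc[features.index, phenotype]
    records = []
    for feat in features.columns:
        groups = _groups(features[feat], grouping)
        if len(groups) < 2:
            logger.warning("%s vs %s skipped: fewer than two usable groups", feat, phenotype)
            continue
        sizes = tuple(len(g) for g in groups)
        if len(groups) == 2:
            a, b = groups
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (len(a) <= EXACT_GROUP_MAX and len(b) <= EXACT_GROUP_MAX
                                 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            records.append(
                AssociationRecord(feat, phenotype, "mann_whitney",
                                  float(res.statistic), float(res.pvalue), sizes)
            )
        else:
            res = stats.kruskal(*groups)
            records.append(
                AssociationRecord(feat, phenotype, "kruskal_wallis",
                                  float(res.statistic), float(res.pvalue), sizes)
            )
    return records


def pearson_scan(
    features: pd.DataFrame, metadata: pd.DataFrame, phenotype: str
) -> list[AssociationRecord]:
    """Pearson-correlate every feature with a numeric phenotype.

    The two-sided p comes from the t transform with n-2 degrees of freedom.
    Features with fewer than 3 paired values or zero variance on either side
    are skipped with a logged reason.
    """
    y_all = metadata.loc[features.index, phenotype]
    records = []
    for feat in features.columns:
        df = pd.DataFrame({"x": features[feat], "y": y_all}).dropna()
        if len(df) < 3:
            logger.warning("%s vs %s skipped: fewer than 3 paired values", feat, phenotype)
            continue
        x, y = df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("%s vs %s skipped: zero variance", feat, phenotype)
            continue
        r, p = stats.pearsonr(x, y)
        records.append(
            AssociationRecord(feat, phenotype, "pearson", float(r), float(p), (len(df),))
        )
    return records


def categorical_test(
    metadata: pd.DataFrame, var_a: str, var_b: str
) -> AssociationRecord:
    """Association between two categorical variables.

    Builds the contingency table on non-missing pairs and uses Fisher's exact
    test (two-sided, point-probability rule) when the table is 2x2 with any
    expected count below 5, and the chi-squared test without continuity
    correction otherwise.
    """
    df = metadata[[var_a, var_b]].dropna()
    table = pd.crosstab(df[var_a], df[var_b])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"{var_a!r} x {var_b!r}: a variable has a single level")
    obs = table.to_numpy()
    expected = stats.contingency.expected_freq(obs)
    if obs.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(obs, alternative="two-sided")
        test, statistic = "fisher_exact", float(odds)
        logger.debug("%s x %s: Fisher branch (sparse 2x2)", var_a, var_b)
    else:
        statistic, p, _, _ = stats.chi2_contingency(obs, correction=False)
        test, statistic = "chi_squared", float(statistic)
        logger.debug("%s x %s: chi-squared branch", var_a, var_b)
    sizes = tuple(int(n) for n in obs.sum(axis=1))
    return AssociationRecord(var_a, var_b, test, statistic, float(p), sizes)


def adjust_pvalues(
    records: list[AssociationRecord], method: str, level: float | None = None
) -> list[AssociationRecord]:
    """Adjust one scan's p-values in place and flag significance.

    ``method`` is "bonferroni" (p_adj = min(1, m p); study level 0.15) or
    "bh_fdr" (Benjamini-Hochberg step-up with monotonicity; study levels 0.15
    or 0.05). The records of one call are treated as one family.
    """
    if not records:
        raise ValueError("empty record list")
    if method not in ("bonferroni", "bh_fdr"):
        raise ValueError(f"unknown correction {method!r}")
    if level is None:
        level = 0.15
    raw = np.array([r.p_value for r in records])
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    _, adjusted, _, _ = multipletests(raw, alpha=level, method=sm_method)
    for rec, p_adj in zip(records, adjusted):
        rec.adjusted_p = float(p_adj)
        rec.correction = method
        rec.level = level
        rec.significant = bool(p_adj <= level)
    return records
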