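"""Clinicopathologic association battery.

Nonparametric throughout (the IEL scores are right-skewed; a Shapiro-Wilk
screen is provided to confirm this on a given cohort): chi-square tests with
odds ratios for 2x2 tables, Mann-Whitney U with the point-biserial
correlation r_pb as effect size for two-group comparisons of a continuous
score, Kruskal-Wallis H with eta-squared for >= 3 groups (with post-hoc
pairwise Mann-Whitney when significant), and Spearman's rho with a
permutation p-value for ordinal/continuous pairs. p-values are unadjusted;
an optional Benjamini-Hochberg column is available on the feature screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ielscore.grading import consensus_features
from ielscore.io_annotations import CohortRecord, HISTOLOGICAL_FEATURES

__all__ = [
    "AssociationResult",
    "two_by_two_or",
    "contingency_test",
    "mann_whitney_rpb",
    "kruskal_eta2",
    "spearman_perm",
    "shapiro_screen",
    "feature_score_screen",
    "point_biserial",
]


@dataclass
class AssociationResult:
    """One association test: statistic, two-sided p, named effect size."""

    test_name: str
    statistic: float
    p: float | None
    effect_name: str
    effect: float | None
    n: tuple[int, ...]
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# -- 2x2 tables ---------------------------------------------------------------


def two_by_two_or(a: int, b: int, c: int, d: int) -> AssociationResult:
    """Odds ratio and Pearson chi-square p for the 2x2 table [[a, b], [c, d]].

    OR = (a*d)/(b*c). The chi-square test is uncorrected (no Yates
    continuity correction). A zero cell triggers the Haldane-Anscombe +0.5
    correction for the OR, flagged in the result. The OR is invariant under
    swapping both rows with both columns and inverts under swapping one
    dimension.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("cell counts must be non-negative integers")
    flags = []
    if np.any(table == 0):
        flags.append("haldane_anscombe_correction")
        a_, b_, c_, d_ = (table + 0.5).ravel()
    else:
        a_, b_, c_, d_ = table.ravel()
    odds_ratio = (a_ * d_) / (b_ * c_)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = np.nan, None
        flags.append("degenerate_margin")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        p = float(p)
    return AssociationResult(
        test_name="chi_square_2x2",
        statistic=float(chi2),
        p=p,
        effect_name="odds_ratio",
        effect=float(odds_ratio),
        n=(int(a + b), int(c + d)),
        flags=flags,
    )


def contingency_test(table: np.ndarray) -> AssociationResult:
    """Omnibus Pearson chi-square on an R x C table, with all pairwise ORs.

    For tables larger than 2x2 the result carries one uncorrected omnibus p
    plus the pairwise 2x2 odds ratios between row levels (columns taken as
    the two outcome states), mirroring a one-p-many-ORs report.
    """
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    extra = {}
    if table.shape[1] == 2 and table.shape[0] > 2:
        for i, j in combinations(range(table.shape[0]), 2):
            a, b = table[i]
            c, d = table[j]
            extra[f"or_{i}_vs_{j}"] = two_by_two_or(int(a), int(b), int(c), int(d)).effect
    return AssociationResult(
        test_name="chi_square_rxc",
        statistic=float(chi2),
        p=float(p),
        effect_name="none",
        effect=None,
        n=tuple(int(s) for s in table.sum(axis=1)),
        extra=extra,
    )


# -- two-group comparisons ----------------------------------------------------


def point_biserial(values: np.ndarray, indicator: np.ndarray) -> float:
    """Pearson correlation between a continuous variable and a 0/1 indicator."""
    values = np.asarray(values, dtype=float)
    indicator = np.asarray(indicator, dtype=float)
    if np.std(values) == 0 or np.std(indicator) == 0:
        raise ValueError("point-biserial undefined for a constant input")
    return float(np.corrcoef(values, indicator)[0, 1])


def mann_whitney_rpb(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Two-sided Mann-Whitney U with point-biserial effect size.

    The p-value uses the tie-corrected normal approximation. The effect size
    r_pb is the Pearson correlation between the pooled values and the group
    indicator (1 for the first group), so a positive r_pb means the first
    group tends to be larger.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    pooled = np.concatenate([x, y])
    indicator = np.concatenate([np.ones(len(x)), np.zeros(len(y))])
    if np.std(pooled) == 0:
        rpb, flags = 0.0, ["constant_pooled_values"]
    else:
        rpb, flags = point_biserial(pooled, indicator), []
    return AssociationResult(
        test_name="mann_whitney_u",
        statistic=float(u),
        p=float(p),
        effect_name="r_pb",
        effect=rpb,
        n=(len(x), len(y)),
        flags=flags,
    )


def kruskal_eta2(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AssociationResult:
    """Tie-corrected Kruskal-Wallis H with eta-squared effect size.

    eta² = (H - k + 1) / (n - k); reported even when negative (clamp only at
    display time). When p < ``alpha``, post-hoc pairwise Mann-Whitney results
    are attached under ``extra["posthoc"]``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use mann_whitney_rpb for two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    h, p = stats.kruskal(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    eta2 = (h - k + 1) / (n - k)
    extra = {}
    if p < alpha:
        extra["posthoc"] = {
            (i, j): mann_whitney_rpb(groups[i], groups[j])
            for i, j in combinations(range(k), 2)
        }
    return AssociationResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p=float(p),
        effect_name="eta_squared",
        effect=float(eta2),
        n=tuple(len(g) for g in groups),
        extra=extra,
    )


# -- correlation & normality --------------------------------------------------


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    exact: bool = False,
) -> AssociationResult:
    """Spearman's rho with a two-sided permutation p-value.

    rho is Pearson on average ranks. The p-value is
    (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm) over ``n_perm`` random
    permutations of y — bit-reproducible for a fixed seed. With
    ``exact=True`` (small n only) all n! permutations are enumerated and
    p = #{|rho_perm| >= |rho_obs|} / n! (the identity permutation makes the
    count >= 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman's rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry_c = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
    rho_obs = float(rx_c @ ry_c)
    if exact:
        from itertools import permutations

        if len(x) > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        perms = np.array(list(permutations(ry_c)))
        rho_perm = perms @ rx_c
        p = float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
        n_perm = len(perms)
    else:
        if seed is None:
            raise ValueError("a seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(ry_c, (n_perm, 1)), axis=1)
        rho_perm = perms @ rx_c
        n_extreme = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
        p = (1 + n_extreme) / (1 + n_perm)
    return AssociationResult(
        test_name="spearman_permutation",
        statistic=rho_obs,
        p=float(p),
        effect_name="spearman_rho",
        effect=rho_obs,
        n=(len(x),),
        extra={"n_perm": n_perm},
    )


def shapiro_screen(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test, used to gate the nonparametric battery."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(values == values[0]):
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(values)
    return float(w), float(p)


# -- feature / score screen ---------------------------------------------------


def feature_score_screen(
    cohort: Sequence[CohortRecord],
    scores: pd.DataFrame,
    score_names: Sequence[str] = ("iel_c", "iel_pc"),
    *,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Associate each consensus histological feature with each IEL score.

    One row per (feature, score): the median (IQR) of the score in slides
    with and without the feature (2-of-3 pathologist consensus), the
    point-biserial correlation and the Mann-Whitney p. A feature present in
    all or none of the slides yields a flagged row with no p-value.
    ``bh_adjust`` appends a Benjamini-Hochberg column (off by default; the
    battery reports unadjusted p-values).
    """
    scores = scores.set_index("slide_id") if "slide_id" in scores.columns else scores
    rows = []
    for feat in HISTOLOGICAL_FEATURES:
        votes = {
            r.slide_id: consensus_features(r.features[feat])
            for r in cohort
            if r.features and feat in r.features
        }
        if not votes:
            continue
        ids = [sid for sid in votes if sid in scores.index]
        for score in score_names:
            vals = scores.loc[ids, score].to_numpy(dtype=float)
            pres = np.array([votes[sid] for sid in ids], dtype=bool)
            x, y = vals[pres], vals[~pres]

            def med_iqr(v: np.ndarray) -> str:
                if len(v) == 0:
                    return ""
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                return f"{med:.2f} ({q1:.2f}-{q3:.2f})"

            if len(x) < 2 or len(y) < 2:
                rows.append(
                    {
                        "feature": feat,
                        "score": score,
                        "present_median_iqr": med_iqr(x),
                        "absent_median_iqr": med_iqr(y),
                        "n_present": len(x),
                        "n_absent": len(y),
                        "r_pb": np.nan,
                        "p": np.nan,
                        "flag": "single_presence_level",
                    }
                )
                continue
            res = mann_whitney_rpb(x, y)
            rows.append(
                {
                    "feature": feat,
                    "score": score,
                    "present_median_iqr": med_iqr(x),
                    "absent_median_iqr": med_iqr(y),
                    "n_present": len(x),
                    "n_absent": len(y),
                    "r_pb": res.effect,
                    "p": res.p,
                    "flag": "",
                }
            )
    table = pd.DataFrame(rows)
    if bh_adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        mask = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
        table["p_bh"] = adj
    return table
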