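"""Region-wise CNA frequency comparisons between sample groups.

Implements the statistical battery for contrasting copy-number event
frequencies between cohorts (pre- vs post-treatment, responder classes):
the continuity-corrected test of equal proportions for unmatched groups,
McNemar's test for matched pairs, a genome-wide two-tailed Fisher exact scan,
Benjamini-Hochberg FDR adjustment, and the power calculus (Bonferroni
threshold, two-proportion sample size with Fleiss continuity correction)
used to judge what effect sizes a cohort can resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .recurrence import EventMatrix


@dataclass
class GroupedEvents:
    """Event carrier counts for one region in two groups.

    ``paired_table`` is (both, a_only, b_only, neither) when the groups are
    matched pairs; required by :func:`mcnemar_test`.
    """

    count_a: int
    n_a: int
    count_b: int
    n_b: int
    region: str | None = None
    paired_table: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.count_a <= self.n_a and 0 <= self.count_b <= self.n_b):
            raise ValueError("carrier counts must lie in [0, group size]")


@dataclass
class RegionTestResult:
    region: str | None
    freq_a: float
    freq_b: float
    p: float
    test_name: str
    p_adj: float | None = None


@dataclass
class SampleSizeSpec:
    """Inputs to the two-proportion sample-size formula (two equal groups)."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80
    continuity_correction: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p1 < 1 and 0 < self.p2 < 1):
            raise ValueError("proportions must lie in (0, 1)")
        if self.p1 == self.p2:
            raise ValueError("p1 and p2 must differ")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def two_proportion_test(ev: GroupedEvents) -> RegionTestResult:
    """Continuity-corrected test of equal proportions (two-sided).

    The pooled-variance chi-square form with Yates correction, equivalent to
    R's ``prop.test``. Degenerate tables with no information (identical
    proportions, or an all-zero/all-one margin) return p = 1.
    """
    if ev.n_a == 0 or ev.n_b == 0:
        raise ValueError("zero-size group")
    fa, fb = ev.count_a / ev.n_a, ev.count_b / ev.n_b
    table = np.array(
        [[ev.count_a, ev.n_a - ev.count_a], [ev.count_b, ev.n_b - ev.count_b]],
        dtype=float,
    )
    if fa == fb or table.sum(axis=0).min() == 0:
        p = 1.0
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        p = float(min(p, 1.0))
    return RegionTestResult(ev.region, fa, fb, p, "two_proportion")


def mcnemar_test(ev: GroupedEvents) -> RegionTestResult:
    """McNemar's test on matched pairs.

    Exact two-sided binomial on the discordant counts when b + c < 25,
    continuity-corrected chi-square otherwise. No discordant pairs carry no
    information: p = 1.
    """
    if ev.paired_table is None:
        raise ValueError("mcnemar_test requires a paired_table")
    both, a_only, b_only, neither = ev.paired_table
    n_pairs = both + a_only + b_only + neither
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    b, c = a_only, b_only
    if b + c == 0:
        p = 1.0
    else:
        table = [[both, b], [c, neither]]
        res = _sm_mcnemar(table, exact=(b + c < 25), correction=True)
        p = float(min(res.pvalue, 1.0))
    fa = (both + a_only) / n_pairs
    fb = (both + b_only) / n_pairs
    return RegionTestResult(ev.region, fa, fb, p, "mcnemar")


def fisher_exact_test(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-tailed Fisher exact p: probability mass of tables no more likely
    than the observed one, margins fixed (hypergeometric summation)."""
    table = [[count_a, n_a - count_a], [count_b, n_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_scan(
    matrix: "EventMatrix",
    group_labels: pd.Series | dict,
    direction: str,
    flag_threshold: float = 0.005,
) -> pd.DataFrame:
    """Region-by-region two-tailed Fisher exact scan between two groups.

    ``group_labels`` maps sample_id to one of exactly two labels. Regions
    with unadjusted p <= ``flag_threshold`` are flagged; BH-adjusted p is
    reported alongside.
    """
    labels = pd.Series(group_labels)
    labels = labels.reindex(matrix.samples)
    if labels.isna().any():
        missing = labels[labels.isna()].index.tolist()
        raise ValueError(f"samples without a group label: {missing[:5]}")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    in_a = (labels == groups[0]).to_numpy()
    in_b = (labels == groups[1]).to_numpy()
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("one group is empty")
    ev = matrix.events(direction)
    count_a = ev[:, in_a].sum(axis=1)
    count_b = ev[:, in_b].sum(axis=1)
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    p = np.array(
        [fisher_exact_test(int(a), n_a, int(b), n_b) for a, b in zip(count_a, count_b)]
    )
    out = matrix.regions.copy()
    out["direction"] = direction
    out[f"count_{groups[0]}"] = count_a
    out[f"count_{groups[1]}"] = count_b
    out[f"freq_{groups[0]}"] = count_a / n_a
    out[f"freq_{groups[1]}"] = count_b / n_b
    out["p"] = p
    out["p_adj"] = bh_adjust(p)
    out["flagged"] = p <= flag_threshold
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance level controlling FWER at alpha_family."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_family / n_tests


def sample_size_two_prop(spec: SampleSizeSpec) -> dict:
    """Required sample size for detecting a difference in two proportions.

    Normal-approximation formula with pooled variance under the null and
    unpooled under the alternative:

        n = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p1 q1 + p2 q2))^2 / d^2

    per group, with the Fleiss continuity correction
    ``n' = n/4 (1 + sqrt(1 + 4/(n d)))^2`` applied when requested (the
    default; the uncorrected value is also returned). Total is across two
    equal groups, each rounded up.
    """
    p1, p2 = spec.p1, spec.p2
    d = abs(p2 - p1)
    pbar = (p1 + p2) / 2.0
    z_a = stats.norm.isf(spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    n_uncorrected = (num / d) ** 2
    n = n_uncorrected
    if spec.continuity_correction:
        n = n / 4.0 * (1.0 + math.sqrt(1.0 + 4.0 / (n * d))) ** 2
    per_group = math.ceil(n)
    return {
        "n_per_group": per_group,
        "total": 2 * per_group,
        "n_per_group_uncorrected": math.ceil(n_uncorrected),
        "total_uncorrected": 2 * math.ceil(n_uncorrected),
    }
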