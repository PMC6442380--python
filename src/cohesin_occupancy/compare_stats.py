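"""Statistical comparisons between conditions and genetic-interaction tests.

Occupancy shifts between a mock control and a depletion condition are
tested per feature class with the paired Wilcoxon signed-rank test (the
same features are scored in both conditions).  Cross viability uses
Fisher's exact test on recovered male/female counts, and bristle counts
use Welch's two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .occupancy import OccupancyTable


@dataclass(frozen=True)
class ConditionComparison:
    class_label: str
    factor: str
    n: int
    median_difference: float      # depleted - mock
    statistic: float              # signed-rank W
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ViabilityResult:
    test_males: int
    test_females: int
    ref_males: int
    ref_females: int
    expected_ratio: float
    percent_recovered: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def signed_rank_p(differences: np.ndarray, exact_max_n: int = 25) -> tuple:
    """Two-sided Wilcoxon signed-rank (statistic, P) on paired differences.

    Zero differences are dropped; with n <= ``exact_max_n`` and no tied
    |d| the exact null distribution is used, otherwise the normal
    approximation with continuity correction.  All-zero differences give
    P = 1.0 by convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def paired_wilcoxon(occ_mock: OccupancyTable, occ_depleted: OccupancyTable,
                    class_label: str, factor: str) -> ConditionComparison:
    """Paired signed-rank test of depleted vs mock occupancy for one class."""
    mock = occ_mock.subset(class_label, factor).set_index("feature")["value"]
    depl = occ_depleted.subset(class_label, factor).set_index("feature")["value"]
    shared = mock.index.intersection(depl.index)
    if len(shared) == 0:
        raise ValueError(
            f"no shared {class_label} features between conditions for {factor}")
    d = (depl.loc[shared] - mock.loc[shared]).to_numpy()
    w, p = signed_rank_p(d)
    return ConditionComparison(class_label, factor, len(shared),
                               float(np.median(d)), w, p)


def compare_all_classes(occ_mock: OccupancyTable, occ_depleted: OccupancyTable,
                        factor: str, classes: list[str],
                        fdr: bool = False) -> list[ConditionComparison]:
    """Per-class comparisons; optional Benjamini-Hochberg adjustment."""
    results = [paired_wilcoxon(occ_mock, occ_depleted, c, factor)
               for c in classes]
    if fdr:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [ConditionComparison(r.class_label, r.factor, r.n,
                                       r.median_difference, r.statistic,
                                       float(p))
                   for r, p in zip(results, adj)]
    return results


def fisher_viability(test_males: int, test_females: int, ref_males: int,
                     ref_females: int,
                     expected_ratio: float = 1.0) -> ViabilityResult:
    """Viability of a test genotype relative to a reference genotype.

    percent recovered = 100 * (test_males/test_females) / expected_ratio,
    where the expected ratio is the male:female ratio of the cross.  The
    two-sided Fisher P sums all tables (fixed margins) whose point
    probability does not exceed the observed table's.
    """
    counts = (test_males, test_females, ref_males, ref_females)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    if test_females <= 0:
        raise ValueError("test_females must be > 0 to compute percent recovered")
    table = np.array([[test_males, test_females], [ref_males, ref_females]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined with an all-zero margin")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    percent = 100.0 * (test_males / test_females) / expected_ratio
    return ViabilityResult(test_males, test_females, ref_males, ref_females,
                           expected_ratio, percent, p)


def two_sample_t(values_a, values_b) -> TTestResult:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(float(np.mean(a)), 0.0, a.size,
                               float(np.mean(b)), 0.0, b.size, 0.0, 1.0)
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(np.mean(a)), sd_a, a.size,
                       float(np.mean(b)), sd_b, b.size, float(t), float(p))
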