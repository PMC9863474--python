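"""Descriptive and inferential statistics for a scored cohort.

Per-procedure summaries report n, mean and sample standard deviation (n − 1
denominator); SD is undefined for singleton groups. Between-group comparisons
follow the conventional screen-then-test recipe: with exactly two groups that
both pass a Shapiro–Wilk normality screen (alpha = 0.05, requires n >= 3 per
group), a Welch (unequal-variance) two-sided t-test is used; otherwise the
Kruskal–Wallis rank-sum test. Nominal associations use Fisher's exact test
for 2x2 tables with any expected cell below 5, Pearson's chi-square
otherwise. No multiple-testing correction is applied.

All tests are delegated to scipy.stats; this module owns the selection rules
and the cohort-shaped interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .scoring import BinaryLabel, ScoredPatient, SurgicalProcedure, to_binary

__all__ = [
    "GroupSummary",
    "CohortSummary",
    "TestResult",
    "AssociationResult",
    "summarize",
    "compare_groups",
    "group_vs_rest",
    "association_test",
    "NORMALITY_ALPHA",
]

#: Shapiro–Wilk screening level for the auto t-test / Kruskal–Wallis choice.
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean_ratio: float
    sd_ratio: float | None  # None when n == 1


@dataclass(frozen=True)
class CohortSummary:
    """Per-procedure ratio summaries, ordered single patch, double patch, Warden."""

    groups: tuple[GroupSummary, ...]

    def group(self, label) -> GroupSummary:
        label = getattr(label, "value", label)
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def as_dict(self) -> dict:
        return {
            g.label: {"n": g.n, "mean_ratio": g.mean_ratio, "sd_ratio": g.sd_ratio}
            for g in self.groups
        }


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | None = None

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
        }


@dataclass(frozen=True)
class AssociationResult:
    test: str
    p_value: float
    statistic: float | None = None
    odds_ratio: float | None = None

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "p_value": self.p_value,
            "statistic": self.statistic,
            "odds_ratio": self.odds_ratio,
        }


def _grouped_ratios(
    scored: Iterable[ScoredPatient], binary: bool
) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for p in scored:
        if p.actual_procedure is None:
            raise ValueError(f"patient {p.patient_id!r} has no actual procedure label")
        key = (to_binary(p.actual_procedure) if binary else p.actual_procedure).value
        groups.setdefault(key, []).append(p.ratio)
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def summarize(scored: Sequence[ScoredPatient]) -> CohortSummary:
    """Per-procedure n / mean / sample SD of the PAPVR ratio."""
    if len(scored) == 0:
        raise ValueError("empty cohort")
    groups = _grouped_ratios(scored, binary=False)
    ordered = [p.value for p in SurgicalProcedure if p.value in groups]
    out = []
    for label in ordered:
        # sorted accumulation: output is bit-identical under cohort permutation
        vals = np.sort(groups[label])
        out.append(
            GroupSummary(
                label=label,
                n=len(vals),
                mean_ratio=float(vals.mean()),
                sd_ratio=float(vals.std(ddof=1)) if len(vals) >= 2 else None,
            )
        )
    return CohortSummary(groups=tuple(out))


def _all_normal(samples: Sequence[np.ndarray]) -> bool:
    for s in samples:
        if len(s) < 3:
            return False  # screen not applicable; fall back to rank test
        if np.ptp(s) == 0:
            return False  # constant sample: Shapiro undefined
        if stats.shapiro(s).pvalue < NORMALITY_ALPHA:
            return False
    return True


def _compare_samples(samples: Sequence[np.ndarray], mode: str) -> TestResult:
    if len(samples) < 2:
        raise ValueError("need at least two groups to compare")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group must have at least two members")
    if mode == "auto":
        mode = "t_test" if (len(samples) == 2 and _all_normal(samples)) else "kruskal_wallis"
    if mode == "t_test":
        if len(samples) != 2:
            raise ValueError("t-test requires exactly two groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        return TestResult(
            test="welch_t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=float(res.df),
        )
    if mode == "kruskal_wallis":
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:
            # all observations identical in every group: no evidence of any
            # difference; scipy rejects this input, so report the null directly
            return TestResult(
                test="kruskal_wallis",
                statistic=0.0,
                p_value=1.0,
                df=float(len(samples) - 1),
            )
        stat, p = stats.kruskal(*samples)
        return TestResult(
            test="kruskal_wallis",
            statistic=float(stat),
            p_value=float(p),
            df=float(len(samples) - 1),
        )
    raise ValueError(f"unknown mode {mode!r}; expected auto, t_test or kruskal_wallis")


def compare_groups(
    scored: Sequence[ScoredPatient], mode: str = "auto", binary: bool = False
) -> TestResult:
    """Compare ratio distributions between procedure groups.

    ``binary=True`` pools single and double patch into one PATCH group
    (the Warden-vs-patch comparison behind the cutoff). Mode ``auto``
    selects Welch's t-test for two normal-screened groups and the
    Kruskal–Wallis rank-sum test otherwise.
    """
    groups = _grouped_ratios(scored, binary=binary)
    labels = sorted(groups)
    return _compare_samples([groups[k] for k in labels], mode)


def group_vs_rest(
    scored: Sequence[ScoredPatient], mode: str = "auto"
) -> dict[str, TestResult]:
    """Each procedure group's ratios against the pooled rest of the cohort.

    The published per-group p-values do not state which comparison they refer
    to, so this is reported alongside the omnibus test, explicitly labelled.
    """
    groups = _grouped_ratios(scored, binary=False)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out: dict[str, TestResult] = {}
    for label, vals in groups.items():
        rest = np.concatenate([v for k, v in groups.items() if k != label])
        out[label] = _compare_samples([vals, rest], mode)
    return out


def association_test(table) -> AssociationResult:
    """Test association in an r×c contingency table of non-negative counts.

    2×2 tables with any expected cell below 5 use Fisher's exact test
    (two-sided) and report the sample odds ratio; all other tables use
    Pearson's chi-square.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2×2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table entries must be non-negative integers")
    counts = np.round(arr).astype(int)

    odds_ratio = None
    if counts.shape == (2, 2):
        a, b = counts[0]
        c, d = counts[1]
        if b * c > 0:
            odds_ratio = float(a * d) / float(b * c)
        elif a * d > 0:
            odds_ratio = float("inf")
        else:
            odds_ratio = float("nan")

    expected = stats.contingency.expected_freq(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        res = stats.fisher_exact(counts, alternative="two-sided")
        return AssociationResult(
            test="fisher_exact", p_value=float(res.pvalue), odds_ratio=odds_ratio
        )
    chi2 = stats.chi2_contingency(counts, correction=False)
    return AssociationResult(
        test="pearson_chi2",
        p_value=float(chi2.pvalue),
        statistic=float(chi2.statistic),
        odds_ratio=odds_ratio,
    )
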