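"""Group statistics and end-to-end orchestration.

The statistical layer mirrors the study design: a between-subject
one-way ANOVA across muscles for MUAP durations and MDFs, a
between-subject two-way ANOVA (muscle x contraction intensity) for
interference-signal MDFs, paired t-tests between the first and second
15 s halves per muscle and intensity (the fatigue check), Kruskal-Wallis
as a non-parametric confirmation, Shapiro-Wilk normality checks, and
Bonferroni correction of post hoc pairwise contrasts. Significance is
fixed at alpha = 0.05, two-sided.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core_io import AnalysisConfig, CohortTable, EmgSignal
from .preprocess import preprocess_interference
from .spectral import fatigue_half_split, mdf_of_interference

logger = logging.getLogger("myospect")


class DesignError(ValueError):
    """The data layout does not match the test's required design."""


class DegenerateDataError(ValueError):
    """The data admit no defined test statistic (e.g. zero variance)."""


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: tuple[int, ...]
    p_value: float
    effect_label: str = ""
    test_name: str = ""
    adjusted_p: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < alpha


def one_way_anova(groups: Sequence[Sequence[float]], effect_label: str = "group") -> TestResult:
    """Classical between-subject one-way ANOVA, F on (k-1, N-k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DesignError("one-way ANOVA needs at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise DesignError(f"group {i} has fewer than two observations")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return TestResult(0.0, (df_between, df_within), 1.0, effect_label, "one-way ANOVA")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise DegenerateDataError("zero within-group variance with group differences")
    f_stat = ms_between / ms_within
    p = float(sstats.f.sf(f_stat, df_between, df_within))
    return TestResult(float(f_stat), (df_between, df_within), p, effect_label, "one-way ANOVA")


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    labels: tuple[str, str] = ("A", "B"),
) -> list[TestResult]:
    """Balanced fully-crossed between-subject two-way ANOVA.

    Returns main effects and the interaction. With a balanced design the
    type I/II/III sums of squares coincide; an unbalanced layout is
    rejected with a :class:`DesignError` naming the offending cell.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(values) == len(fa) == len(fb)):
        raise DesignError("values and factor labels must have equal length")
    levels_a = sorted(set(fa.tolist()))
    levels_b = sorted(set(fb.tolist()))
    a, b = len(levels_a), len(levels_b)
    counts = {}
    for la in levels_a:
        for lb in levels_b:
            counts[(la, lb)] = int(np.sum((fa == la) & (fb == lb)))
    n_per_cell = counts[(levels_a[0], levels_b[0])]
    for cell, count in counts.items():
        if count != n_per_cell:
            raise DesignError(
                f"unbalanced design: cell {cell} has {count} observations, "
                f"expected {n_per_cell}"
            )
    if n_per_cell < 2:
        raise DesignError("need at least two observations per cell")
    grand = values.mean()
    mean_a = {la: values[fa == la].mean() for la in levels_a}
    mean_b = {lb: values[fb == lb].mean() for lb in levels_b}
    mean_cell = {
        (la, lb): values[(fa == la) & (fb == lb)].mean()
        for la in levels_a
        for lb in levels_b
    }
    n = n_per_cell
    ss_a = n * b * sum((mean_a[la] - grand) ** 2 for la in levels_a)
    ss_b = n * a * sum((mean_b[lb] - grand) ** 2 for lb in levels_b)
    ss_ab = n * sum(
        (mean_cell[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
        for la in levels_a
        for lb in levels_b
    )
    ss_err = sum(
        ((values[(fa == la) & (fb == lb)] - mean_cell[(la, lb)]) ** 2).sum()
        for la in levels_a
        for lb in levels_b
    )
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err

    def result(ss: float, df: int, label: str) -> TestResult:
        if ms_err == 0:
            f_stat = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            f_stat = (ss / df) / ms_err
            p = float(sstats.f.sf(f_stat, df, df_err))
        return TestResult(float(f_stat), (df, df_err), p, label, "two-way ANOVA")

    return [
        result(ss_a, df_a, labels[0]),
        result(ss_b, df_b, labels[1]),
        result(ss_ab, df_ab, f"{labels[0]} x {labels[1]}"),
    ]


def paired_t_test(
    first: Sequence[float], second: Sequence[float], effect_label: str = "paired"
) -> TestResult:
    """Two-sided paired t-test on the element-wise differences."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if len(first) != len(second):
        raise DesignError("paired samples must have equal length")
    if len(first) < 2:
        raise DesignError("paired t-test needs at least two pairs")
    diff = first - second
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences; t statistic undefined")
    n = len(diff)
    t_stat = diff.mean() / (sd / np.sqrt(n))
    p = float(2 * sstats.t.sf(abs(t_stat), n - 1))
    return TestResult(float(t_stat), (n - 1,), p, effect_label, "paired t")


def kruskal_wallis(
    groups: Sequence[Sequence[float]], effect_label: str = "group"
) -> TestResult:
    """Rank-based H test with tie correction, chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DesignError("Kruskal-Wallis needs at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations identical; H undefined")
    h_stat, p = sstats.kruskal(*groups)
    return TestResult(float(h_stat), (len(groups) - 1,), float(p), effect_label, "Kruskal-Wallis")


def shapiro_wilk(sample: Sequence[float], effect_label: str = "normality") -> TestResult:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    sample = np.asarray(sample, dtype=float)
    if not 3 <= len(sample) <= 5000:
        raise DesignError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(sample == sample[0]):
        raise DegenerateDataError("constant sample; W undefined")
    w_stat, p = sstats.shapiro(sample)
    return TestResult(float(w_stat), (len(sample),), float(p), effect_label, "Shapiro-Wilk")


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Multiply each p by the family size, capping at 1."""
    p_values = list(p_values)
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisReport:
    """Machine-readable outcome of the full pipeline."""

    cohort: CohortTable
    tests: list[TestResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": [t.test_name for t in self.tests],
                "effect": [t.effect_label for t in self.tests],
                "statistic": [t.statistic for t in self.tests],
                "df": [str(t.df) for t in self.tests],
                "p_value": [t.p_value for t in self.tests],
                "adjusted_p": [t.adjusted_p for t in self.tests],
            }
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "tests": self.to_frame().to_dict(orient="records"),
            "warnings": self.warnings,
            "n_rows": len(self.cohort),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def get(self, test_name: str, effect_label: str) -> TestResult:
        for t in self.tests:
            if t.test_name == test_name and t.effect_label == effect_label:
                return t
        raise KeyError(f"no result for ({test_name!r}, {effect_label!r})")


def build_cohort_table(
    signals: Sequence[EmgSignal], config: AnalysisConfig | None = None
) -> CohortTable:
    """Preprocess every interference signal and tabulate its MDF measures."""
    config = config or AnalysisConfig()
    rows = []
    for signal in signals:
        conditioned = preprocess_interference(signal, config)
        mdf_full = mdf_of_interference(conditioned, config)
        mdf_first, mdf_second = fatigue_half_split(conditioned, config)
        rows.append(
            {
                "subject": signal.subject,
                "muscle": signal.muscle,
                "intensity": signal.intensity,
                "mdf_full": mdf_full,
                "mdf_first_half": mdf_first,
                "mdf_second_half": mdf_second,
            }
        )
    return CohortTable(pd.DataFrame(rows))


def run_full_analysis(
    signals: Sequence[EmgSignal] | CohortTable,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Full interference-signal analysis: preprocessing, MDFs, statistics.

    Two-way ANOVA (muscle x intensity) on the full-segment MDFs; when the
    interaction is significant, follow-up one-way ANOVAs are run within
    each factor level. Post hoc pairwise muscle contrasts are
    Bonferroni-corrected. Paired t-tests compare the half-split MDFs per
    (muscle, intensity); Kruskal-Wallis across muscles and Shapiro-Wilk
    per muscle are reported alongside. Missing design cells degrade to
    the tests that remain estimable, with warnings.
    """
    config = config or AnalysisConfig()
    config.log_effective()
    cohort = signals if isinstance(signals, CohortTable) else build_cohort_table(signals, config)
    data = cohort.data
    report = AnalysisReport(cohort=cohort)
    muscles = sorted(data["muscle"].unique())
    intensities = sorted(data["intensity"].unique())

    # --- between-muscle / between-intensity ANOVA on full-segment MDF
    if len(muscles) >= 2 and len(intensities) >= 2:
        try:
            results = two_way_anova(
                data["mdf_full"],
                data["muscle"],
                data["intensity"],
                labels=("muscle", "intensity"),
            )
            report.tests.extend(results)
            interaction = results[2]
            if interaction.significant(config.alpha):
                for intensity in intensities:
                    sub = data[data["intensity"] == intensity]
                    groups = [sub[sub["muscle"] == m]["mdf_full"].to_numpy() for m in muscles]
                    report.tests.append(
                        one_way_anova(groups, effect_label=f"muscle | {intensity}")
                    )
                for muscle in muscles:
                    sub = data[data["muscle"] == muscle]
                    groups = [
                        sub[sub["intensity"] == i]["mdf_full"].to_numpy() for i in intensities
                    ]
                    report.tests.append(
                        one_way_anova(groups, effect_label=f"intensity | {muscle}")
                    )
        except DesignError as exc:
            report.warnings.append(f"two-way ANOVA skipped: {exc}")
            logger.warning("two-way ANOVA skipped: %s", exc)
    elif len(muscles) >= 2:
        groups = [data[data["muscle"] == m]["mdf_full"].to_numpy() for m in muscles]
        report.tests.append(one_way_anova(groups, effect_label="muscle"))
    else:
        report.warnings.append("single muscle: between-muscle ANOVA skipped")
        logger.warning("single muscle: between-muscle ANOVA skipped")

    # --- post hoc pairwise muscle contrasts, Bonferroni-corrected
    if len(muscles) >= 2:
        pair_results = []
        for i in range(len(muscles)):
            for j in range(i + 1, len(muscles)):
                gi = data[data["muscle"] == muscles[i]]["mdf_full"].to_numpy()
                gj = data[data["muscle"] == muscles[j]]["mdf_full"].to_numpy()
                t_stat, p = sstats.ttest_ind(gi, gj)
                pair_results.append(
                    TestResult(
                        float(t_stat),
                        (len(gi) + len(gj) - 2,),
                        float(p),
                        f"{muscles[i]} vs {muscles[j]}",
                        "post hoc t",
                    )
                )
        adjusted = bonferroni_adjust([r.p_value for r in pair_results])
        for r, adj in zip(pair_results, adjusted):
            r.adjusted_p = adj
        report.tests.extend(pair_results)

        # non-parametric confirmation across muscles
        try:
            report.tests.append(
                kruskal_wallis(
                    [data[data["muscle"] == m]["mdf_full"].to_numpy() for m in muscles],
                    effect_label="muscle",
                )
            )
        except DegenerateDataError as exc:
            report.warnings.append(f"Kruskal-Wallis skipped: {exc}")

    # --- normality per muscle
    for muscle in muscles:
        sample = data[data["muscle"] == muscle]["mdf_full"].to_numpy()
        if 3 <= len(sample) <= 5000 and not np.all(sample == sample[0]):
            report.tests.append(shapiro_wilk(sample, effect_label=f"mdf | {muscle}"))

    # --- fatigue: paired half-split t-test per (muscle, intensity)
    for muscle in muscles:
        for intensity in intensities:
            sub = data[(data["muscle"] == muscle) & (data["intensity"] == intensity)]
            if len(sub) < 2:
                report.warnings.append(
                    f"fatigue test skipped for ({muscle}, {intensity}): n={len(sub)}"
                )
                continue
            try:
                report.tests.append(
                    paired_t_test(
                        sub["mdf_first_half"],
                        sub["mdf_second_half"],
                        effect_label=f"fatigue | {muscle} {intensity}",
                    )
                )
            except DegenerateDataError as exc:
                report.warnings.append(
                    f"fatigue test degenerate for ({muscle}, {intensity}): {exc}"
                )
    return report
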