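"""Modality-agreement statistics for pneumoconiosis staging.

Two imaging modalities (e.g. high-kV digital radiography and CT) each assign
every case a stage from the ordered set {I, II, III, ND}, where ND marks an
undetermined call.  This module computes their cross-tabulation, raw percent
agreement, Cohen's kappa with conventional interpretation bands
(kappa <= 0.4 poor, <= 0.6 general, <= 0.8 high, > 0.8 good), per-stage
detection rates against an expert gold standard, an exact McNemar test for
paired detection-rate comparison, and a Pearson chi-square test for 2x2
count tables.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGE_SET",
    "cross_table",
    "AgreementResult",
    "cohen_kappa",
    "kappa_band",
    "percent_agreement",
    "detection_rate",
    "discordant_counts",
    "paired_exact_test",
    "chi_square_test",
    "agreement_report",
]

#: Ordered staging categories; "ND" is an undetermined/no-call category.
STAGE_SET = ("I", "II", "III", "ND")


def cross_table(staging: pd.DataFrame, col_a: str = "stage_a",
                col_b: str = "stage_b",
                stages: Sequence[str] = STAGE_SET) -> pd.DataFrame:
    """Square (stage_a x stage_b) contingency table, zero-filled.

    Raises
    ------
    ValueError
        On an empty table or a stage value outside ``stages``.
    """
    if len(staging) == 0:
        raise ValueError("staging table is empty")
    for col in (col_a, col_b):
        bad = set(staging[col]) - set(stages)
        if bad:
            raise ValueError(f"unknown stage value(s) {sorted(bad)} in {col!r}")
    a = pd.Categorical(staging[col_a], categories=list(stages))
    b = pd.Categorical(staging[col_b], categories=list(stages))
    return pd.crosstab(a, b, dropna=False).reindex(
        index=list(stages), columns=list(stages), fill_value=0)


@dataclasses.dataclass(frozen=True)
class AgreementResult:
    """Observed/expected agreement, kappa and its interpretation band."""

    p_observed: float
    p_expected: float
    kappa: float
    band: str
    n: int


def kappa_band(kappa: float) -> str:
    """Interpretation band; boundary values fall in the lower band."""
    if kappa <= 0.4:
        return "poor"
    if kappa <= 0.6:
        return "general"
    if kappa <= 0.8:
        return "high"
    return "good"


def cohen_kappa(table: pd.DataFrame | np.ndarray) -> AgreementResult:
    """Cohen's kappa of a square contingency table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/n and
    p_e = sum_i (row_i * col_i) / n^2.

    Raises
    ------
    ValueError
        On an empty table or degenerate margins with p_e = 1 (all mass in
        one row-and-column cell), where kappa is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("expected a square contingency table")
    n = t.sum()
    if n <= 0:
        raise ValueError("contingency table is empty")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate margins)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_observed=float(p_o), p_expected=p_e,
                           kappa=float(kappa), band=kappa_band(float(kappa)),
                           n=int(round(n)))


def percent_agreement(table: pd.DataFrame | np.ndarray) -> float:
    """Raw concordance: trace / grand total."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        raise ValueError("contingency table is empty")
    return float(np.trace(t) / n)


def detection_rate(staging: pd.DataFrame, modality_col: str, stage: str,
                   gold_col: str = "gold") -> float:
    """Fraction of gold-``stage`` cases the modality stages correctly.

    Undetermined (ND) and misstaged calls both count as incorrect.

    Raises
    ------
    ValueError
        If the gold standard contains no case of the requested stage.
    """
    gold_cases = staging[staging[gold_col] == stage]
    if len(gold_cases) == 0:
        raise ValueError(f"no gold-standard cases of stage {stage!r}")
    return float((gold_cases[modality_col] == stage).mean())


def discordant_counts(staging: pd.DataFrame, col_a: str = "stage_a",
                      col_b: str = "stage_b", gold_col: str = "gold",
                      stage: str | None = None) -> tuple[int, int]:
    """(b, c): cases only modality A staged correctly / only modality B.

    Optionally restricted to cases of one gold stage.
    """
    df = staging if stage is None else staging[staging[gold_col] == stage]
    a_ok = df[col_a] == df[gold_col]
    b_ok = df[col_b] == df[gold_col]
    return int((a_ok & ~b_ok).sum()), int((~a_ok & b_ok).sum())


def paired_exact_test(b: int, c: int) -> float:
    """Exact McNemar test on discordant-pair counts.

    Two-sided exact binomial test of ``b`` successes in ``b + c`` trials at
    rate 1/2; p = 1 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    if b + c == 0:
        return 1.0
    return float(stats.binomtest(b, b + c, 0.5).pvalue)


def chi_square_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 count table.

    Returns ``(statistic, p)`` with df = 1.

    Raises
    ------
    ValueError
        If any row or column marginal is zero (expected counts undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square expected counts undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def agreement_report(staging: pd.DataFrame, nd_mode: str = "category") -> dict:
    """Full agreement summary of a staging table.

    ``nd_mode="category"`` keeps undetermined (ND) calls as a fourth staging
    category; ``"exclude"`` drops cases where either modality made no call.
    Per-stage detection rates and the paired exact test are included when a
    ``gold`` column is present.
    """
    if nd_mode not in ("category", "exclude"):
        raise ValueError("nd_mode must be 'category' or 'exclude'")
    df = staging
    if nd_mode == "exclude":
        df = df[(df["stage_a"] != "ND") & (df["stage_b"] != "ND")]
    table = cross_table(df)
    agg = cohen_kappa(table)
    report = {
        "n": agg.n,
        "nd_mode": nd_mode,
        "cross_table": table.to_numpy().tolist(),
        "stages": list(STAGE_SET),
        "percent_agreement": percent_agreement(table),
        "kappa": agg.kappa,
        "kappa_band": agg.band,
        "p_observed": agg.p_observed,
        "p_expected": agg.p_expected,
    }
    if "gold" in staging.columns:
        rates = {}
        for stage in ("I", "II", "III"):
            if (staging["gold"] == stage).any():
                rates[stage] = {
                    "stage_a": detection_rate(staging, "stage_a", stage),
                    "stage_b": detection_rate(staging, "stage_b", stage),
                    "paired_exact_p": paired_exact_test(
                        *discordant_counts(staging, stage=stage)),
                }
        b, c = discordant_counts(staging)
        report["detection_rates"] = rates
        report["overall_discordant"] = [b, c]
        report["overall_paired_exact_p"] = paired_exact_test(b, c)
    return report
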