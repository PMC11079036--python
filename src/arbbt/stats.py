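"""Validation statistics for a paired-score dexterity study.

Covers the statistical surface of a clinical validation of a virtual
dexterity test against its physical counterpart on the same patients:

* a priori power analysis for a correlation (Fisher-z approximation,
  with an analytic power function and a Monte-Carlo cross-check);
* Pearson correlation with t-based significance and Cohen effect-size
  classification;
* a paired decrease test (paired t by default, Wilcoxon selectable);
* cohort eligibility filtering with a documented exclusion-reason
  precedence;
* 4-level Likert questionnaire summaries with collapsed agree/disagree
  percentages;
* a seeded bivariate-normal generator of synthetic paired scores for
  parameter-recovery testing (the study's patient data are not public).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

LIKERT_LEVELS = ("strongly disagree", "disagree", "agree", "strongly agree")

QUESTIONNAIRE_ITEMS = (
    "I was excited",
    "I learned something new",
    "I was frustrated",
    "I was bored",
    "I felt successful",
    "I had fun",
    "I was angry",
    "I was motivated",
    "I was challenged by the absence of physical items",
    "I was fascinated",
    "I think this tool can support Rehabilitation",
)

# Reference moments of the validation study the synthetic generator
# emulates: paired BBT / AR-BBT block counts on the hemiplegic side.
STUDY_N = 31
STUDY_BBT_MEAN, STUDY_BBT_SD = 36.64, 6.14
STUDY_ARBBT_MEAN, STUDY_ARBBT_SD = 11.90, 2.11
STUDY_RHO = 0.918


def _round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matches clinical-report conventions;
    Python's round() is banker's rounding)."""
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


# ---------------------------------------------------------------------------
# Power analysis for a correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """A priori power-analysis inputs for detecting a correlation."""

    rho_H1: float
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2

    def __post_init__(self) -> None:
        if not -1.0 < self.rho_H1 < 1.0:
            raise ValueError("rho_H1 must lie in (-1, 1)")
        if self.rho_H1 == 0.0:
            raise ValueError("rho_H1 = 0 admits no finite sample size")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def sample_size_for_correlation(spec: PowerSpec) -> int:
    """Required n to detect rho_H1 at the given alpha and power.

    Fisher-z approximation: n = ((z_{1-alpha/tails} + z_{power}) /
    atanh(rho))^2 + 3, rounded to the nearest integer. Nearest-integer
    rounding (rather than always rounding up) reproduces the exact
    bivariate-normal routine of standard power software at conventional
    design points — e.g. 29 for (rho=0.5, alpha=0.05, power=0.80,
    two-tailed) — because the Fisher approximation slightly understates
    power near the boundary. :func:`monte_carlo_power` provides the
    simulation cross-check.
    """
    z_alpha = sps.norm.ppf(1.0 - spec.alpha / spec.tails)
    z_power = sps.norm.ppf(spec.power)
    n = ((z_alpha + z_power) / math.atanh(abs(spec.rho_H1))) ** 2 + 3.0
    return int(math.floor(n + 0.5))


def correlation_power(
    n: int, rho: float, alpha: float = 0.05, tails: int = 2
) -> float:
    """Analytic (Fisher-z) power of the correlation test at sample size n."""
    if n <= 3:
        raise ValueError("n must exceed 3")
    z_alpha = sps.norm.ppf(1.0 - alpha / tails)
    ncp = math.atanh(abs(rho)) * math.sqrt(n - 3)
    return float(sps.norm.cdf(ncp - z_alpha))


def monte_carlo_power(
    n: int,
    rho: float,
    alpha: float = 0.05,
    tails: int = 2,
    n_sims: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Simulated rejection rate of H0: rho = 0 under bivariate-normal
    data with the given rho, using the t-test on the sample correlation.
    Vectorized over simulations."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n))
    e = rng.standard_normal((n_sims, n))
    y = rho * x + math.sqrt(1.0 - rho * rho) * e
    r = _rowwise_pearson(x, y)
    t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    if tails == 2:
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    else:
        p = sps.t.sf(t, df=n - 2)
    return float(np.mean(p < alpha))


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    return num / den


# ---------------------------------------------------------------------------
# Correlation, effect size, paired comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    df: int
    p_two_tailed: float
    cohen_class: str


def cohen_class(r: float) -> str:
    """Cohen's effect-size class for a correlation: |r| >= 0.5 large,
    >= 0.3 medium, >= 0.1 small, below that negligible."""
    a = abs(r)
    if a > 1.0:
        raise ValueError("|r| must not exceed 1")
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "negligible"


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Product-moment correlation with t-based two-tailed p and Cohen class."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(xa) == 0.0:
        raise ValueError("zero variance in x")
    if np.var(ya) == 0.0:
        raise ValueError("zero variance in y")
    res = sps.pearsonr(xa, ya)
    r = float(res.statistic)
    df = n - 2
    denom = max(1.0 - r * r, 0.0)
    t = math.inf if denom == 0.0 else r * math.sqrt(df) / math.sqrt(denom)
    return CorrelationResult(
        r=r,
        n=n,
        t_statistic=t,
        df=df,
        p_two_tailed=float(res.pvalue),
        cohen_class=cohen_class(r),
    )


def r_confidence_interval(
    r: Union[float, np.ndarray], n: int, confidence: float = 0.95
) -> Tuple[np.ndarray, np.ndarray]:
    """Fisher-z confidence interval for a correlation (vectorized over r)."""
    if n <= 3:
        raise ValueError("n must exceed 3")
    r = np.asarray(r, dtype=float)
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + confidence / 2.0) / math.sqrt(n - 3)
    return np.tanh(z - half), np.tanh(z + half)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    direction: str  # "decrease", "increase", or "none" (of x relative to y)
    mean_difference: float
    method: str
    degenerate: bool = False


def paired_decrease_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
) -> PairedTestResult:
    """Paired comparison of x against y (differences x - y).

    ``method="t"`` runs a paired t-test; ``method="wilcoxon"`` the
    signed-rank alternative. ``direction`` reports the sign of the mean
    difference ("decrease" means x below y). All-zero differences yield
    p = 1 with the degenerate flag set.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = xa - ya
    mean_diff = float(diff.mean())
    if np.all(diff == 0.0):
        return PairedTestResult(
            statistic=0.0,
            p_value=1.0,
            direction="none",
            mean_difference=0.0,
            method=method,
            degenerate=True,
        )
    if method == "t":
        res = sps.ttest_rel(xa, ya)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "wilcoxon":
        res = sps.wilcoxon(xa, ya)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("method must be 't' or 'wilcoxon'")
    direction = "decrease" if mean_diff < 0 else "increase" if mean_diff > 0 else "none"
    return PairedTestResult(
        statistic=stat,
        p_value=p,
        direction=direction,
        mean_difference=mean_diff,
        method=method,
    )


# ---------------------------------------------------------------------------
# Cohort eligibility filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyRecord:
    """One screened patient: paired scores, demographics, spasticity,
    comorbidity labels, and optional 11-item questionnaire responses."""

    patient_id: str
    bbt_score: Optional[int] = None
    arbbt_score: Optional[int] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    months_since_diagnosis: Optional[float] = None
    ashworth: Optional[int] = None
    etiology: str = "hemorrhagic stroke"
    comorbidities: Tuple[str, ...] = ()
    questionnaire: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.ashworth is not None and not 0 <= self.ashworth <= 4:
            raise ValueError("ashworth must lie in the 0-4 scale range")
        if self.months_since_diagnosis is not None and self.months_since_diagnosis < 0:
            raise ValueError("months_since_diagnosis must be >= 0")
        if self.questionnaire is not None:
            if len(self.questionnaire) != len(QUESTIONNAIRE_ITEMS):
                raise ValueError(
                    f"questionnaire must have {len(QUESTIONNAIRE_ITEMS)} responses"
                )
            for resp in self.questionnaire:
                if resp not in LIKERT_LEVELS:
                    raise ValueError(f"unknown Likert level: {resp!r}")


@dataclass(frozen=True)
class EligibilityCriteria:
    """Inclusion/exclusion rules for the cohort.

    Inclusion requires the stated etiology, Ashworth <= max_ashworth,
    and time since the incident <= max_months. Exclusion labels are
    matched (case-insensitively) against each record's comorbidities.
    """

    required_etiology: str = "hemorrhagic stroke"
    max_ashworth: int = 3
    max_months: float = 6.0
    neurological_labels: Tuple[str, ...] = ("parkinson's disease",)
    arthritis_labels: Tuple[str, ...] = ("rheumatoid arthritis",)
    stiffness_labels: Tuple[str, ...] = ("joint stiffness",)


# Fixed precedence of exclusion reasons: a record carrying several
# reasons is tallied under the first that matches, in this order.
EXCLUSION_REASON_ORDER = (
    "neurological_comorbidity",
    "rheumatoid_arthritis",
    "joint_stiffness",
    "ashworth_above_max",
    "time_since_incident",
    "etiology",
    "other_musculoskeletal",
)


def _has_label(record: StudyRecord, labels: Tuple[str, ...]) -> bool:
    have = {c.strip().lower() for c in record.comorbidities}
    return any(lbl.lower() in have for lbl in labels)


def exclusion_reason(
    record: StudyRecord, criteria: EligibilityCriteria
) -> Optional[str]:
    """First matching exclusion reason per the documented precedence, or
    None if the record is eligible."""
    for fname in ("ashworth", "months_since_diagnosis"):
        if getattr(record, fname) is None:
            raise ValueError(
                f"record {record.patient_id!r} is missing field {fname!r}"
            )
    if _has_label(record, criteria.neurological_labels):
        return "neurological_comorbidity"
    if _has_label(record, criteria.arthritis_labels):
        return "rheumatoid_arthritis"
    if _has_label(record, criteria.stiffness_labels):
        return "joint_stiffness"
    if record.ashworth > criteria.max_ashworth:
        return "ashworth_above_max"
    if record.months_since_diagnosis > criteria.max_months:
        return "time_since_incident"
    if record.etiology.strip().lower() != criteria.required_etiology.lower():
        return "etiology"
    return None


def cohort_filter(
    records: Sequence[StudyRecord],
    criteria: Optional[EligibilityCriteria] = None,
) -> Tuple[List[StudyRecord], Dict[str, int]]:
    """Split screened records into (included, exclusion tally by reason).

    Conserves records: len(included) + sum(tally.values()) equals the
    input count, and filtering the included output again is the identity.
    """
    criteria = criteria if criteria is not None else EligibilityCriteria()
    included: List[StudyRecord] = []
    tally: Counter = Counter()
    for rec in records:
        reason = exclusion_reason(rec, criteria)
        if reason is None:
            included.append(rec)
        else:
            tally[reason] += 1
    return included, dict(tally)


# ---------------------------------------------------------------------------
# Likert questionnaire summaries
# ---------------------------------------------------------------------------


def likert_summarize(
    responses: Union[pd.DataFrame, Dict[str, Dict[str, int]]],
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Per-item response percentages on the 4-level scale.

    Accepts either a DataFrame of raw responses (one row per subject,
    one column per item) or a mapping item -> {level: count}. Returns a
    DataFrame indexed by item with one column per level plus collapsed
    ``agree_combined`` (agree + strongly agree) and ``disagree_combined``
    columns, all rounded to one decimal, half away from zero.
    """
    if isinstance(responses, pd.DataFrame):
        counts = {
            str(col): {
                lvl: int((responses[col] == lvl).sum()) for lvl in LIKERT_LEVELS
            }
            for col in responses.columns
        }
        unknown = set(np.unique(responses.values.astype(str))) - set(LIKERT_LEVELS)
        if unknown:
            raise ValueError(f"unknown Likert levels: {sorted(unknown)}")
        if n is None:
            n = len(responses)
    else:
        counts = {
            item: {lvl: int(cnt.get(lvl, 0)) for lvl in LIKERT_LEVELS}
            for item, cnt in responses.items()
        }
        if n is None:
            n = max(sum(c.values()) for c in counts.values())
    rows = {}
    for item, cnt in counts.items():
        total = sum(cnt.values())
        if total > n:
            raise ValueError(f"item {item!r}: counts ({total}) exceed n ({n})")
        pct = {lvl: _round_half_away(100.0 * cnt[lvl] / n) for lvl in LIKERT_LEVELS}
        pct["disagree_combined"] = _round_half_away(
            100.0 * (cnt["strongly disagree"] + cnt["disagree"]) / n
        )
        pct["agree_combined"] = _round_half_away(
            100.0 * (cnt["agree"] + cnt["strongly agree"]) / n
        )
        rows[item] = pct
    return pd.DataFrame.from_dict(rows, orient="index")[
        list(LIKERT_LEVELS) + ["disagree_combined", "agree_combined"]
    ]


# ---------------------------------------------------------------------------
# Synthetic paired-score generation (the study's data are unreleased)
# ---------------------------------------------------------------------------


def generate_paired_scores(
    n: int,
    mean_x: float = STUDY_ARBBT_MEAN,
    sd_x: float = STUDY_ARBBT_SD,
    mean_y: float = STUDY_BBT_MEAN,
    sd_y: float = STUDY_BBT_SD,
    rho: float = STUDY_RHO,
    seed: Optional[int] = None,
    integerize: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded bivariate-normal paired scores with the given moments.

    With ``integerize`` the draws are rounded to the nearest non-negative
    integer (block counts). Defaults are the reference study moments
    (x = AR-BBT, y = BBT).
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be below 1")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sd_x * sd_x, rho * sd_x * sd_y],
            [rho * sd_x * sd_y, sd_y * sd_y],
        ]
    )
    xy = rng.multivariate_normal([mean_x, mean_y], cov, size=n)
    x, y = xy[:, 0], xy[:, 1]
    if integerize:
        x = np.maximum(np.rint(x), 0.0)
        y = np.maximum(np.rint(y), 0.0)
    return x, y


def synthetic_screened_cohort(seed: Optional[int] = None) -> List[StudyRecord]:
    """A synthetic 48-patient screened table emulating the study's
    recruitment: 31 eligible hemorrhagic-stroke patients plus 5 excluded
    for Parkinson's disease, 9 for rheumatoid arthritis of the finger
    joints, and 3 for finger-joint stiffness. Eligible patients carry
    paired synthetic scores, demographics and questionnaire responses.
    """
    rng = np.random.default_rng(seed)
    arbbt, bbt = generate_paired_scores(
        STUDY_N, seed=int(rng.integers(2**31)), integerize=True
    )
    records: List[StudyRecord] = []
    # Demographics near the study cohort: age 72.22 +/- 5.23 y, time from
    # diagnosis 4.49 +/- 1.12 months, Ashworth mean ~1.96, 20 M / 11 F.
    sexes = ["male"] * 20 + ["female"] * 11
    rng.shuffle(sexes)
    for i in range(STUDY_N):
        months = float(np.clip(rng.normal(4.49, 1.12), 0.5, 6.0))
        q = tuple(
            LIKERT_LEVELS[int(k)]
            for k in rng.choice(4, size=len(QUESTIONNAIRE_ITEMS), p=[0.05, 0.15, 0.45, 0.35])
        )
        records.append(
            StudyRecord(
                patient_id=f"P{i + 1:03d}",
                bbt_score=int(bbt[i]),
                arbbt_score=int(arbbt[i]),
                age=float(np.round(rng.normal(72.22, 5.23), 1)),
                sex=sexes[i],
                months_since_diagnosis=round(months, 1),
                ashworth=int(np.clip(np.rint(rng.normal(1.96, 0.89)), 0, 3)),
                etiology="hemorrhagic stroke",
                questionnaire=q,
            )
        )
    excluded_specs = (
        [("parkinson's disease",)] * 5
        + [("rheumatoid arthritis",)] * 9
        + [("joint stiffness",)] * 3
    )
    for j, comorb in enumerate(excluded_specs):
        records.append(
            StudyRecord(
                patient_id=f"X{j + 1:03d}",
                age=float(np.round(rng.normal(72.22, 5.23), 1)),
                sex="male" if rng.random() < 0.5 else "female",
                months_since_diagnosis=round(float(np.clip(rng.normal(4.49, 1.12), 0.5, 6.0)), 1),
                ashworth=int(np.clip(np.rint(rng.normal(1.96, 0.89)), 0, 3)),
                etiology="hemorrhagic stroke",
                comorbidities=comorb,
            )
        )
    order = rng.permutation(len(records))
    return [records[k] for k in order]


# ---------------------------------------------------------------------------
# Study-table CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id",
    "bbt_score",
    "arbbt_score",
    "age",
    "sex",
    "months_since_diagnosis",
    "ashworth",
    "etiology",
    "comorbidities",
] + [f"q{i + 1}" for i in range(len(QUESTIONNAIRE_ITEMS))]


def study_table_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "bbt_score": r.bbt_score,
            "arbbt_score": r.arbbt_score,
            "age": r.age,
            "sex": r.sex,
            "months_since_diagnosis": r.months_since_diagnosis,
            "ashworth": r.ashworth,
            "etiology": r.etiology,
            "comorbidities": ";".join(r.comorbidities),
        }
        for i in range(len(QUESTIONNAIRE_ITEMS)):
            row[f"q{i + 1}"] = (
                r.questionnaire[i] if r.questionnaire is not None else ""
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_study_csv(records: Sequence[StudyRecord], path: Union[str, Path]) -> None:
    study_table_frame(records).to_csv(path, index=False)


def read_study_csv(path: Union[str, Path]) -> List[StudyRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        q_vals = [str(row[f"q{i + 1}"]) for i in range(len(QUESTIONNAIRE_ITEMS))]
        questionnaire = tuple(q_vals) if all(q_vals) else None
        comorb = tuple(c for c in str(row["comorbidities"]).split(";") if c)

        def _num(name, cast):
            v = row[name]
            return None if v == "" else cast(float(v))

        records.append(
            StudyRecord(
                patient_id=row["patient_id"],
                bbt_score=_num("bbt_score", int),
                arbbt_score=_num("arbbt_score", int),
                age=_num("age", float),
                sex=str(row["sex"]) or None,
                months_since_diagnosis=_num("months_since_diagnosis", float),
                ashworth=_num("ashworth", int),
                etiology=str(row["etiology"]),
                comorbidities=comorb,
                questionnaire=questionnaire,
            )
        )
    return records


def questionnaire_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Raw questionnaire responses of records that carry them, one row
    per subject, columns named by the item text."""
    rows = [r.questionnaire for r in records if r.questionnaire is not None]
    return pd.DataFrame(rows, columns=list(QUESTIONNAIRE_ITEMS))
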