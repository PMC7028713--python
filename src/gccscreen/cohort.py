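"""Cohort table I/O, eligibility filtering and descriptive statistics.

The cohort is a subject-level table: one row per postmenopausal woman with
age, ten continuous metabolic biomarkers (BMI, WHR, total cholesterol,
triglycerides, HDL-C, LDL-C, fasting plasma glucose, OGTT 2-h plasma
glucose, systolic and diastolic blood pressure) and five reproductive
factors (age at menarche, age at menopause, reproductive life span, live
births, abortion count).  Missing cells are carried explicitly as NaN.

This module provides schema-validated CSV reading/writing, eligibility
filtering with an exclusion tally, anthropometric derivations (BMI, WHR),
the classic proportion sample-size formula, age-stratified descriptive
summaries (mean/SD/n with one-way ANOVA, Levene and Lilliefors-KS
normality tests), reproductive-factor frequency tables, and the Pearson
correlation + hierarchical-clustering structure of the biomarkers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import ConfigError, DomainError, FormatError, SchemaError

#: Canonical biomarker column names, in fixed order.
BIOMARKERS: tuple[str, ...] = (
    "bmi", "whr", "tc", "tg", "hdl", "ldl", "fpg", "ogtt2h", "sbp", "dbp",
)

#: Canonical reproductive-factor column names.
REPRO_FACTORS: tuple[str, ...] = (
    "menarche_age", "menopause_age", "repro_lifespan", "live_births", "abortions",
)

#: Columns every cohort CSV must provide (possibly under mapped names).
MANDATORY_COLUMNS: tuple[str, ...] = ("subject_id", "age") + BIOMARKERS + REPRO_FACTORS

#: Default age strata (inclusive lower/upper bounds in years).
DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (41.0, 50.0), (51.0, 65.0), (66.0, math.inf),
)

_NUMERIC_COLUMNS = ("age",) + BIOMARKERS + REPRO_FACTORS


def _round2(x: float) -> float:
    """Round a non-negative value half-up to 2 decimals (table convention)."""
    return math.floor(x * 100.0 + 0.5) / 100.0


@dataclass
class CohortTable:
    """A typed subject-level cohort table.

    ``data`` holds one row per subject with the canonical columns of
    :data:`MANDATORY_COLUMNS`; missing cells are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table lacks mandatory column(s): {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def biomarkers(self) -> pd.DataFrame:
        """Return the 10 biomarker columns (view, canonical order)."""
        return self.data.loc[:, list(BIOMARKERS)]

    def validate(self, lifespan_tol: float = 1e-6) -> None:
        """Check the value-level invariants; raise :class:`DomainError` on violation.

        Present biomarker values must be strictly positive, WHR must lie in
        (0.3, 1.5), the reproductive-life-span identity
        ``repro_lifespan = menopause_age - menarche_age`` must hold wherever
        all three are present, and the two count variables must be
        non-negative integers.
        """
        bio = self.biomarkers()
        if (bio <= 0).any().any():
            bad = [c for c in BIOMARKERS if (bio[c] <= 0).any()]
            raise DomainError(f"non-positive biomarker value(s) in: {bad}")
        whr = self.data["whr"].dropna()
        if ((whr <= 0.3) | (whr >= 1.5)).any():
            raise DomainError("whr outside (0.3, 1.5)")
        trio = self.data[["menarche_age", "menopause_age", "repro_lifespan"]].dropna()
        resid = trio["repro_lifespan"] - (trio["menopause_age"] - trio["menarche_age"])
        if (resid.abs() > lifespan_tol).any():
            raise DomainError("repro_lifespan != menopause_age - menarche_age")
        for c in ("live_births", "abortions"):
            v = self.data[c].dropna()
            if (v < 0).any() or (v != np.round(v)).any():
                raise DomainError(f"{c} must be non-negative integers")


def read_cohort(path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path
        CSV file with a header row, one subject per row, UTF-8.
    schema
        Optional mapping from canonical column names to the names used in
        the file; identity for unmapped columns.  Empty cells become NaN.

    Raises
    ------
    SchemaError
        if a mandatory column is absent (the error names it).
    FormatError
        if more than half of a numeric column's non-empty cells fail to
        parse.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in MANDATORY_COLUMNS}
    present = {v for v in raw.columns}
    for canonical in MANDATORY_COLUMNS:
        if schema.get(canonical, canonical) not in present:
            raise SchemaError(f"missing mandatory column: {canonical!r} "
                              f"(file column {schema.get(canonical, canonical)!r})")
    df = raw.rename(columns=rename).loc[:, list(MANDATORY_COLUMNS)].copy()
    for col in _NUMERIC_COLUMNS:
        cells = df[col].str.strip()
        nonempty = cells != ""
        parsed = pd.to_numeric(cells.where(nonempty, np.nan), errors="coerce")
        bad = int((nonempty & parsed.isna()).sum())
        n_nonempty = int(nonempty.sum())
        if n_nonempty and bad > 0.5 * n_nonempty:
            raise FormatError(
                f"column {col!r}: {bad}/{n_nonempty} non-empty cells are not numeric")
        df[col] = parsed.astype(float)
    return CohortTable(df.reset_index(drop=True))


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV (missing cells as empty strings); round-trips with
    :func:`read_cohort` bit-exactly for finite decimal values."""
    table.data.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# eligibility filtering

_CRITERION_OPS = {
    "eq": lambda s, v: s == v,
    "ne": lambda s, v: s != v,
    "ge": lambda s, v: s >= v,
    "le": lambda s, v: s <= v,
    "notnull": lambda s, v: s.notna(),
}


@dataclass(frozen=True)
class EligibilityCriterion:
    """One inclusion rule: keep rows where ``column <op> value`` holds.

    NaN comparisons evaluate false, so rows missing the flag are excluded
    by every op except ``notnull``.
    """

    name: str
    column: str
    op: str
    value: object = None

    def __post_init__(self) -> None:
        if self.op not in _CRITERION_OPS:
            raise ConfigError(f"unknown eligibility op {self.op!r}")


def apply_eligibility(
    table: CohortTable, criteria: Sequence[EligibilityCriterion],
) -> tuple[CohortTable, dict[str, int]]:
    """Apply inclusion criteria in order; return the filtered table and a
    tally of rows removed per criterion (in application order)."""
    df = table.data
    tally: dict[str, int] = {}
    for crit in criteria:
        if crit.column not in df.columns:
            raise ConfigError(f"criterion {crit.name!r} references absent column "
                              f"{crit.column!r}")
        keep = _CRITERION_OPS[crit.op](df[crit.column], crit.value)
        keep = keep.fillna(False).astype(bool)
        tally[crit.name] = int((~keep).sum())
        df = df.loc[keep]
    return CohortTable(df.reset_index(drop=True)), tally


# ---------------------------------------------------------------------------
# derivations and the sample-size formula

def compute_anthropometrics(weight_kg, height_m, waist_cm, hip_cm):
    """BMI = weight (kg) / height (m)^2 and WHR = waist (cm) / hip (cm).

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    w, h, wa, hi = (np.asarray(a, dtype=float) for a in
                    (weight_kg, height_m, waist_cm, hip_cm))
    if np.any(w <= 0) or np.any(h <= 0) or np.any(wa <= 0) or np.any(hi <= 0):
        raise DomainError("anthropometric inputs must be strictly positive")
    bmi = w / h ** 2
    whr = wa / hi
    if bmi.ndim == 0:
        return float(bmi), float(whr)
    return bmi, whr


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the proportion sample-size formula N = Z^2 P(1-P)/eps^2."""

    confidence: float = 0.95
    margin: float = 0.05
    p: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.confidence < 1):
            raise ConfigError("confidence must lie in (0, 1)")
        if not (0 < self.margin < 1):
            raise ConfigError("margin must lie in (0, 1)")
        if not (0 < self.p < 1):
            raise ConfigError("p must lie in (0, 1)")


def sample_size(params: SampleSizeParams) -> int:
    """Required N for estimating a proportion P to margin eps at the given
    confidence: ``N = Z_{alpha/2}^2 * P(1-P) / eps^2``, rounded half-up.

    Half-up rounding is used (384.146 -> 384); a ceiling convention would
    give 385 instead.
    """
    z = stats.norm.ppf(1.0 - (1.0 - params.confidence) / 2.0)
    n_raw = z * z * params.p * (1.0 - params.p) / params.margin ** 2
    return int(math.floor(n_raw + 0.5))


# ---------------------------------------------------------------------------
# descriptive statistics

@dataclass
class DescriptiveSummary:
    """Age-stratified biomarker descriptives.

    ``group_stats`` is indexed by biomarker with one (mean, sd, n) triple of
    columns per age stratum; ``tests`` holds the per-biomarker one-way ANOVA
    p-value, Levene p-value and Lilliefors-KS normality p-value (NaN where
    undefined, e.g. a stratum with fewer than 2 rows or zero variance).
    """

    group_labels: list[str]
    group_stats: pd.DataFrame
    tests: pd.DataFrame
    n_total: int


def _bin_label(lo: float, hi: float) -> str:
    if math.isinf(hi):
        return f">{lo - 1:g}" if float(lo).is_integer() else f">={lo:g}"
    return f"{lo:g}-{hi:g}"


def descriptive_by_age(
    table: CohortTable,
    bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    columns: Sequence[str] = BIOMARKERS,
) -> DescriptiveSummary:
    """Summarize biomarkers within inclusive age strata.

    Rows whose age falls in no stratum are excluded from the summary.  Test
    p-values are NaN (never an exception) when undefined: any stratum with
    fewer than 2 non-missing values, or zero variance everywhere.
    """
    df = table.data
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    masks = [(df["age"] >= lo) & (df["age"] <= hi) for lo, hi in bins]
    stats_rows, test_rows = {}, {}
    n_total = int(sum(int(m.sum()) for m in masks))
    for col in columns:
        groups = [df.loc[m, col].dropna().to_numpy() for m in masks]
        row = {}
        for lab, g in zip(labels, groups):
            row[f"{lab}_mean"] = float(np.mean(g)) if g.size else np.nan
            row[f"{lab}_sd"] = float(np.std(g, ddof=1)) if g.size > 1 else (
                0.0 if g.size == 1 else np.nan)
            row[f"{lab}_n"] = int(g.size)
        stats_rows[col] = row
        usable = [g for g in groups if g.size >= 2]
        anova_p = levene_p = np.nan
        if len(usable) == len(groups) and len(groups) >= 2:
            pooled_var = sum(float(np.var(g, ddof=1)) for g in usable)
            if pooled_var > 0 or len({g.mean() for g in usable}) > 1:
                if pooled_var > 0:
                    anova_p = float(stats.f_oneway(*usable).pvalue)
                    levene_p = float(stats.levene(*usable).pvalue)
        allvals = df[col].dropna().to_numpy()
        ks_p = np.nan
        if allvals.size >= 4 and np.std(allvals) > 0:
            ks_p = float(lilliefors(allvals, dist="norm", pvalmethod="table")[1])
        test_rows[col] = {"anova_p": anova_p, "levene_p": levene_p, "ks_p": ks_p}
    return DescriptiveSummary(
        group_labels=labels,
        group_stats=pd.DataFrame.from_dict(stats_rows, orient="index"),
        tests=pd.DataFrame.from_dict(test_rows, orient="index"),
        n_total=n_total,
    )


# ---------------------------------------------------------------------------
# reproductive-factor frequency tables

@dataclass(frozen=True)
class FrequencyBin:
    """One ordered category: values v with lo <= v < hi fall in the bin."""

    label: str
    lo: float
    hi: float


@dataclass
class FrequencyTable:
    """Per-factor category counts with percentages of the full cohort n.

    Percentages are denominated by the total included n (the published-table
    convention), while ``factor_n`` records each factor's own non-missing
    denominator, which may differ when factors have unequal missingness.
    """

    n_total: int
    tables: dict[str, pd.DataFrame]
    factor_n: dict[str, int]


def percentage(count: int, n: int) -> float:
    """Table-style percentage: 100*count/n rounded half-up to 2 decimals."""
    if n <= 0:
        raise DomainError("denominator must be positive")
    return _round2(100.0 * count / n)


def reproductive_frequency(
    table: CohortTable,
    bin_specs: Mapping[str, Sequence[FrequencyBin]],
) -> FrequencyTable:
    """Count subjects per category bin for each reproductive factor.

    Missing values are excluded from counts; percentages use the full
    cohort size as denominator.  Overlapping bins raise ConfigError.
    """
    n_total = len(table)
    tables: dict[str, pd.DataFrame] = {}
    factor_n: dict[str, int] = {}
    for factor, bins in bin_specs.items():
        if factor not in table.data.columns:
            raise ConfigError(f"unknown reproductive factor {factor!r}")
        ordered = sorted(bins, key=lambda b: b.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo < a.hi:
                raise ConfigError(
                    f"overlapping bins for {factor!r}: {a.label!r} and {b.label!r}")
        vals = table.data[factor].dropna()
        factor_n[factor] = int(vals.size)
        rows = []
        for b in bins:
            count = int(((vals >= b.lo) & (vals < b.hi)).sum())
            rows.append({"category": b.label, "count": count,
                         "pct": percentage(count, n_total) if n_total else np.nan})
        tables[factor] = pd.DataFrame(rows)
    return FrequencyTable(n_total=n_total, tables=tables, factor_n=factor_n)


# ---------------------------------------------------------------------------
# correlation structure

@dataclass
class CorrelationStructure:
    """Pairwise Pearson correlations among biomarkers plus their
    average-linkage agglomeration under the distance 1 - |r|.

    ``linkage_matrix`` is a scipy hierarchical-clustering linkage array
    (exactly ``len(labels) - 1`` merge rows).  ``degenerate`` lists any
    zero-variance biomarkers, whose correlations are undefined (NaN).
    """

    labels: list[str]
    corr: pd.DataFrame
    linkage_matrix: np.ndarray
    degenerate: list[str]


def correlation_structure(
    table: CohortTable, columns: Sequence[str] = BIOMARKERS,
) -> CorrelationStructure:
    """Pearson correlation matrix (pairwise complete observations) and
    average-linkage clustering of the biomarkers with distance 1 - |r|.

    Absolute correlation is used as similarity so that strongly negatively
    related biomarkers (e.g. HDL-C versus the rest) cluster together: the
    clustering's purpose is redundancy detection, for which the sign is
    irrelevant.  Zero-variance columns are flagged and excluded from the
    dendrogram.
    """
    sub = table.data.loc[:, list(columns)]
    corr = sub.corr(method="pearson", min_periods=2)
    degenerate = [c for c in columns if sub[c].dropna().nunique() <= 1]
    usable = [c for c in columns if c not in degenerate]
    dist = 1.0 - corr.loc[usable, usable].abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    return CorrelationStructure(
        labels=list(usable), corr=corr, linkage_matrix=z, degenerate=degenerate)
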