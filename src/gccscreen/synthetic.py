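"""Synthetic cohort generator with a single latent metabolic-health factor.

The generator emulates the statistical structure the downstream analysis
assumes: ten biomarkers that share one latent factor L (their pairwise
correlation is the product of factor loadings), reproductive factors whose
standardized values shift L, published-table-calibrated marginal means/SDs
and category frequencies, and configurable item-level missingness.  The
latent factor and pre-missingness reproductive factors are returned
alongside the cohort as ground truth for recovery testing; they are never
an input to any inference stage.

Generative model (per subject i):

    menarche, menopause  ~ categorical bins (uniform within bin)
    lifespan              = menopause - menarche            (exact identity)
    L_i = a_men * z(menarche_i) + a_life * z(lifespan_i)
          + sqrt(1 - a_men^2 - a_life^2) * eta_i,    eta ~ N(0, 1)
    x_ij = mu_j + sigma_j * (lambda_j * g_j(L_i) + sqrt(1-lambda_j^2) e_ij)

with e ~ N(0,1) i.i.d. and g_j either the identity ("none") or a
per-biomarker saturating link ("saturating"):

    g_j(L) = tanh(gain * (L - c_j))

with the centres c_j spread across the latent range so that each biomarker
saturates in a different region.  A shared saturating link would leave the
data on a straight line in biomarker space (the scalar tanh(L) would simply
replace L as the common factor); the per-biomarker centres are what bend
the one-dimensional manifold into a curve, the regime in which a nonlinear
encoder can genuinely beat a linear projection.  g_j is standardized
empirically within each generated sample so the configured marginal SDs are
preserved and, under the identity link, corr(x_i, x_j) = lambda_i*lambda_j
exactly in population.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import BIOMARKERS, REPRO_FACTORS, CohortTable, FrequencyBin
from .exceptions import ConfigError

#: Published-table marginal (mean, SD) per biomarker ("Total" column).
TABLE1_MARGINALS: dict[str, tuple[float, float]] = {
    "bmi": (22.54, 2.91),
    "whr": (0.86, 0.07),
    "tc": (4.46, 0.94),
    "tg": (1.73, 1.16),
    "hdl": (1.30, 0.31),
    "ldl": (2.75, 0.72),
    "fpg": (4.88, 0.90),
    "ogtt2h": (6.50, 2.10),
    "sbp": (120.39, 13.75),
    "dbp": (76.50, 11.76),
}

#: Age-stratum sizes from the published cohort (41-50, 51-65, >65).
TABLE1_AGE_GROUPS: tuple[tuple[float, float, int], ...] = (
    (41.0, 50.0, 577), (51.0, 65.0, 554), (66.0, 80.0, 525),
)


@dataclass(frozen=True)
class RFCategory:
    """One reproductive-factor category: draw uniform on [lo, hi) with
    probability ``prob``.  ``count`` is the published category count."""

    label: str
    lo: float
    hi: float
    count: int


def _rf(categories: Sequence[tuple[str, float, float, int]]) -> tuple[RFCategory, ...]:
    return tuple(RFCategory(*c) for c in categories)


#: Published category counts per reproductive factor.  Bin edges are placed
#: at half-integers so a continuous draw falls back into its own category;
#: open-ended bins take the width of the adjacent bin.  Note the published
#: per-factor totals are not all equal (1,655-1,658): probabilities are
#: normalized within each factor.
TABLE2_CATEGORIES: dict[str, tuple[RFCategory, ...]] = {
    "menarche_age": _rf([
        ("<=12", 11.5, 12.5, 77), ("13", 12.5, 13.5, 387), ("14", 13.5, 14.5, 662),
        ("15", 14.5, 15.5, 219), ("16", 15.5, 16.5, 129), (">=17", 16.5, 17.5, 182),
    ]),
    "menopause_age": _rf([
        ("<=45", 42.5, 45.5, 137), ("46-48", 45.5, 48.5, 477),
        ("49-50", 48.5, 50.5, 691), (">=51", 50.5, 52.5, 353),
    ]),
    "live_births": _rf([
        ("0", -0.5, 0.5, 200), ("1", 0.5, 1.5, 752),
        ("2", 1.5, 2.5, 468), (">=3", 2.5, 3.5, 236),
    ]),
    "abortions": _rf([
        ("0", -0.5, 0.5, 1532), ("1", 0.5, 1.5, 86), (">=2", 1.5, 2.5, 39),
    ]),
    # life span is derived (menopause - menarche); bins used for reporting only
    "repro_lifespan": _rf([
        ("<=29", 20.0, 29.5, 182), ("30-33", 29.5, 33.5, 452),
        ("34-36", 33.5, 36.5, 641), ("37-39", 36.5, 39.5, 272),
        (">=40", 39.5, 60.0, 108),
    ]),
}

_COUNT_FACTORS = ("live_births", "abortions")


def default_frequency_bins() -> dict[str, list[FrequencyBin]]:
    """Frequency-table bin specs matching the published category layout."""
    return {
        factor: [FrequencyBin(c.label, c.lo, c.hi) for c in cats]
        for factor, cats in TABLE2_CATEGORIES.items()
    }


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic cohort.

    Attributes
    ----------
    n, seed
        Cohort size and the seed controlling all draws.
    biomarker_marginals
        Per-biomarker (mean, SD), defaulting to the published totals.
    loadings
        Per-biomarker factor loading lambda_j in [-1, 1]; HDL-C loads
        negatively (higher HDL-C is metabolically protective).
    nonlinearity
        "none" (identity link) or "saturating" (per-biomarker tanh link).
    sat_gain, sat_centers
        Saturating-link steepness and per-biomarker centres (defaults:
        gain 2.5, centres evenly spaced on [-1.2, 1.2]).
    rf_effects
        (a_menarche, a_lifespan): standardized effects of menarche age and
        reproductive life span on the latent factor; both non-positive so
        earlier menarche and shorter life span raise L (worse metabolic
        state), matching the direction of the reported associations.
    rf_marginals
        Category probabilities per reproductive factor (published defaults).
    missing_rate, missing_mechanism, missing_columns, mar_slope
        Item-level missingness: per-column probability, "MCAR" or
        "MAR-age" (logistic in standardized age with slope ``mar_slope``),
        applied to the reproductive factors by default.
    """

    n: int = 1656
    seed: int = 0
    biomarker_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_MARGINALS))
    loadings: dict[str, float] = field(
        default_factory=lambda: {b: (-0.7 if b == "hdl" else 0.7) for b in BIOMARKERS})
    nonlinearity: str = "none"
    sat_gain: float = 2.5
    sat_centers: dict[str, float] | None = None
    rf_effects: tuple[float, float] = (-0.3, -0.3)
    rf_marginals: dict[str, tuple[RFCategory, ...]] = field(
        default_factory=lambda: dict(TABLE2_CATEGORIES))
    missing_rate: float = 0.05
    missing_mechanism: str = "MCAR"
    missing_columns: tuple[str, ...] = REPRO_FACTORS
    mar_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for b, lam in self.loadings.items():
            if abs(lam) > 1.0:
                raise ConfigError(f"loading for {b!r} outside [-1, 1]: {lam}")
        a1, a2 = self.rf_effects
        if a1 * a1 + a2 * a2 > 1.0:
            raise ConfigError("rf_effects too large: a_men^2 + a_life^2 must be <= 1")
        if self.nonlinearity not in ("none", "saturating"):
            raise ConfigError(f"unknown nonlinearity {self.nonlinearity!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR-age"):
            raise ConfigError(f"unknown missing mechanism {self.missing_mechanism!r}")
        for factor, cats in self.rf_marginals.items():
            total = sum(c.count for c in cats)
            if total <= 0:
                raise ConfigError(f"empty category counts for {factor!r}")

    def category_probs(self, factor: str) -> np.ndarray:
        cats = self.rf_marginals[factor]
        counts = np.array([c.count for c in cats], dtype=float)
        return counts / counts.sum()


def default_config(calibration: str = "table1", **overrides) -> SyntheticConfig:
    """The published-table-calibrated configuration (the study conditions)."""
    if calibration != "table1":
        raise ConfigError(f"unknown calibration {calibration!r}")
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def _default_centers() -> dict[str, float]:
    centers = np.linspace(-1.2, 1.2, len(BIOMARKERS))
    return dict(zip(BIOMARKERS, centers))


def _draw_categorical(rng: np.random.Generator, cats: Sequence[RFCategory],
                      probs: np.ndarray, n: int, integer: bool) -> np.ndarray:
    idx = rng.choice(len(cats), size=n, p=probs)
    lo = np.array([c.lo for c in cats])[idx]
    hi = np.array([c.hi for c in cats])[idx]
    if integer:
        # count variables: the bin identifies the integer value (midpoint)
        return np.round((lo + hi) / 2.0)
    return lo + rng.uniform(0.0, 1.0, size=n) * (hi - lo)


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Generate a cohort and its latent ground-truth record.

    Returns ``(cohort, truth)`` where ``truth`` has columns ``subject_id``,
    ``latent`` (the factor L) and the pre-missingness reproductive factors.
    Reproducible bit-for-bit given the seed.  Missingness is NOT applied
    here; see :func:`inject_missing`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    # ages: stratum mixture matching the published group sizes
    group_n = np.array([g[2] for g in TABLE1_AGE_GROUPS], dtype=float)
    gidx = rng.choice(len(TABLE1_AGE_GROUPS), size=n, p=group_n / group_n.sum())
    glo = np.array([g[0] for g in TABLE1_AGE_GROUPS])[gidx]
    ghi = np.array([g[1] for g in TABLE1_AGE_GROUPS])[gidx]
    age = np.round(glo + rng.uniform(0.0, 1.0, size=n) * (ghi - glo), 1)

    # reproductive factors
    menarche = _draw_categorical(
        rng, config.rf_marginals["menarche_age"],
        config.category_probs("menarche_age"), n, integer=False)
    menopause = _draw_categorical(
        rng, config.rf_marginals["menopause_age"],
        config.category_probs("menopause_age"), n, integer=False)
    lifespan = menopause - menarche
    births = _draw_categorical(
        rng, config.rf_marginals["live_births"],
        config.category_probs("live_births"), n, integer=True)
    abortions = _draw_categorical(
        rng, config.rf_marginals["abortions"],
        config.category_probs("abortions"), n, integer=True)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    a_men, a_life = config.rf_effects
    resid = np.sqrt(max(0.0, 1.0 - a_men ** 2 - a_life ** 2))
    latent = a_men * z(menarche) + a_life * z(lifespan) + resid * rng.standard_normal(n)
    # menarche and life span are negatively correlated, which shrinks the
    # raw variance below 1; the stored factor is standardized in-sample
    latent = z(latent)

    centers = config.sat_centers if config.sat_centers is not None else _default_centers()
    cols: dict[str, np.ndarray] = {}
    for b in BIOMARKERS:
        mu, sigma = config.biomarker_marginals[b]
        lam = config.loadings.get(b, 0.0)
        if config.nonlinearity == "saturating":
            g = np.tanh(config.sat_gain * (latent - centers[b]))
        else:
            g = latent
        gsd = g.std()
        gz = (g - g.mean()) / gsd if gsd > 0 else np.zeros_like(g)
        noise = rng.standard_normal(n)
        cols[b] = mu + sigma * (lam * gz + np.sqrt(1.0 - lam * lam) * noise)

    df = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)], "age": age})
    for b in BIOMARKERS:
        df[b] = cols[b]
    df["menarche_age"] = menarche
    df["menopause_age"] = menopause
    df["repro_lifespan"] = lifespan
    df["live_births"] = births
    df["abortions"] = abortions

    truth = pd.DataFrame({
        "subject_id": df["subject_id"], "latent": latent,
        "menarche_age": menarche, "menopause_age": menopause,
        "repro_lifespan": lifespan, "live_births": births, "abortions": abortions,
    })
    return CohortTable(df), truth


def inject_missing(table: CohortTable, config: SyntheticConfig) -> CohortTable:
    """Blank cells at the configured per-column rate.

    MCAR: each cell independently missing with probability ``missing_rate``.
    MAR-age: the per-row missingness probability is logistic in standardized
    age, ``expit(logit(rate) + mar_slope * z(age))``, so older subjects are
    (for positive slope) more often missing.  Uses a seed stream distinct
    from the generator's so cohort values are unchanged by re-injection.
    """
    rate = config.missing_rate
    if rate == 0.0:
        return CohortTable(table.data.copy())
    df = table.data.copy()
    rng = np.random.default_rng([config.seed, 1])
    if config.missing_mechanism == "MAR-age":
        zage = (df["age"] - df["age"].mean()) / df["age"].std()
        p_row = expit(logit(rate) + config.mar_slope * zage.to_numpy())
    else:
        p_row = np.full(len(df), rate)
    for col in config.missing_columns:
        mask = rng.uniform(size=len(df)) < p_row
        df.loc[mask, col] = np.nan
    return CohortTable(df)
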