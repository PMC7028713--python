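"""GCC ~ reproductive-factor association with multiple imputation.

Missing reproductive-factor values are handled by multiple imputation by
chained equations (m = 5 completed datasets by default), each completed
dataset is analysed by forward-stepwise multivariate linear regression of
the GCC on the five reproductive factors with age force-entered, and the
per-imputation estimates are combined by Rubin's rules.  Coefficients are
reported on the exponentiated scale ("OR" columns) for comparability with
the published table layout; these are exponentiated linear-regression
coefficients, NOT odds ratios from a logistic model, and the output flags
them as such.

The chained-equations engine is scikit-learn's IterativeImputer with a
Bayesian linear conditional model and posterior sampling, run once per
imputation with an offset seed — i.e. m independent chains drawing each
missing cell from its fitted conditional.  Count variables are imputed on
the continuous scale (ordinal-as-continuous).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

# IterativeImputer is behind an experimental flag in scikit-learn
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge

from .exceptions import ConfigError, ImputationError

#: exponentiated-coefficient columns are NOT logistic odds ratios
OR_SCALE_NOTE = ("'OR' columns are exponentiated linear-regression "
                 "coefficients, not odds ratios from a logistic model")


@dataclass(frozen=True)
class MICEConfig:
    """Chained-equations settings: m imputations, sweeps per imputation,
    and the master seed (chain i uses seed + i)."""

    m: int = 5
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


@dataclass
class ImputationSet:
    """m completed data frames plus the mask of cells that were imputed."""

    completed: list[pd.DataFrame]
    imputed_mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.completed)


def mice_impute(df: pd.DataFrame, variables: Sequence[str],
                cfg: MICEConfig | None = None,
                min_observed: int = 20) -> ImputationSet:
    """Multiply impute the named variables by chained equations.

    All numeric columns of ``df`` (including the response, per standard
    imputation practice) serve as predictors; only cells in ``variables``
    are ever altered.  With no missing cells the result is m identical
    copies of the input.  Deterministic given the seed.

    Raises ImputationError if a target variable is entirely missing or has
    fewer than ``min_observed`` observed rows.
    """
    cfg = cfg or MICEConfig()
    num = df.select_dtypes(include=[np.number])
    for v in variables:
        if v not in num.columns:
            raise ConfigError(f"imputation target {v!r} is not a numeric column")
        obs = num[v].notna().sum()
        if obs == 0:
            raise ImputationError(f"variable {v!r} is entirely missing")
        if obs < min_observed:
            raise ImputationError(
                f"variable {v!r} has only {obs} observed rows (< {min_observed})")
    mask = num[list(variables)].isna()
    if not mask.to_numpy().any():
        return ImputationSet([df.copy() for _ in range(cfg.m)],
                             imputed_mask=mask)
    completed = []
    for i in range(cfg.m):
        imputer = IterativeImputer(
            estimator=BayesianRidge(), sample_posterior=True,
            max_iter=cfg.iterations, random_state=cfg.seed + i,
            keep_empty_features=True)
        filled = pd.DataFrame(imputer.fit_transform(num),
                              columns=num.columns, index=num.index)
        out = df.copy()
        for v in variables:
            out.loc[mask[v], v] = filled.loc[mask[v], v]
        # predictors outside `variables` keep their original NaNs
        completed.append(out)
    return ImputationSet(completed, imputed_mask=mask)


# ---------------------------------------------------------------------------
# forward-stepwise linear regression

@dataclass
class RegressionResult:
    """One OLS fit: per-variable coefficient/SE/p (intercept under
    'const'), residual df, and the stepwise entry trace."""

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    df_resid: float
    entered: list[str]
    trace: list[dict] = field(default_factory=list)


def fit_stepwise(df: pd.DataFrame, response: str,
                 candidates: Sequence[str],
                 forced: Sequence[str] = ("age",),
                 alpha: float = 0.05,
                 cond_threshold: float = 1e10) -> RegressionResult:
    """Forward-stepwise OLS with force-entered covariates.

    Starting from intercept + forced covariates, each step adds the
    candidate with the smallest partial-F p-value (equivalently, for a
    single added column, its coefficient's t-test p-value) provided it is
    below ``alpha``; stops when no candidate qualifies.  Candidates whose
    addition makes the design rank-deficient or ill-conditioned (condition
    number above ``cond_threshold``) are skipped and recorded in the trace
    — this is how the exact collinearity life span = menopause - menarche
    resolves: whichever two of the trio enter first block the third.

    ``alpha >= 1`` enters every (non-collinear) candidate; ``alpha <= 0``
    enters none.
    """
    cols = [response, *forced, *candidates]
    data = df.loc[:, cols].dropna()
    if data.empty:
        raise ConfigError("no complete rows for stepwise regression")
    y = data[response].to_numpy(dtype=float)
    entered: list[str] = []
    trace: list[dict] = []
    remaining = list(candidates)

    def design(names: Sequence[str]) -> np.ndarray:
        X = data.loc[:, list(names)].to_numpy(dtype=float)
        return sm.add_constant(X, has_constant="add")

    def well_conditioned(names: Sequence[str]) -> bool:
        X = design(names)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return False
        sv = np.linalg.svd(X, compute_uv=False)
        return sv[-1] > 0 and sv[0] / sv[-1] < cond_threshold

    while remaining:
        best_p, best_var = np.inf, None
        for var in remaining:
            names = [*forced, *entered, var]
            if not well_conditioned(names):
                trace.append({"step": len(entered), "candidate": var,
                              "skipped": "collinear"})
                continue
            fit = sm.OLS(y, design(names)).fit()
            p = float(fit.pvalues[-1])
            trace.append({"step": len(entered), "candidate": var, "p": p})
            if p < best_p:
                best_p, best_var = p, var
        if best_var is None or not (best_p < alpha):
            break
        entered.append(best_var)
        remaining.remove(best_var)

    final_names = [*forced, *entered]
    fit = sm.OLS(y, design(final_names)).fit()
    keys = ["const", *final_names]
    return RegressionResult(
        params={k: float(v) for k, v in zip(keys, fit.params)},
        bse={k: float(v) for k, v in zip(keys, fit.bse)},
        pvalues={k: float(v) for k, v in zip(keys, fit.pvalues)},
        df_resid=float(fit.df_resid),
        entered=entered,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Rubin's rules

@dataclass
class PooledEstimate:
    """Rubin-pooled quantities for one variable.

    qbar: mean of the m_v estimates; W: mean squared SE (within-imputation
    variance); B: between-imputation variance; T = W + (1 + 1/m_v) B;
    df by the classic Rubin formula; m_v: imputations in which the
    variable entered the model.
    """

    qbar: float
    w: float
    b: float
    t: float
    df: float
    p_value: float
    m_v: int


def pool_rubin(results: Sequence[RegressionResult],
               variables: Sequence[str] | None = None
               ) -> dict[str, PooledEstimate]:
    """Combine per-imputation OLS fits by Rubin's rules.

    Stepwise selection is re-run per imputation, so a variable may enter
    only some models; pooling then covers the union of entered variables,
    with non-entering imputations excluded and m reduced for that variable.
    With B = 0 (identical estimates, or m_v = 1) the total variance reduces
    to W and the reference t uses the smallest per-fit residual df, so a
    single imputation reproduces its own fit exactly.
    """
    if not results:
        raise ConfigError("no regression results to pool")
    if variables is None:
        seen: list[str] = []
        for r in results:
            for k in r.params:
                if k not in seen:
                    seen.append(k)
        variables = seen
    pooled: dict[str, PooledEstimate] = {}
    for var in variables:
        est = np.array([r.params[var] for r in results if var in r.params])
        ses = np.array([r.bse[var] for r in results if var in r.params])
        dfs = [r.df_resid for r in results if var in r.params]
        if est.size == 0:
            continue
        m_v = int(est.size)
        if est.max() == est.min():
            # identical estimates (e.g. the no-missing degenerate case):
            # averaging would perturb the value by an ulp, so short-circuit
            qbar, b = float(est[0]), 0.0
        else:
            qbar = float(est.mean())
            b = float(est.var(ddof=1))
        w = float((ses ** 2).mean())
        t_var = w + (1.0 + 1.0 / m_v) * b
        if b > 0:
            df = (m_v - 1) * (1.0 + w / ((1.0 + 1.0 / m_v) * b)) ** 2
        else:
            df = float(min(dfs))
        se = np.sqrt(t_var)
        p = 2.0 * float(stats.t.sf(abs(qbar) / se, df)) if se > 0 else (
            0.0 if qbar != 0 else 1.0)
        pooled[var] = PooledEstimate(qbar=qbar, w=w, b=b, t=t_var, df=df,
                                     p_value=p, m_v=m_v)
    return pooled


def to_or_scale(pooled: dict[str, PooledEstimate], level: float = 0.95
                ) -> pd.DataFrame:
    """Exponentiate pooled coefficients and their CIs (published-table
    layout).  CI bounds are always emitted as (low, high) sorted.  See
    :data:`OR_SCALE_NOTE`."""
    rows = []
    for var, p in pooled.items():
        half = stats.t.ppf(0.5 + level / 2, p.df) * np.sqrt(p.t) if p.t > 0 else 0.0
        lo, hi = sorted((np.exp(p.qbar - half), np.exp(p.qbar + half)))
        rows.append({"variable": var, "OR": float(np.exp(p.qbar)),
                     "p": p.p_value, "ci_low": float(lo), "ci_high": float(hi),
                     "m": p.m_v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end association stage

RF_CANDIDATES: tuple[str, ...] = (
    "menarche_age", "menopause_age", "repro_lifespan", "live_births", "abortions",
)

_TRIO = ("menarche_age", "menopause_age", "repro_lifespan")


def close_reproductive_trio(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministically complete the menarche/menopause/lifespan trio.

    Reproductive life span is menopause age minus menarche age by
    definition, so whenever two of the three are observed the third is
    known exactly; filling it is logical completion, not imputation.
    Returns a copy.
    """
    out = df.copy()
    men, menop, life = (out[c] for c in _TRIO)
    out.loc[life.isna() & men.notna() & menop.notna(), "repro_lifespan"] = menop - men
    out.loc[menop.isna() & men.notna() & life.notna(), "menopause_age"] = men + life
    out.loc[men.isna() & menop.notna() & life.notna(), "menarche_age"] = menop - life
    return out


@dataclass
class AssociationResult:
    pooled: dict[str, PooledEstimate]
    or_table: pd.DataFrame
    per_imputation: list[RegressionResult]
    note: str = OR_SCALE_NOTE


def run_association(df: pd.DataFrame, response: str = "gcc",
                    candidates: Sequence[str] = RF_CANDIDATES,
                    forced: Sequence[str] = ("age",),
                    cfg: MICEConfig | None = None,
                    alpha: float = 0.05) -> AssociationResult:
    """MICE -> per-imputation stepwise OLS -> Rubin pooling -> OR table.

    ``df`` must contain the response, the forced covariates and the
    candidates; only candidate columns are imputed.

    The derived variable reproductive life span is handled passively:
    missing trio cells determined by the other two members are completed
    first (:func:`close_reproductive_trio`), chained equations then impute
    menarche and menopause (never life span), and life span is re-derived
    as their difference in every completed dataset.  This keeps the
    defining identity exact — imputing the three independently would break
    it on imputed rows and let the stepwise fit chase pure imputation
    noise in the near-collinear trio.
    """
    cfg = cfg or MICEConfig()
    cols = [response, *forced, *candidates]
    work = df.loc[:, cols].copy()
    work = work[work[response].notna()].reset_index(drop=True)
    passive_trio = set(_TRIO) <= set(candidates)
    targets = list(candidates)
    if passive_trio:
        work = close_reproductive_trio(work)
        targets = [c for c in targets if c != "repro_lifespan"]
    imputations = mice_impute(work, variables=targets, cfg=cfg)
    if passive_trio:
        for comp in imputations.completed:
            comp["repro_lifespan"] = comp["menopause_age"] - comp["menarche_age"]
    fits = [fit_stepwise(comp, response, candidates, forced=forced, alpha=alpha)
            for comp in imputations.completed]
    pooled = pool_rubin(fits)
    return AssociationResult(pooled=pooled, or_table=to_or_scale(pooled),
                             per_imputation=fits)
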