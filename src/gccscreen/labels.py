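"""Binary chronic-condition labels derived from continuous biomarkers.

Three screening labels — pathoglycemia (abnormal glucose status),
hypertension and dyslipidemia — are derived by clinical cutoffs applied to
the relevant biomarkers.  Each condition is positive (1) when ANY of its
criteria fires; comparisons are inclusive (>= for upper thresholds, < for
the HDL-C lower threshold), the usual clinical convention.

Default cutoffs are declared assumptions, not facts from the source study
(which never states its cutoffs): impaired fasting glucose / impaired
glucose tolerance at FPG >= 6.1 or OGTT-2h >= 7.8 mmol/L (WHO), blood
pressure at 140/90 mmHg, and the Chinese adult dyslipidemia guideline
thresholds TC >= 6.2, TG >= 2.3, LDL-C >= 4.1, HDL-C < 1.0 mmol/L.  All are
configurable, and any criterion can be deactivated by setting it to None
(each condition must keep at least one active criterion).
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .exceptions import ConfigError, DomainError

CONDITIONS: tuple[str, ...] = ("pathoglycemia", "hypertension", "dyslipidemia")


@dataclass(frozen=True)
class CutoffSet:
    """Thresholds defining the three condition labels.

    Upper thresholds fire on ``value >= threshold``; the HDL-C threshold
    fires on ``value < threshold``.  ``None`` deactivates a criterion.
    """

    fpg_ge: float | None = 6.1
    ogtt2h_ge: float | None = 7.8
    sbp_ge: float | None = 140.0
    dbp_ge: float | None = 90.0
    tc_ge: float | None = 6.2
    tg_ge: float | None = 2.3
    ldl_ge: float | None = 4.1
    hdl_lt: float | None = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v <= 0:
                raise ConfigError(f"cutoff {f.name} must be strictly positive")
        for cond, crits in self.criteria().items():
            if not crits:
                raise ConfigError(f"condition {cond!r} has no active criterion")

    def criteria(self) -> dict[str, list[tuple[str, str, float]]]:
        """Active criteria per condition as (biomarker, direction, threshold)
        with direction 'ge' or 'lt'."""
        spec = {
            "pathoglycemia": [("fpg", "ge", self.fpg_ge), ("ogtt2h", "ge", self.ogtt2h_ge)],
            "hypertension": [("sbp", "ge", self.sbp_ge), ("dbp", "ge", self.dbp_ge)],
            "dyslipidemia": [("tc", "ge", self.tc_ge), ("tg", "ge", self.tg_ge),
                             ("ldl", "ge", self.ldl_ge), ("hdl", "lt", self.hdl_lt)],
        }
        return {cond: [(b, d, t) for b, d, t in crits if t is not None]
                for cond, crits in spec.items()}

    @classmethod
    def from_quantiles(cls, table: CohortTable, q: float = 0.9,
                       active: dict[str, bool] | None = None) -> "CutoffSet":
        """Cutoffs at each biomarker's marginal q-quantile (HDL-C at 1-q).

        Useful for synthetic cohorts where clinical units are arbitrary;
        each criterion then fires for roughly a (1-q) fraction marginally.
        ``active`` maps cutoff field names to False to deactivate them.
        """
        if not (0.0 < q < 1.0):
            raise ConfigError("quantile must lie in (0, 1)")
        d = table.data
        vals = {
            "fpg_ge": d["fpg"].quantile(q), "ogtt2h_ge": d["ogtt2h"].quantile(q),
            "sbp_ge": d["sbp"].quantile(q), "dbp_ge": d["dbp"].quantile(q),
            "tc_ge": d["tc"].quantile(q), "tg_ge": d["tg"].quantile(q),
            "ldl_ge": d["ldl"].quantile(q), "hdl_lt": d["hdl"].quantile(1.0 - q),
        }
        if active:
            for name, keep in active.items():
                if not keep:
                    vals[name] = None
        return cls(**{k: (None if v is None else float(v)) for k, v in vals.items()})


def derive_labels(table: CohortTable, cutoffs: CutoffSet | None = None) -> pd.DataFrame:
    """Derive the three 0/1 condition labels for every subject.

    A condition is 1 if any present contributing biomarker fires its
    criterion; 0 if all contributing biomarkers are present and none fires;
    NaN (undefined) when some contributors are missing and no present one
    fires.  Deterministic and row-order independent.

    Returns a DataFrame with ``subject_id`` and one float column per
    condition (0.0, 1.0 or NaN).
    """
    cutoffs = cutoffs or CutoffSet()
    df = table.data
    out = pd.DataFrame({"subject_id": df["subject_id"]})
    for cond, crits in cutoffs.criteria().items():
        fired = np.zeros(len(df), dtype=bool)
        all_present = np.ones(len(df), dtype=bool)
        for biomarker, direction, threshold in crits:
            v = df[biomarker]
            present = v.notna().to_numpy()
            all_present &= present
            hit = (v >= threshold) if direction == "ge" else (v < threshold)
            fired |= (hit.fillna(False).to_numpy() & present)
        label = np.where(fired, 1.0, np.where(all_present, 0.0, np.nan))
        out[cond] = label
    return out


def prevalence(labels: pd.DataFrame) -> dict[str, float]:
    """Proportion of positives among defined labels, per condition.

    Raises DomainError if a condition has no defined label at all.
    """
    result: dict[str, float] = {}
    for cond in CONDITIONS:
        v = labels[cond].dropna()
        if v.empty:
            raise DomainError(f"condition {cond!r} has no defined labels")
        result[cond] = float(v.mean())
    return result
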