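"""Survival association of stage-similarity scores.

The per-tumor OP1 similarity score (Spearman rho against the OP1 mean
profile) enters a Cox proportional-hazards model as a single continuous
covariate; the partial likelihood is maximised with Efron handling of
tied event times (ties are common in month-resolution data).  A
median-split Kaplan-Meier comparison with a two-group log-rank test
gives the non-parametric view of the same association.

Model fitting is delegated to lifelines (Newton-Raphson on the Efron
partial likelihood); this module owns input validation, the Wald
confidence interval on the log-hazard scale, the per-stage sweep and the
median-split rule (samples exactly at the median go to the "low" group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

from .data import GliomirError, ValidationError
from .lineage import TumorStageCorrelationMatrix

__all__ = [
    "CoxResult",
    "StageCoxTable",
    "KMResult",
    "DegeneratePredictorError",
    "CoxDivergenceError",
    "cox_fit",
    "cox_all_stages",
    "km_median_split",
]


class DegeneratePredictorError(GliomirError):
    """The covariate is constant (or nearly so); no hazard ratio exists."""


class CoxDivergenceError(GliomirError):
    """The partial likelihood is monotone; no finite MLE exists."""


@dataclass
class CoxResult:
    """Cox fit for a single continuous covariate.

    ``hr = exp(beta)``; ``ci95`` is the Wald interval on the hazard-ratio
    scale; ``p`` is the Wald p-value.
    """

    label: str
    beta: float
    se: float
    hr: float
    ci95: tuple
    p: float
    n: int
    n_events: int


@dataclass
class StageCoxTable:
    """One Cox fit per differentiation stage.

    ``table`` is indexed by stage with columns ``beta, se, hr, ci_low,
    ci_high, p, n, n_events, error`` (``error`` holds the message for
    stages whose fit failed; failures are non-fatal for other stages).
    """

    table: pd.DataFrame

    @property
    def best_stage(self) -> str:
        return self.table["hr"].idxmax()

    @property
    def all_significant(self) -> bool:
        p = self.table["p"].dropna()
        return bool(len(p) == len(self.table) and (p < 0.05).all())


@dataclass
class KMResult:
    """Median-split Kaplan-Meier comparison."""

    groups: pd.Series
    curves: dict
    logrank_chi2: float
    logrank_p: float
    split_value: float


def _aligned(covariate: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"}.issubset(survival.columns):
        raise ValidationError("survival table needs 'time' and 'event' columns")
    idx = covariate.index.intersection(survival.index)
    if len(idx) == 0:
        raise ValidationError("covariate and survival share no sample ids")
    df = pd.DataFrame(
        {
            "x": covariate.loc[idx].astype(float),
            "time": survival.loc[idx, "time"].astype(float),
            "event": survival.loc[idx, "event"].astype(bool),
        }
    )
    if df.isna().any().any():
        raise ValidationError("missing values after aligning covariate and survival")
    if (df["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    return df


def cox_fit(covariate: pd.Series, survival: pd.DataFrame, label: str = "rho") -> CoxResult:
    """Cox proportional-hazards fit of survival on one continuous covariate.

    ``survival`` is indexed by sample id with columns ``time`` (months)
    and ``event`` (True = death observed).  Requires >= 2 events and a
    non-constant covariate.
    """
    df = _aligned(covariate, survival)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValidationError(f"need >=2 events, got {n_events}")
    if np.isclose(df["x"].std(ddof=0), 0.0):
        raise DegeneratePredictorError(f"covariate {label!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise CoxDivergenceError(
            f"Cox fit for {label!r} did not converge (likely monotone "
            f"likelihood / complete separation): {err}"
        ) from err
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 50:
        raise CoxDivergenceError(
            f"Cox fit for {label!r} diverged (beta={beta:.3g}, se={se:.3g})"
        )
    zcrit = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return CoxResult(
        label=label,
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - zcrit * se)), float(np.exp(beta + zcrit * se))),
        p=float(p),
        n=int(len(df)),
        n_events=n_events,
    )


def cox_all_stages(matrix: TumorStageCorrelationMatrix, survival: pd.DataFrame) -> StageCoxTable:
    """One Cox fit per stage-similarity column; errors per stage are
    recorded, not raised."""
    rows = []
    for stage in matrix.rho.columns:
        try:
            r = cox_fit(matrix.rho[stage], survival, label=stage)
            rows.append(
                (stage, r.beta, r.se, r.hr, r.ci95[0], r.ci95[1], r.p, r.n, r.n_events, None)
            )
        except GliomirError as err:
            rows.append(
                (stage, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0, str(err))
            )
    table = pd.DataFrame(
        rows,
        columns=["stage", "beta", "se", "hr", "ci_low", "ci_high", "p", "n", "n_events", "error"],
    ).set_index("stage")
    return StageCoxTable(table=table)


def km_median_split(covariate: pd.Series, survival: pd.DataFrame) -> KMResult:
    """Kaplan-Meier curves and log-rank test for samples above vs at-or-below
    the median covariate value."""
    df = _aligned(covariate, survival)
    med = float(df["x"].median())
    low = df["x"] <= med
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValidationError("need >=2 samples on each side of the median")
    groups = pd.Series(np.where(low, "low", "high"), index=df.index, name="group")
    curves = {}
    for name, mask in (("low", low), ("high", ~low)):
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"], label=name)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf[name].to_numpy()}
        )
    lr = logrank_test(
        df.loc[low, "time"], df.loc[~low, "time"],
        event_observed_A=df.loc[low, "event"], event_observed_B=df.loc[~low, "event"],
    )
    return KMResult(
        groups=groups,
        curves=curves,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        split_value=med,
    )
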