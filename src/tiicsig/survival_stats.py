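"""Kaplan–Meier estimation, log-rank tests, Cox models and the PH check.

Backed by lifelines (Efron tie handling, Wald intervals on the log-HR
scale); the unit tests hold these routines to hand-coded product-limit /
partial-likelihood oracles. The proportional-hazards check interacts the
covariate with analysis time via episode-splitting at event times,
mirroring a cross-product term of survival time and the covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DegenerateDataError, FitError


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise DegenerateDataError("no subjects")
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise DegenerateDataError("survival times must be positive and finite")
    return times


@dataclass
class KaplanMeierEstimate:
    """Right-continuous product-limit estimate with S(0) = 1."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


def kaplan_meier(times, events) -> KaplanMeierEstimate:
    times = _validate_times(times)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KaplanMeierEstimate(times=t[keep], survival=s[keep])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Mantel–Cox log-rank chi-square (df=1) and two-sided p."""
    ta, tb = _validate_times(times_a), _validate_times(times_b)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    adjustment: str = "univariate",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit(s) returning HR, Wald CI95 and p.

    ``adjustment="univariate"`` fits one model per covariate;
    ``"multivariable"`` fits them jointly. Zero-variance covariates and
    non-convergence raise explicit errors naming the covariate.
    """
    if adjustment not in ("univariate", "multivariable"):
        raise ValueError(f"unknown adjustment '{adjustment}'")
    _validate_times(data[time_col].to_numpy())
    if data[covariates].isna().any().any():
        raise DegenerateDataError("missing covariate values; drop or impute upstream")
    for c in covariates:
        if np.ptp(data[c].to_numpy(dtype=float)) == 0:
            raise DegenerateDataError(f"covariate '{c}' has zero variance")
    n_events = int(data[event_col].sum())
    if adjustment == "multivariable" and n_events < len(covariates) + 1:
        raise DegenerateDataError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )

    groups = [[c] for c in covariates] if adjustment == "univariate" else [covariates]
    rows = []
    for cols in groups:
        cph = CoxPHFitter()
        sub = data[[time_col, event_col, *cols]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(sub, duration_col=time_col, event_col=event_col)
        except (ConvergenceError, ValueError) as exc:
            raise FitError(f"Cox fit failed for {cols}: {exc}") from exc
        summ = cph.summary
        if not np.all(np.isfinite(summ["coef"])):
            raise FitError(f"non-finite Cox estimate for {cols}")
        for c in cols:
            r = summ.loc[c]
            rows.append({
                "covariate": c,
                "adjustment": adjustment,
                "coef": float(r["coef"]),
                "hr": float(np.exp(r["coef"])),
                "ci_lo": float(np.exp(r["coef"] - 1.959963984540054 * r["se(coef)"])),
                "ci_hi": float(np.exp(r["coef"] + 1.959963984540054 * r["se(coef)"])),
                "p": float(r["p"]),
                "n_events": n_events,
            })
    return pd.DataFrame(rows).set_index("covariate")


def _episode_split(data: pd.DataFrame, covariate: str, time_col: str, event_col: str) -> pd.DataFrame:
    """Split each subject's follow-up at the distinct event times."""
    cuts = np.unique(data.loc[data[event_col].astype(bool), time_col].to_numpy(dtype=float))
    rows = []
    for sid, (t, e, x) in enumerate(
        zip(data[time_col].to_numpy(dtype=float),
            data[event_col].to_numpy(dtype=bool),
            data[covariate].to_numpy(dtype=float))
    ):
        inner = cuts[cuts < t]
        starts = np.concatenate([[0.0], inner])
        stops = np.concatenate([inner, [t]])
        for k, (a, b) in enumerate(zip(starts, stops)):
            rows.append({
                "id": sid, "start": a, "stop": b,
                "event": bool(e) and k == len(starts) - 1,
                covariate: x,
            })
    return pd.DataFrame(rows)


def ph_check(
    data: pd.DataFrame,
    covariate: str,
    time_col: str = "time",
    event_col: str = "event",
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Proportional-hazards check via a covariate × time interaction.

    Returns the Wald p-value of the interaction term and a flag that is
    True when the PH assumption is tenable (p > alpha).
    """
    if np.ptp(data[covariate].to_numpy(dtype=float)) == 0:
        raise DegenerateDataError(f"covariate '{covariate}' has zero variance")
    long = _episode_split(data, covariate, time_col, event_col)
    long["xt"] = long[covariate] * long["stop"]
    ctv = CoxTimeVaryingFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(long, id_col="id", start_col="start", stop_col="stop", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        raise FitError(f"PH check failed for '{covariate}': {exc}") from exc
    p = float(ctv.summary.loc["xt", "p"])
    return p, p > alpha
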