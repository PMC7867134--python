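"""Survival stratification: Kaplan–Meier, log-rank, and multivariate Cox.

The Kaplan–Meier product-limit estimator and the two-group log-rank test
(hypergeometric variance) are implemented directly so the per-event-time
tables (n at risk, observed, expected, variance) can be reported.  The
Cox proportional-hazards model is delegated to lifelines' Newton–Raphson
fitter with the Efron tie correction; hazard ratios carry Wald 95%
confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy.stats import chi2

from ilcgate.io_cohort import ClinicalRecord

logger = logging.getLogger(__name__)

COVARIATE_CHOICES = ("age", "sex", "node", "stage", "ilc2")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t_j)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_time(self) -> float:
        """Smallest event time with S(t) ≤ 0.5, or inf if never reached."""
        below = np.where(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk,
            "events": self.events, "survival": self.survival,
        })


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    table: pd.DataFrame  # per event time: n, n1, d, d1, expected1, variance


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate β, HR = exp(β), Wald 95% CI, se, p."""

    table: pd.DataFrame  # index: covariate; columns: coef, hr, hr_lo, hr_hi, se, p
    n: int
    n_events: int
    ties: str = "efron"
    converged: bool = True
    flags: tuple[str, ...] = ()


def _extract(records: Sequence[ClinicalRecord], group: Sequence[int] | np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    group = np.asarray(group, dtype=int)
    if len(records) != group.size:
        raise ValueError("one group label per record required")
    bad = [r.sample_id for r in records if not r.valid_for_survival]
    if bad:
        raise ValueError(f"records not valid for survival: {bad}")
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    return time, event, group


def _km_single(time: np.ndarray, event: np.ndarray, label: str) -> KMCurve:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n_at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for j, t in enumerate(event_times):
        n_at_risk[j] = int(np.sum(time >= t))
        d[j] = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d[j] / n_at_risk[j]
        surv[j] = s
    return KMCurve(label, event_times, n_at_risk, d, surv)


def km_estimate(records: Sequence[ClinicalRecord],
                group: Sequence[int] | np.ndarray,
                labels: tuple[str, str] = ("low", "high")) -> dict[str, KMCurve]:
    """Kaplan–Meier curve per group (group 0 → labels[0], 1 → labels[1])."""
    time, event, grp = _extract(records, group)
    if time.size == 0:
        raise ValueError("no records: every group is empty")
    curves = {}
    for g, name in zip((0, 1), labels):
        mask = grp == g
        if mask.any():
            curves[name] = _km_single(time[mask], event[mask], name)
    return curves


def logrank_test(records: Sequence[ClinicalRecord],
                 group: Sequence[int] | np.ndarray) -> LogRankResult:
    """Two-group log-rank test: χ² = (ΣO₁ − ΣE₁)² / ΣV against 1 df."""
    time, event, grp = _extract(records, group)
    if not (grp == 0).any() or not (grp == 1).any():
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(time[event == 1])
    rows = []
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (grp == 1)).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & (grp == 1)).sum())
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        rows.append((t, n, n1, d, d1, e1, v))
    table = pd.DataFrame(rows, columns=["time", "n", "n1", "d", "d1",
                                        "expected1", "variance"])
    o_minus_e = table["d1"].sum() - table["expected1"].sum()
    var = table["variance"].sum()
    stat = float(o_minus_e ** 2 / var) if var > 0 else 0.0
    p = float(chi2.sf(stat, df=1))
    return LogRankResult(stat, p, table)


def build_design(records: Sequence[ClinicalRecord],
                 ilc2_call: dict[str, int] | None,
                 covariates: Sequence[str]) -> pd.DataFrame:
    """Complete-case design matrix for the Cox model.

    Encodings: age in decades (continuous), sex female=0/male=1,
    node_positive binary, stage ordinal 1–4, ilc2 binary gate call.
    Rows with any missing requested covariate are dropped.
    """
    unknown = set(covariates) - set(COVARIATE_CHOICES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    rows = []
    for r in records:
        if not r.valid_for_survival:
            continue
        row: dict[str, float] = {"time": r.time, "event": r.event}
        ok = True
        for cov in covariates:
            if cov == "age":
                val = None if r.age is None else r.age / 10.0
            elif cov == "sex":
                val = None if r.sex is None else float(r.sex == "male")
            elif cov == "node":
                val = None if r.node_positive is None else float(r.node_positive)
            elif cov == "stage":
                val = None if r.stage is None else float(r.stage)
            else:  # ilc2
                val = None if (ilc2_call is None or r.sample_id not in ilc2_call) \
                    else float(ilc2_call[r.sample_id])
            if val is None:
                ok = False
                break
            row[cov] = val
        if ok:
            rows.append(row)
    return pd.DataFrame(rows, columns=["time", "event", *covariates])


def cox_fit(design: pd.DataFrame, max_iter: int = 100) -> CoxFit:
    """Cox proportional hazards on a (time, event, covariates) frame."""
    covs = [c for c in design.columns if c not in ("time", "event")]
    if not covs:
        raise ValueError("no covariates in design")
    n = len(design)
    n_events = int(design["event"].sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    flags: list[str] = []
    if n < 10 * len(covs):
        flags.append(f"only {n} complete cases for {len(covs)} covariates")
        logger.warning("Cox fit: %s", flags[-1])
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph.fit(design, duration_col="time", event_col="event",
                        fit_options={"max_steps": max_iter})
            for wmsg in caught:
                if issubclass(wmsg.category, ConvergenceWarning):
                    flags.append(str(wmsg.message))
        except ConvergenceError as err:
            raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summary = cph.summary
    table = pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "hr_lo": summary["exp(coef) lower 95%"],
        "hr_hi": summary["exp(coef) upper 95%"],
        "se": summary["se(coef)"],
        "p": summary["p"],
    })
    table.index.name = "covariate"
    return CoxFit(table, n, n_events, ties="efron", converged=converged,
                  flags=tuple(flags))


def survival_report(records: Sequence[ClinicalRecord],
                    ilc2_call: dict[str, int],
                    covariates: Sequence[str] = COVARIATE_CHOICES) -> dict:
    """KM tables, log-rank, and Cox table as one JSON-serialisable dict."""
    valid = [r for r in records if r.valid_for_survival]
    group = np.array([ilc2_call.get(r.sample_id, 0) for r in valid], dtype=int)
    out: dict = {
        "n_records": len(records),
        "n_valid_survival": len(valid),
        "n_ilc2_high": int(group.sum()),
    }
    if group.any() and not group.all():
        curves = km_estimate(valid, group, labels=("ilc2_low", "ilc2_high"))
        out["km"] = {name: c.to_frame().to_dict(orient="list")
                     for name, c in curves.items()}
        out["km_median"] = {name: c.median_time for name, c in curves.items()}
        lr = logrank_test(valid, group)
        out["logrank"] = {"statistic": lr.statistic, "p_value": lr.p_value}
    else:
        out["km"] = {}
        out["logrank"] = None
        logger.warning("one gate group is empty; skipping KM/log-rank")
    design = build_design(valid, ilc2_call, covariates)
    constant = [c for c in covariates if design[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariates from Cox design: %s",
                       constant)
        design = design.drop(columns=constant)
    kept = [c for c in covariates if c not in constant]
    if len(design) >= 3 and design["event"].sum() >= 1 and kept:
        fit = cox_fit(design)
        out["cox"] = {
            "ties": fit.ties,
            "n": fit.n,
            "n_events": fit.n_events,
            "flags": list(fit.flags),
            "table": fit.table.reset_index().to_dict(orient="records"),
        }
    else:
        out["cox"] = None
        logger.warning("Cox model skipped: degenerate design")
    return out
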