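"""Survival analysis: Kaplan-Meier, Cox PH, backward stepwise LR selection,
and SPSS-style case-processing summaries for two endpoints.

Endpoints
---------
``overall``          any death is an event.
``cause_specific``   only breast-cancer deaths are events; deaths from other
                     causes are censored at the death time.

The model object :class:`CoxBackwardStepwise` follows the usual
model/results split: build it from a cohort table, call :meth:`fit`, and
read the selection trace and final model from the returned
:class:`CoxStepwiseResults`.

The stepwise procedure is the classical SPSS "backward: LR" loop: starting
from the full Cox model, each step computes for every covariate the
likelihood-ratio p-value of removing it (chi-square with 1 df on twice the
drop in log partial likelihood); the covariate with the largest p is removed
if that p exceeds the removal threshold, and the loop stops when every
remaining covariate is below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from ._coxlib import cox_loglike, fit_cox

__all__ = [
    "ENDPOINTS",
    "endpoint_events",
    "km_estimate",
    "CoxFitResult",
    "cox_fit",
    "StepwiseStep",
    "StepwiseTrace",
    "backward_stepwise_lr",
    "CoxBackwardStepwise",
    "CoxStepwiseResults",
    "CaseProcessingSummary",
    "case_processing_summary",
    "round_half_up",
    "format_percent",
]

ENDPOINTS = ("overall", "cause_specific")
BREAST_CANCER = "breast_cancer"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of classical stats reports)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, decimals: int = 1) -> str:
    """Report-style percent string: 0.4 -> '.4%', 33.2 -> '33.2%'."""
    r = round_half_up(x, decimals)
    s = f"{r:.{decimals}f}"
    if 0 < r < 1:
        s = s.lstrip("0")
    return s + "%"


def endpoint_events(
    df: pd.DataFrame,
    endpoint: str = "overall",
    event_col: str = "event",
    cause_col: str = "cause",
) -> pd.Series:
    """Event indicator for the requested endpoint.

    For the cause-specific endpoint, deaths from other causes become
    censored observations at the death time.
    """
    if endpoint == "overall":
        return df[event_col].astype(int)
    if endpoint == "cause_specific":
        if cause_col not in df.columns:
            raise ValueError(f"cause-specific endpoint needs a {cause_col!r} column")
        return ((df[event_col].astype(int) == 1) & (df[cause_col] == BREAST_CANCER)).astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(durations, events=None) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and ``survival``. Censored
    observations at t leave the risk set after t.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(durations, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    e = np.ones_like(t) if events is None else np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "events": tab["observed"].to_numpy(dtype=int),
            "censored": tab["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        }
    )
    # lifelines inserts a t=0 anchor row; keep it only if data contain t=0
    if 0.0 not in t and len(out) and out.loc[0, "time"] == 0.0 and out.loc[0, "events"] == 0 and out.loc[0, "censored"] == 0:
        out = out.iloc[1:].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFitResult:
    """A fitted Cox model plus per-covariate LR-removal tests."""

    covariates: list[str]
    params: pd.Series
    bse: pd.Series
    llf: float
    llf_null: float
    lr_pvalues: pd.Series  # p of the LR test removing each covariate
    n: int
    n_events: int
    ties: str

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.bse,
                "HR": self.hazard_ratios,
                "lr_p": self.lr_pvalues,
            }
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        head = (f"<CoxFitResult n={self.n} events={self.n_events} ties={self.ties} "
                f"llf={self.llf:.3f}>")
        return head + "\n" + self.summary().to_string()


def _prepare(df, covariates, duration_col, event_col):
    cols = list(covariates) + [duration_col, event_col]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    data = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if int(data[event_col].sum()) < 2:
        raise ValueError(
            f"need at least 2 events after listwise deletion, found {int(data[event_col].sum())}"
        )
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant on the analysed cases")
    return data


def _fit_llf(data, covariates, duration_col, event_col, ties, start=None):
    """(fit or None, llf) for a covariate subset; llf at beta=0 if empty."""
    t = data[duration_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=int)
    if not covariates:
        # the null partial likelihood does not depend on the covariates
        llf0 = cox_loglike(np.zeros(1), t, e, np.zeros((len(t), 1)), ties=ties)
        return None, float(llf0)
    X = data[list(covariates)].to_numpy(dtype=float)
    fit = fit_cox(t, e, X, ties=ties, start_params=start)
    return fit, fit.llf


def cox_fit(
    df: pd.DataFrame,
    covariates,
    duration_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
    compute_lr: bool = True,
) -> CoxFitResult:
    """Fit a Cox proportional-hazards model with listwise deletion.

    ``ties`` is ``"breslow"`` (default) or ``"efron"``. When ``compute_lr``
    is set, the per-covariate likelihood-ratio removal p-values (1-df
    chi-square on twice the log-likelihood drop) are included.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    data = _prepare(df, covariates, duration_col, event_col)
    fit, llf = _fit_llf(data, covariates, duration_col, event_col, ties)
    _, llf_null = _fit_llf(data, [], duration_col, event_col, ties)
    lr_p = pd.Series(np.nan, index=covariates, dtype=float)
    if compute_lr:
        for i, c in enumerate(covariates):
            rest = [x for x in covariates if x != c]
            start = np.delete(fit.params, i) if rest else None
            _, llf_red = _fit_llf(data, rest, duration_col, event_col, ties, start=start)
            lr = max(2.0 * (llf - llf_red), 0.0)
            lr_p[c] = float(stats.chi2.sf(lr, df=1))
    return CoxFitResult(
        covariates=covariates,
        params=pd.Series(np.asarray(fit.params, dtype=float), index=covariates),
        bse=pd.Series(np.asarray(fit.bse, dtype=float), index=covariates),
        llf=llf,
        llf_null=llf_null,
        lr_pvalues=lr_p,
        n=len(data),
        n_events=int(data[event_col].sum()),
        ties=ties,
    )


# ---------------------------------------------------------------------------
# backward stepwise LR selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseStep:
    index: int  # 1-based step number
    pvalues: dict[str, float]  # LR removal p for every covariate in the model
    removed: str | None  # covariate removed after this step (None at the stop)


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    @property
    def final_covariates(self) -> list[str]:
        if not self.steps:
            return []
        last = self.steps[-1]
        remaining = [c for c in last.pvalues if c != last.removed]
        return remaining

    @property
    def removed_sequence(self) -> list[str]:
        return [s.removed for s in self.steps if s.removed is not None]

    def to_frame(self) -> pd.DataFrame:
        """Long table mirroring the report layout: step, covariate, significance."""
        rows = [
            {"step": s.index, "covariate": c, "significance": p, "removed": int(c == s.removed)}
            for s in self.steps
            for c, p in s.pvalues.items()
        ]
        return pd.DataFrame(rows, columns=["step", "covariate", "significance", "removed"])


class StepwiseError(RuntimeError):
    pass


def backward_stepwise_lr(
    df: pd.DataFrame,
    covariates,
    p_remove: float = 0.10,
    duration_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
) -> StepwiseTrace:
    """Backward stepwise Cox selection by likelihood-ratio tests.

    Start from the full model; at each step remove the covariate with the
    largest LR removal p-value if it exceeds ``p_remove``; stop when every
    remaining p is at or below the threshold (or nothing is left). The
    analysed case set is fixed by listwise deletion on the *full* covariate
    list before the first step.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    try:
        data = _prepare(df, covariates, duration_col, event_col)
    except ValueError as exc:
        raise StepwiseError(f"step 1 (covariates {covariates}): {exc}") from exc
    current = list(covariates)
    trace = StepwiseTrace()
    step_no = 1
    while current:
        try:
            fit, llf = _fit_llf(data, current, duration_col, event_col, ties)
            pvals: dict[str, float] = {}
            for i, c in enumerate(current):
                rest = [x for x in current if x != c]
                start = np.delete(fit.params, i) if rest else None
                _, llf_red = _fit_llf(data, rest, duration_col, event_col, ties, start=start)
                lr = max(2.0 * (llf - llf_red), 0.0)
                pvals[c] = float(stats.chi2.sf(lr, df=1))
        except Exception as exc:  # propagate with the offending step identified
            raise StepwiseError(f"step {step_no} (covariates {current}): {exc}") from exc
        worst = max(current, key=lambda c: pvals[c])
        if pvals[worst] > p_remove:
            trace.steps.append(StepwiseStep(index=step_no, pvalues=pvals, removed=worst))
            current.remove(worst)
            step_no += 1
        else:
            trace.steps.append(StepwiseStep(index=step_no, pvalues=pvals, removed=None))
            break
    return trace


class CoxBackwardStepwise:
    """Backward stepwise Cox model for a cohort table.

    Parameters
    ----------
    data : DataFrame
        One row per case with duration, event (and optionally cause) columns
        plus the candidate covariates.
    covariates : list of str
        The candidate covariate menu for selection.
    endpoint : {"overall", "cause_specific"}
        Which event definition to analyse; cause-specific treats deaths from
        other causes as censored.
    ties : {"breslow", "efron"}
        Tie-handling of the partial likelihood.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates,
        duration_col: str = "time_months",
        event_col: str = "event",
        cause_col: str = "cause",
        endpoint: str = "overall",
        ties: str = "breslow",
    ):
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
        self.data = data
        self.covariates = list(covariates)
        self.duration_col = duration_col
        self.event_col = event_col
        self.cause_col = cause_col
        self.endpoint = endpoint
        self.ties = ties

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, covariates, endpoint: str = "overall", **kw):
        return cls(cohort, covariates, endpoint=endpoint, **kw)

    def _frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df["_event"] = endpoint_events(df, self.endpoint, self.event_col, self.cause_col)
        return df

    def fit(self, p_remove: float = 0.10) -> "CoxStepwiseResults":
        df = self._frame()
        trace = backward_stepwise_lr(
            df, self.covariates, p_remove=p_remove,
            duration_col=self.duration_col, event_col="_event", ties=self.ties,
        )
        final = None
        if trace.final_covariates:
            final = cox_fit(
                df, trace.final_covariates,
                duration_col=self.duration_col, event_col="_event", ties=self.ties,
            )
        return CoxStepwiseResults(model=self, trace=trace, final=final, p_remove=p_remove)

    def case_processing(self) -> "CaseProcessingSummary":
        return case_processing_summary(
            self.data, endpoint=self.endpoint, covariates=self.covariates,
            duration_col=self.duration_col, event_col=self.event_col,
            cause_col=self.cause_col,
        )

    def km(self) -> pd.DataFrame:
        df = self._frame()
        sub = df[[self.duration_col, "_event"]].dropna()
        return km_estimate(sub[self.duration_col], sub["_event"])


@dataclass
class CoxStepwiseResults:
    """Results of a backward stepwise Cox fit: trace + final model."""

    model: CoxBackwardStepwise
    trace: StepwiseTrace
    final: CoxFitResult | None
    p_remove: float

    @property
    def retained(self) -> list[str]:
        return self.trace.final_covariates

    def summary(self) -> str:
        lines = [
            f"Cox regression, backward stepwise (likelihood ratio), "
            f"endpoint={self.model.endpoint}, removal threshold p > {self.p_remove}",
        ]
        for s in self.trace.steps:
            lines.append(f"Step {s.index}:")
            for c, p in s.pvalues.items():
                mark = "  -> removed" if c == s.removed else ""
                lines.append(f"    {c:<12s} significance {p:6.3f}{mark}")
        if self.final is not None:
            lines.append("Final model:")
            lines.append(self.final.summary().to_string())
        else:
            lines.append("Final model: empty (every covariate was removed)")
        return "\n".join(lines)

    def plot_km(self, ax=None):  # pragma: no cover - plotting convenience
        import matplotlib.pyplot as plt

        km = self.model.km()
        if ax is None:
            _, ax = plt.subplots()
        ax.step(np.r_[0.0, km["time"]], np.r_[1.0, km["survival"]], where="post")
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"Kaplan-Meier ({self.model.endpoint})")
        return ax


# ---------------------------------------------------------------------------
# case-processing summary
# ---------------------------------------------------------------------------


@dataclass
class CaseProcessingSummary:
    """SPSS-style case-processing counts for one endpoint.

    ``n_early_censored`` are complete cases censored before the earliest
    event time in their stratum (a single stratum by default) — excluded
    from analysis alongside the missing-value cases.
    """

    n_events: int
    n_censored: int
    n_missing: int
    n_early_censored: int = 0

    @property
    def n_available(self) -> int:
        return self.n_events + self.n_censored

    @property
    def n_unused(self) -> int:
        return self.n_missing + self.n_early_censored

    @property
    def n_total(self) -> int:
        return self.n_available + self.n_unused

    @classmethod
    def from_counts(cls, n_events, n_censored, n_missing, n_early_censored=0):
        return cls(int(n_events), int(n_censored), int(n_missing), int(n_early_censored))

    def percent(self, count: int) -> float:
        return round_half_up(100.0 * count / self.n_total, 1)

    def to_frame(self, formatted: bool = True) -> pd.DataFrame:
        rows = [
            ("Cases available for analysis", "Event", self.n_events),
            ("Cases available for analysis", "Censored", self.n_censored),
            ("Cases available for analysis", "Total", self.n_available),
            ("Unused cases", "Cases with missing values", self.n_missing),
            ("Unused cases", "Censored cases prior to earliest event in one layer",
             self.n_early_censored),
            ("Unused cases", "Total", self.n_unused),
            ("Total", "", self.n_total),
        ]
        df = pd.DataFrame(rows, columns=["class", "subclass", "N"])
        pct = [100.0 * n / self.n_total for n in df["N"]]
        if formatted:
            df["percent"] = [format_percent(p) for p in pct]
        else:
            df["percent"] = [round_half_up(p, 1) for p in pct]
        return df


def case_processing_summary(
    df: pd.DataFrame,
    endpoint: str = "overall",
    covariates=(),
    duration_col: str = "time_months",
    event_col: str = "event",
    cause_col: str = "cause",
) -> CaseProcessingSummary:
    """Classify every case as event / censored / unused for one endpoint.

    A case is *unused* when any required covariate is missing (listwise
    deletion) or when it is censored before the earliest event time among
    the complete cases (the classical exclusion from the risk sets).
    """
    if df.empty:
        raise ValueError("empty cohort")
    ev = endpoint_events(df, endpoint, event_col, cause_col)
    cols = [c for c in covariates if c in df.columns]
    missing_cols = [c for c in covariates if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks covariates: {missing_cols}")
    if cols:
        num = df[cols].apply(pd.to_numeric, errors="coerce")
        is_missing = num.isna().any(axis=1) | df[duration_col].isna()
    else:
        is_missing = df[duration_col].isna()
    complete = df[~is_missing]
    ev_c = ev[~is_missing]
    t = complete[duration_col].astype(float)
    event_times = t[ev_c == 1]
    earliest = event_times.min() if len(event_times) else np.inf
    early = (ev_c == 0) & (t < earliest)
    return CaseProcessingSummary(
        n_events=int((ev_c == 1).sum()),
        n_censored=int(((ev_c == 0) & ~early).sum()),
        n_missing=int(is_missing.sum()),
        n_early_censored=int(early.sum()),
    )
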