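"""Severity stratification and the trauma dose-response regression.

Children are stratified into four ordinal severity states by the number of
endorsed items on a 14-item functional-impairment checklist (IOS): state
Q1 = 0 items, Q2 = 1-2, Q3 = 3-4, Q4 = 5 or more. The dose-response of
severity on the count of confirmed trauma types is estimated with a
proportional-odds (cumulative logit) regression adjusted for age and sex;
its exponentiated trauma coefficient — the odds ratio of occupying a more
severe state per additional trauma type — is the key input the policy
scenarios consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ChildRecord

__all__ = ["CONDITIONS", "STATE_LABELS", "IOS_BINS", "assign_state",
           "PrevalenceTable", "tabulate_prevalence", "TraumaEffect",
           "fit_cumulative_logit", "EstimationError"]

CONDITIONS = ("ptsd", "depression", "anxiety", "adhd")
STATE_LABELS = ("Q1", "Q2", "Q3", "Q4")
#: Inclusive IOS item-count bins per state (14 items total).
IOS_BINS = ((0, 0), (1, 2), (3, 4), (5, 14))


class EstimationError(RuntimeError):
    """Raised when the proportional-odds fit fails or the data are degenerate."""


def assign_state(ios_count: int) -> int:
    """Map an IOS item count to its 0-based severity state.

    0 -> Q1; 1-2 -> Q2; 3-4 -> Q3; >=5 -> Q4.
    """
    if ios_count < 0:
        raise ValueError(f"ios_count must be non-negative, got {ios_count}")
    if ios_count == 0:
        return 0
    if ios_count <= 2:
        return 1
    if ios_count <= 4:
        return 2
    return 3


@dataclass
class PrevalenceTable:
    """State-conditional diagnosis prevalence with full-sample margins.

    ``counts``/``proportions`` are condition x (Q1..Q4, full) frames;
    proportions are held at full precision, with :meth:`to_report_frame`
    applying the 2-decimal percentage rounding used in report output.
    Cells in empty strata are NaN (flagged, never zero-filled).
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    state_n: pd.Series

    def to_report_frame(self) -> pd.DataFrame:
        rep = (self.proportions * 100).round(2)
        out = pd.concat({"n": self.counts, "pct": rep}, axis=1)
        return out.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)

    def by_state(self, condition: str) -> np.ndarray:
        """P(condition | state) over the four living states."""
        return self.proportions.loc[condition, list(STATE_LABELS)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.to_report_frame().to_csv(path)


def tabulate_prevalence(cohort: Sequence["ChildRecord"]) -> PrevalenceTable:
    """Per-state and full-sample counts and prevalence of the four diagnoses."""
    from .cohort import cohort_to_frame

    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    df = cohort_to_frame(cohort)
    cols = list(STATE_LABELS) + ["full"]
    counts = pd.DataFrame(index=list(CONDITIONS), columns=cols, dtype=float)
    state_n = pd.Series(
        [int((df["state"] == s).sum()) for s in range(4)] + [len(df)], index=cols
    )
    for cond in CONDITIONS:
        for s, lab in enumerate(STATE_LABELS):
            counts.loc[cond, lab] = df.loc[df["state"] == s, cond].sum()
        counts.loc[cond, "full"] = df[cond].sum()
    denom = state_n.astype(float).where(state_n > 0)  # empty stratum -> NaN
    proportions = counts.div(denom, axis=1)
    return PrevalenceTable(counts=counts.astype(int), proportions=proportions, state_n=state_n)


@dataclass
class TraumaEffect:
    """Per-trauma-type odds ratio with Wald 95% CI from the adjusted fit."""

    or_point: float
    or_low: float
    or_high: float
    covariates: tuple[str, ...] = ("age", "sex")
    coefficients: dict = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.or_low <= self.or_point <= self.or_high):
            raise ValueError(
                f"require 0 < or_low <= or_point <= or_high, got "
                f"({self.or_low}, {self.or_point}, {self.or_high})"
            )

    def to_json_dict(self) -> dict:
        return {"or": self.or_point, "ci_low": self.or_low, "ci_high": self.or_high,
                "n": self.n}


def fit_cumulative_logit(cohort: Sequence["ChildRecord"]) -> TraumaEffect:
    """Proportional-odds ML fit of severity state on trauma count, age and sex.

    The model is parameterized so that an odds ratio above 1 means higher
    odds of a MORE severe state per additional trauma type (cumulative
    probabilities P(state <= k) are modelled internally; the linear
    predictor enters with a positive sign toward severity). Sex is coded
    male = 1. Records with any missing model variable are dropped listwise.
    Returns the exponentiated trauma coefficient with its Wald 95% CI.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    from .cohort import cohort_to_frame

    df = cohort_to_frame(cohort).dropna(subset=["state", "trauma_count", "age", "sex"])
    if df["state"].nunique() < 2:
        raise ValueError("need at least 2 occupied severity states to fit")
    if df["trauma_count"].nunique() < 2:
        raise EstimationError("trauma_count is constant; effect not identifiable")
    exog = pd.DataFrame({
        "trauma_count": df["trauma_count"].astype(float),
        "age": df["age"].astype(float),
        "male": (df["sex"] == "male").astype(float),
    })
    # OrderedModel: P(y <= k) = logistic(threshold_k - x.beta), so beta > 0
    # shifts mass toward more severe states — the direction we report.
    model = OrderedModel(df["state"].astype(int), exog, distr="logit")
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            # bfgs is run past its formal gtol for a sharp optimum; the
            # resulting "failed to converge" warning is spurious, so
            # convergence is checked directly on the score below
            _warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", disp=False, maxiter=500, gtol=1e-10)
        score = np.asarray(model.score(res.params))
        if np.abs(score).max() > 1e-4 * max(len(df), 100):
            res = model.fit(method="newton", disp=False, start_params=res.params,
                            tol=1e-10, maxiter=50)
    except Exception as exc:  # separation / singular Hessian
        raise EstimationError(f"proportional-odds fit failed: {exc}") from exc
    beta = float(res.params["trauma_count"])
    se = float(res.bse["trauma_count"])
    if not np.isfinite(beta) or not np.isfinite(se):
        raise EstimationError("non-finite estimate or standard error (degenerate data)")
    z = norm.ppf(0.975)
    return TraumaEffect(
        or_point=float(np.exp(beta)),
        or_low=float(np.exp(beta - z * se)),
        or_high=float(np.exp(beta + z * se)),
        coefficients={k: float(v) for k, v in res.params.items()},
        n=len(df),
    )
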