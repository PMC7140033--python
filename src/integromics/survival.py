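"""Median-split marker survival analysis.

The marker (e.g. a miRNA's expression) splits the cohort at its median into
High (> median) and Low (<= median; ties go Low) groups. Group curves come
from the Kaplan-Meier product-limit estimator, the group contrast from the
two-group log-rank test, and the adjusted effect from a multivariate Cox
proportional-hazards model (marker group with High as reference, age per
year, tumor stage as indicators against stage I), maximized by Newton
iterations on the partial likelihood with the Efron approximation for tied
event times (Breslow available via ``ties``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from sklearn.base import BaseEstimator

from .model import SurvivalRecord, survival_records_to_frame


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return survival_records_to_frame(list(records))


def median_split(records) -> pd.Series:
    """Label each record High (marker > median) or Low (marker <= median)."""
    frame = _as_frame(records)
    if len(frame) < 2:
        raise ValueError("need at least 2 records to split")
    marker = frame["marker"].to_numpy(dtype=float)
    if np.ptp(marker) == 0:
        raise ValueError("all marker values are equal; no median split possible")
    median = float(np.median(marker))
    labels = np.where(marker > median, "High", "Low")
    return pd.Series(labels, index=frame.index, name="marker_group")


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    event_times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    median: float | None  # first time S <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(records, groups=None) -> dict[str, KMCurve]:
    """Kaplan-Meier curves, one per group (a single 'all' group if none).

    S(t) = prod_{t_i <= t} (1 - d_i / n_i); the median survival is the first
    event time where S drops to 0.5 or below, undefined (None) when the
    curve never reaches it.
    """
    frame = _as_frame(records)
    if groups is None:
        groups = pd.Series("all", index=frame.index)
    groups = pd.Series(groups, index=frame.index)
    curves: dict[str, KMCurve] = {}
    for label in sorted(groups.unique()):
        sub = frame[groups == label]
        times = sub["time"].to_numpy(dtype=float)
        events = sub["event"].to_numpy(dtype=int)
        order = np.argsort(times, kind="stable")
        times, events = times[order], events[order]
        event_times = np.unique(times[events == 1])
        surv, at_risk = [], []
        s = 1.0
        for t in event_times:
            n_i = int((times >= t).sum())
            d_i = int(((times == t) & (events == 1)).sum())
            s *= 1.0 - d_i / n_i
            surv.append(s)
            at_risk.append(n_i)
        surv = np.array(surv)
        median = None
        reached = np.nonzero(surv <= 0.5)[0]
        if reached.size:
            median = float(event_times[reached[0]])
        curves[label] = KMCurve(
            group=label,
            event_times=event_times,
            survival=surv,
            at_risk=np.array(at_risk),
            median=median,
        )
    return curves


def logrank_test(records, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (O1 - E1)^2 / V, p from chi2(1 df)."""
    frame = _as_frame(records)
    groups = pd.Series(groups, index=frame.index)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {labels}")
    times = frame["time"].to_numpy(dtype=float)
    events = frame["event"].to_numpy(dtype=int)
    in_g1 = (groups == labels[0]).to_numpy()
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        raise ValueError("no events; log-rank statistic undefined")
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in_g1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValueError("zero log-rank variance")
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_design(frame: pd.DataFrame, covariates) -> pd.DataFrame:
    data = pd.DataFrame({"time": frame["time"], "event": frame["event"]})
    for cov in covariates:
        if cov == "marker_group":
            groups = (
                frame["marker_group"]
                if "marker_group" in frame.columns
                else median_split(frame)
            )
            data["marker_Low"] = (pd.Series(groups).to_numpy() == "Low").astype(float)
        elif cov == "age":
            data["age"] = frame["age"].astype(float)
        elif cov == "stage":
            stage = frame["stage"].astype(int)
            for s in (2, 3, 4):
                data[f"stage_{['I','II','III','IV'][s-1]}"] = (stage == s).astype(float)
        else:
            data[cov] = frame[cov].astype(float)
    return data


def cox_ph_fit(
    records,
    covariates=("marker_group", "age", "stage"),
    ties: str = "efron",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit.

    Stage enters as indicator contrasts against stage I and the marker group
    as Low against the High reference, matching the usual presentation of
    such models. Returns a DataFrame indexed by covariate with columns coef,
    HR, ci_low, ci_high, p. Degenerate covariates (no variation) raise, as
    does non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    frame = _as_frame(records)
    if int(frame["event"].sum()) < 1:
        raise ValueError("Cox fit needs at least one event")
    data = _cox_design(frame, covariates)
    exog_cols = [c for c in data.columns if c not in ("time", "event")]
    for col in exog_cols:
        if data[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is degenerate (constant)")
    model = PHReg(
        data["time"].to_numpy(),
        data[exog_cols].to_numpy(),
        status=data["event"].to_numpy(),
        ties=ties,
    )
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            result = model.fit(disp=False)
        convergence_failed = any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    except Exception as exc:
        raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
    coef = np.asarray(result.params, dtype=float)
    se = np.asarray(result.bse, dtype=float)
    if convergence_failed or not (
        np.isfinite(coef).all() and np.isfinite(se).all()
    ):
        raise RuntimeError(
            "Cox partial-likelihood maximization did not converge (possible "
            f"monotone likelihood / perfect separation); coef={coef}, se={se}"
        )
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "coef": coef,
            "HR": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": 2.0 * stats.norm.sf(np.abs(coef) / se),
        },
        index=pd.Index(exog_cols, name="covariate"),
    )


class MedianSplitSurvival(BaseEstimator):
    """Median-split survival analysis as one estimator.

    ``fit`` takes a survival DataFrame (or list of records); fitted
    attributes: ``groups_``, ``km_curves_``, ``logrank_chi2_``,
    ``logrank_p_``, ``cox_``.
    """

    def __init__(self, covariates=("marker_group", "age", "stage"), ties="efron"):
        self.covariates = covariates
        self.ties = ties

    def fit(self, X, y=None):
        frame = _as_frame(X)
        self.groups_ = median_split(frame)
        self.km_curves_ = km_estimator(frame, self.groups_)
        self.logrank_chi2_, self.logrank_p_ = logrank_test(frame, self.groups_)
        frame = frame.assign(marker_group=self.groups_)
        self.cox_ = cox_ph_fit(frame, covariates=self.covariates, ties=self.ties)
        return self
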