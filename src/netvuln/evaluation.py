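"""Biomarker performance: ROC/AUC for group discrimination and
Kaplan-Meier / log-rank survival comparison.

ROC takes a single miRNA's expression as the score with "resistant" as
the positive class (higher expression = more resistant); AUC is the
Mann-Whitney probability ``P(score_R > score_S) + 0.5 P(equal)``, which
equals the trapezoidal area under the threshold-swept curve.

Survival stratifies patients at the upper quartile of expression
(linear-interpolation empirical quantile; "high" strictly above the
threshold), estimates each arm with the Kaplan-Meier product-limit
estimator, and compares arms with the two-group log-rank chi-square
``(O - E)^2 / V`` using the hypergeometric variance at each event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .data_io import validate_groups
from .errors import ParameterError

__all__ = ["ROCResult", "SurvivalFit", "roc_auc", "km_logrank", "km_curve"]


@dataclass
class ROCResult:
    mirna_id: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class SurvivalFit:
    high: pd.DataFrame  # columns: time, at_risk, events, survival
    low: pd.DataFrame
    logrank_chi2: float
    p: float
    split_threshold: float
    n_high: int
    n_low: int


def roc_auc(scores: pd.Series, groups: pd.Series, mirna_id: str = "") -> ROCResult:
    """ROC curve and AUC for one miRNA's expression against the
    sensitive/resistant labels."""
    validate_groups(groups)
    labels = groups.loc[scores.index]
    y = (labels == "resistant").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ParameterError("both classes must be present among the scored samples")
    s = scores.to_numpy(dtype=float)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(mirna_id=mirna_id or str(scores.name), auc=auc, fpr=fpr, tpr=tpr)


def _km_table(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier event table over distinct event times.

    Censored subjects at an event time count as at-risk at that time.
    """
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    event_times = np.unique(times[events == 1])
    rows = []
    surv = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / n_at_risk
        rows.append((float(t), n_at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def km_curve(times, events) -> pd.DataFrame:
    """Public Kaplan-Meier estimate for one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ParameterError("negative survival times")
    return _km_table(t, e)


def _logrank(t1, e1, t2, e2) -> tuple[float, float]:
    """Two-group log-rank chi-square and p (1 df)."""
    all_event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = 0.0  # observed events in group 1
    E = 0.0
    V = 0.0
    for t in all_event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def km_logrank(
    expr: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "PFS",
    quartile: float = 0.75,
) -> SurvivalFit:
    """Upper-quartile expression split followed by KM + log-rank.

    Parameters
    ----------
    expr
        one miRNA's expression per sample.
    clinical
        table with pfs_time/pfs_event/os_time/os_event indexed by sample.
    endpoint
        'PFS' or 'OS'.
    quartile
        quantile (default 0.75) defining the high-expression arm
        (strictly greater than the threshold).
    """
    endpoint = endpoint.upper()
    if endpoint not in ("PFS", "OS"):
        raise ParameterError(f"endpoint must be PFS or OS, got {endpoint!r}")
    if not (0 < quartile < 1):
        raise ParameterError(f"quartile must be in (0,1), got {quartile}")
    common = [s for s in expr.index if s in clinical.index]
    if not common:
        raise ParameterError("no samples shared between expression and clinical table")
    x = expr.loc[common].to_numpy(dtype=float)
    thr = float(np.quantile(x, quartile))  # linear-interpolation (type-7) quantile
    high_mask = x > thr
    n_high = int(high_mask.sum())
    n_low = int((~high_mask).sum())
    if n_high < 2 or n_low < 2:
        raise ParameterError(
            f"expression split at threshold {thr:.4g} leaves a group with <2 samples"
        )
    tcol, ecol = (("pfs_time", "pfs_event") if endpoint == "PFS" else ("os_time", "os_event"))
    times = clinical.loc[common, tcol].to_numpy(dtype=float)
    events = clinical.loc[common, ecol].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ParameterError("no events observed at this endpoint")

    t_hi, e_hi = times[high_mask], events[high_mask]
    t_lo, e_lo = times[~high_mask], events[~high_mask]
    chi2, p = _logrank(t_hi, e_hi, t_lo, e_lo)
    return SurvivalFit(
        high=_km_table(t_hi, e_hi),
        low=_km_table(t_lo, e_lo),
        logrank_chi2=chi2,
        p=p,
        split_threshold=thr,
        n_high=n_high,
        n_low=n_low,
    )
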