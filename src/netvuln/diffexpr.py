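"""Two-group differential expression with empirical-Bayes variance
moderation.

The moderated t statistic shrinks each feature's residual variance toward
a pooled prior estimated by moment matching on log residual variances
(Smyth-style closed form): with per-feature pooled variance s^2 on d
residual degrees of freedom and prior (d0, s0^2),

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod     = log2fc / (s_tilde * sqrt(1/n1 + 1/n2))

and two-sided p-values come from a t distribution on d0 + d degrees of
freedom.  Fold change is 2**(difference of group means of log2 values),
resistant over sensitive.  Significance calls use the conventional
criteria: fold change > fc_hi or < fc_lo (strict) and BH-adjusted
p < alpha (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_io import validate_groups
from .errors import DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["EBayesParams", "moderated_t", "bh_adjust", "filter_de"]


@dataclass(frozen=True)
class EBayesParams:
    """Estimated prior degrees of freedom and prior variance."""

    d0: float  # may be inf
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, d: float) -> EBayesParams:
    """Moment-match log(s^2) to a scaled F model to estimate (d0, s0^2).

    Uses E[log s^2] and Var[log s^2] under s^2 ~ s0^2 * F(d, d0):
    Var = trigamma(d/2) + trigamma(d0/2), so d0 comes from inverting the
    trigamma function; s0^2 follows from the mean equation.  Features with
    zero variance are excluded from estimation.  If the observed variance
    of log s^2 does not exceed trigamma(d/2), d0 is infinite and all
    variances shrink fully to s0^2.
    """
    pos = s_sq[s_sq > 0]
    if pos.size == 0:
        raise DegenerateDataError("all features have zero residual variance")
    e = np.log(pos)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if pos.size > 1 else 0.0
    resid_var = evar - float(special.polygamma(1, d / 2.0))
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0_sq = float(
            np.exp(
                emean
                - special.polygamma(0, d / 2.0)
                + special.polygamma(0, d0 / 2.0)
                - np.log(d0 / d)
            )
        )
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean - special.polygamma(0, d / 2.0) + np.log(d / 2.0)))
        logger.warning("log-variance spread below sampling floor; using d0=inf")
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        raise DegenerateDataError("prior variance estimation failed")
    return EBayesParams(d0=float(d0), s0_sq=s0_sq)


def moderated_t(
    expr: pd.DataFrame,
    groups: pd.Series,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, EBayesParams]:
    """Empirical-Bayes moderated t for every feature.

    Parameters
    ----------
    expr
        features x samples log2 expression.
    groups
        sample -> {'sensitive', 'resistant'}; every column of ``expr``
        must be labeled.
    d0_override
        Force the prior degrees of freedom (0 recovers the ordinary
        pooled-variance t; inf fully shrinks to the prior variance).

    Returns
    -------
    (table, params) where table has columns log2fc, t_mod, df_total, p,
    adj_p indexed by feature, in input order.
    """
    validate_groups(groups)
    missing = [c for c in expr.columns if c not in groups.index]
    if missing:
        raise ParameterError(f"samples without group label: {missing[:5]}")
    labels = groups.loc[expr.columns]
    sens = expr.loc[:, (labels == "sensitive").to_numpy()]
    res = expr.loc[:, (labels == "resistant").to_numpy()]
    n1, n2 = sens.shape[1], res.shape[1]
    if n1 < 2 or n2 < 2:
        raise ParameterError(f"need >=2 samples per group, got {n1} sensitive, {n2} resistant")
    d = float(n1 + n2 - 2)

    x1 = sens.to_numpy(dtype=float)
    x2 = res.to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = m2 - m1  # resistant minus sensitive
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d

    if d0_override is not None:
        if d0_override < 0:
            raise ParameterError("d0_override must be >= 0")
        if d0_override == 0:
            params = EBayesParams(d0=0.0, s0_sq=float(np.median(s_sq[s_sq > 0]))
                                  if (s_sq > 0).any() else 1.0)
        else:
            base = estimate_prior(s_sq, d)
            params = EBayesParams(d0=float(d0_override), s0_sq=base.s0_sq)
    else:
        params = estimate_prior(s_sq, d)

    d0 = params.d0
    if np.isinf(d0):
        s_post = np.full_like(s_sq, params.s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * params.s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    # zero posterior variance with zero difference: t=0, p=1 by convention
    t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
    if np.any((se == 0) & (log2fc != 0)):
        raise DegenerateDataError("zero posterior variance with non-zero difference")

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=expr.index,
    )
    return table, params


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; output order matches input."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must be in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def filter_de(
    de: pd.DataFrame,
    fc_hi: float = 1.5,
    fc_lo: float = 0.67,
    alpha: float = 0.05,
) -> list[str]:
    """Feature IDs passing the fold-change and FDR filters, in input order.

    A feature is differentially expressed iff 2**log2fc > fc_hi or
    2**log2fc < fc_lo, and adj_p < alpha, all strict.
    """
    if not (0 < fc_lo < 1 < fc_hi):
        raise ParameterError("require 0 < fc_lo < 1 < fc_hi")
    fc = np.power(2.0, de["log2fc"].to_numpy(dtype=float))
    keep = ((fc > fc_hi) | (fc < fc_lo)) & (de["adj_p"].to_numpy(dtype=float) < alpha)
    return [str(f) for f, k in zip(de.index, keep) if k]


def add_de_flag(de: pd.DataFrame, fc_hi: float = 1.5, fc_lo: float = 0.67,
                alpha: float = 0.05) -> pd.DataFrame:
    """Return a copy of the DE table with an ``is_de`` boolean column."""
    out = de.copy()
    flagged = set(filter_de(de, fc_hi=fc_hi, fc_lo=fc_lo, alpha=alpha))
    out["is_de"] = [f in flagged for f in de.index]
    return out
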