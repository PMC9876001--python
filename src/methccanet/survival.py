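"""Kaplan-Meier estimation and log-rank screening of key methylation sites.

For each key site, samples are split into high/low methylation at the
median beta and the two groups' survival is compared with the standard
two-sample log-rank test: at every pooled event time the expected events in
group A are ``n_A * d / n`` and the variance follows the hypergeometric
formula; the statistic ``(O_A - E_A)^2 / V`` is chi-square with 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BetaMatrix, ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalFit",
    "LogRankResult",
    "km_estimate",
    "split_by_site",
    "logrank_test",
    "key_site_survival",
]


@dataclass
class SurvivalFit:
    """Product-limit survival estimate for one group."""

    group: str
    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # subjects at risk at each event time
    n_events: np.ndarray  # events at each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(times, events, group: str = "") -> SurvivalFit:
    """Kaplan-Meier product-limit estimator S(t) = prod(1 - d_i/n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    ev_times = np.unique(t[e == 1])
    surv, risks, deaths = [], [], []
    s = 1.0
    for ti in ev_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risks.append(n_i)
        deaths.append(d_i)
    return SurvivalFit(
        group=group,
        event_times=ev_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(risks, dtype=int),
        n_events=np.asarray(deaths, dtype=int),
    )


def split_by_site(beta, quantile: float = 0.5) -> np.ndarray:
    """Label samples "high" (beta above the cut) or "low" (ties go low)."""
    b = np.asarray(beta, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 samples to split")
    if np.all(b == b[0]):
        raise ValueError("constant beta vector: no split possible")
    cut = float(np.quantile(b, quantile))
    return np.where(b > cut, "high", "low")


@dataclass
class LogRankResult:
    """Two-sample log-rank comparison."""

    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, float]  # events in (A, B)
    expected: tuple[float, float]


def logrank_test(
    times_a, events_a, times_b, events_b
) -> LogRankResult:
    """Standard two-sample log-rank test (no continuity correction)."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    is_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    ev_times = np.unique(t_all[e_all == 1])
    if ev_times.size == 0:
        warnings.warn("no events in either group; log-rank is degenerate", stacklevel=2)
        return LogRankResult(0.0, 1, 1.0, (0.0, 0.0), (0.0, 0.0))
    o_a = e_a_exp = var = 0.0
    total_events = 0
    for ti in ev_times:
        at_risk = t_all >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & is_a).sum())
        dead = (t_all == ti) & (e_all == 1)
        d = int(dead.sum())
        d_a = int((dead & is_a).sum())
        o_a += d_a
        e_a_exp += n_a * d / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        total_events += d
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a_exp) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    o_b = total_events - o_a
    e_b = total_events - e_a_exp
    return LogRankResult(
        chi_square=float(chi2),
        df=1,
        p_value=p,
        observed=(float(o_a), float(o_b)),
        expected=(float(e_a_exp), float(e_b)),
    )


def key_site_survival(
    key_sites,
    bm: BetaMatrix,
    clin: ClinicalTable,
    quantile: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split log-rank test for every key site, sorted by p.

    Sites absent from the beta matrix get a missing row with a warning;
    sites flagged at p < ``alpha`` carry ``significant = True``.
    """
    samples = [s for s in bm.sample_ids if s in set(clin.sample_ids)]
    t = clin.table.loc[samples, "time"].to_numpy(dtype=float)
    e = clin.table.loc[samples, "event"].to_numpy(dtype=int)
    rows = []
    for site in key_sites:
        if site not in bm.values.index:
            warnings.warn(f"key site {site!r} absent from beta matrix", stacklevel=2)
            rows.append(
                {"site_id": site, "n_high": np.nan, "n_low": np.nan,
                 "chi_square": np.nan, "p_value": np.nan, "significant": False}
            )
            continue
        b = bm.values.loc[site, samples].to_numpy(dtype=float)
        labels = split_by_site(b, quantile=quantile)
        hi = labels == "high"
        res = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
        rows.append(
            {"site_id": site, "n_high": int(hi.sum()), "n_low": int((~hi).sum()),
             "chi_square": res.chi_square, "p_value": res.p_value,
             "significant": bool(res.p_value < alpha)}
        )
    out = pd.DataFrame(
        rows, columns=["site_id", "n_high", "n_low", "chi_square", "p_value", "significant"]
    )
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
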