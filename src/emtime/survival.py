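"""Kaplan–Meier estimation and log-rank comparison of EMT groups.

Overall survival (OS) and progression-free interval (PFI) are contrasted
between EMT groups per cohort: pairwise high vs low and the three-group
test.  The Kaplan–Meier curve comes from lifelines' product-limit
estimator; the k-sample log-rank statistic is computed here in the
standard Mantel–Haenszel form (hypergeometric variance with ties) so the
result can expose per-group observed and expected event counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test"]


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    event_times: np.ndarray     # ordered distinct event times (days)
    survival_prob: np.ndarray   # S(t) at each event time
    at_risk: np.ndarray         # number at risk just before each event time
    n_total: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: pd.Series   # per-group observed event counts
    expected: pd.Series   # per-group expected event counts under H0


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    ``times`` are durations in days (≥ 0); ``events`` are 1 for an
    observed event, 0 for censoring.  A censored-only input gives S ≡ 1
    (no event times).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if len(t) == 0:
        raise ValueError("need >= 1 subject")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(e, [0.0, 1.0])):
        raise ValueError("event flags must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival_prob=kmf.survival_function_.loc[ev.index,
                                                 "KM_estimate"].to_numpy(),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_total=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(group_times: dict[str, np.ndarray],
                 group_events: dict[str, np.ndarray]) -> LogRankResult:
    """Unweighted k-sample log-rank test (k−1 df).

    At each distinct event time the observed events per group are compared
    with their expectation under the hypergeometric null; ties use the
    standard multivariate hypergeometric variance.  The chi-square drops
    the last group and inverts the (k−1)×(k−1) covariance.  Requires ≥ 2
    groups and ≥ 1 event overall.
    """
    labels = list(group_times)
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if set(labels) != set(group_events):
        raise ValueError("group label mismatch between times and events")
    t_all, e_all, g_all = [], [], []
    for gi, lab in enumerate(labels):
        t = np.asarray(group_times[lab], dtype=float)
        e = np.asarray(group_events[lab], dtype=float)
        if len(t) != len(e):
            raise ValueError(f"group {lab}: time/event length mismatch")
        if np.any(t < 0):
            raise ValueError(f"group {lab}: negative time")
        t_all.append(t)
        e_all.append(e)
        g_all.append(np.full(len(t), gi))
    t = np.concatenate(t_all)
    e = np.concatenate(e_all)
    g = np.concatenate(g_all).astype(int)
    if e.sum() == 0:
        raise ValueError("test undefined: zero events")

    k = len(labels)
    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for tt in event_times:
        at_risk = t >= tt
        n = at_risk.sum()
        d = ((t == tt) & (e == 1)).sum()
        n_g = np.array([np.sum(at_risk & (g == gi)) for gi in range(k)],
                       dtype=float)
        d_g = np.array([np.sum((t == tt) & (e == 1) & (g == gi))
                        for gi in range(k)], dtype=float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            c = d * (n - d) / (n - 1)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(
        chi2=chi2, df=df, p=p,
        observed=pd.Series(O, index=labels, name="observed"),
        expected=pd.Series(E, index=labels, name="expected"),
    )
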