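"""Kaplan-Meier product-limit estimation, life tables, and the log-rank test.

The product-limit estimator is

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over the distinct event times t_i, with d_i events among n_i subjects at
risk.  Its variance is estimated by Greenwood's formula

    Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i * (n_i - d_i))

and confidence intervals are built, by default, on the complementary
log-log scale so they stay inside [0, 1].

Tied event and censoring times follow the standard convention: events
precede censorings, i.e. a subject censored at t is still at risk for an
event at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["KaplanMeier", "KMResults", "LogRankResult", "logrank", "km_strata"]


def _check_surv_input(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or events.ndim != 1 or len(times) != len(events):
        raise ValidationError("times and events must be equal-length 1-d vectors")
    if len(times) == 0:
        raise ValidationError("empty survival input")
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise ValidationError("survival times must be positive and finite")
    ev = events.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValidationError("event indicators must be binary (0=censored, 1=event)")
    return times, ev.astype(int)


class KaplanMeier:
    """Product-limit survival model for one right-censored sample.

    Parameters
    ----------
    times : array-like of positive floats
        Observed follow-up time per subject.
    events : array-like of {0, 1}
        1 if the event was observed at ``times``, 0 if right-censored.
    label : optional hashable
        Carried through to the results, useful for stratified curves.
    """

    def __init__(self, times, events, label=None):
        self.times, self.events = _check_surv_input(times, events)
        self.label = label
        self.n = len(self.times)

    def fit(self, conf_level: float = 0.95, ci_transform: str = "loglog") -> "KMResults":
        if not 0 < conf_level < 1:
            raise ValidationError("conf_level must be in (0, 1)")
        if ci_transform not in ("loglog", "linear"):
            raise ValidationError("ci_transform must be 'loglog' or 'linear'")

        order = np.argsort(self.times, kind="stable")
        t, e = self.times[order], self.events[order]
        event_times = np.unique(t[e == 1])

        m = len(event_times)
        n_at_risk = np.empty(m, dtype=int)
        n_events = np.empty(m, dtype=int)
        n_censored = np.empty(m, dtype=int)
        for i, ti in enumerate(event_times):
            # censorings at exactly ti remain at risk at ti
            n_at_risk[i] = int(np.sum(t >= ti))
            n_events[i] = int(np.sum((t == ti) & (e == 1)))
            upper = event_times[i + 1] if i + 1 < m else np.inf
            n_censored[i] = int(np.sum((t >= ti) & (t < upper) & (e == 0)))

        with np.errstate(divide="ignore", invalid="ignore"):
            frac = 1.0 - n_events / n_at_risk
            survival = np.cumprod(frac)
            gw_terms = n_events / (n_at_risk * (n_at_risk - n_events).astype(float))
            gw_terms[n_at_risk == n_events] = np.inf
            cum_gw = np.cumsum(gw_terms)
            variance = survival**2 * cum_gw
            variance[survival == 0.0] = np.nan
            std_err = np.sqrt(variance)

        z = stats.norm.ppf(0.5 + conf_level / 2)
        lo, hi = self._conf_band(survival, std_err, cum_gw, z, ci_transform)

        return KMResults(
            event_times=event_times,
            n_at_risk=n_at_risk,
            n_events=n_events,
            n_censored=n_censored,
            survival=survival,
            variance=variance,
            std_err=std_err,
            ci_lower=lo,
            ci_upper=hi,
            conf_level=conf_level,
            ci_transform=ci_transform,
            n=self.n,
            total_events=int(self.events.sum()),
            max_time=float(self.times.max()),
            label=self.label,
            input_times=self.times,
        )

    @staticmethod
    def _conf_band(s, se, cum_gw, z, transform):
        with np.errstate(divide="ignore", invalid="ignore"):
            if transform == "linear":
                lo = np.clip(s - z * se, 0.0, 1.0)
                hi = np.clip(s + z * se, 0.0, 1.0)
            else:
                # theta = log(-log S); se(theta) = sqrt(cum_gw)/|log S|
                interior = (s > 0) & (s < 1)
                lo = np.full_like(s, np.nan)
                hi = np.full_like(s, np.nan)
                se_theta = np.sqrt(cum_gw[interior]) / np.abs(np.log(s[interior]))
                lo[interior] = s[interior] ** np.exp(z * se_theta)
                hi[interior] = s[interior] ** np.exp(-z * se_theta)
                lo[s == 1.0] = 1.0
                hi[s == 1.0] = 1.0
        return lo, hi


@dataclass
class KMResults:
    """Fitted product-limit curve with Greenwood uncertainty."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    std_err: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    conf_level: float
    ci_transform: str
    n: int
    total_events: int
    max_time: float
    label: object = None
    input_times: np.ndarray | None = None

    def survival_at(self, t) -> np.ndarray:
        """Step-function value of S at arbitrary times (S=1 before the first event)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.event_times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out

    def at_risk_at(self, t) -> np.ndarray:
        """Number of subjects still under observation at each time in ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.array([int(np.sum(self.input_times >= ti)) for ti in t])

    def life_table(self, with_ci: bool = True) -> pd.DataFrame:
        """Tabular rendering of the curve, one row per distinct event time."""
        cols = {
            "time": self.event_times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "n_censored": self.n_censored,
            "survival": self.survival,
            "std_err": self.std_err,
        }
        if with_ci:
            cols["ci_lower"] = self.ci_lower
            cols["ci_upper"] = self.ci_upper
        return pd.DataFrame(cols)

    def summary(self) -> str:
        head = f"Kaplan-Meier estimate (n={self.n}, events={self.total_events}"
        if self.label is not None:
            head += f", stratum={self.label}"
        head += f", {int(round(self.conf_level * 100))}% CI, {self.ci_transform})"
        return head + "\n" + self.life_table().to_string(index=False, float_format="%.6g")


@dataclass
class LogRankResult:
    """Two-group log-rank test with tie-corrected hypergeometric variance."""

    observed: np.ndarray  # O_g per group
    expected: np.ndarray  # E_g per group
    variance: float
    chi_square: float
    p_value: float
    df: int = 1

    def summary(self) -> str:
        return (
            f"log-rank: O={self.observed.tolist()} E={np.round(self.expected, 4).tolist()} "
            f"chi2={self.chi_square:.4f} (df={self.df}) p={self.p_value:.4g}"
        )


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test over the pooled distinct event times.

    At each pooled event time with d events among n at risk (n_a in group A),
    group A's expected events are d*n_a/n and the variance contribution is
    the hypergeometric d*(n_a/n)*(1-n_a/n)*(n-d)/(n-1).
    """
    ta, ea = _check_surv_input(times_a, events_a)
    tb, eb = _check_surv_input(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(len(ta), dtype=int), np.ones(len(tb), dtype=int)])

    obs = np.zeros(2)
    exp = np.zeros(2)
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n = int(at.sum())
        na = int((at & (g == 0)).sum())
        d = int(((t == ti) & (e == 1)).sum())
        da = int(((t == ti) & (e == 1) & (g == 0)).sum())
        obs += (da, d - da)
        exp += (d * na / n, d * (n - na) / n)
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)

    if var == 0.0:
        chi2 = 0.0
    else:
        chi2 = float((obs[0] - exp[0]) ** 2 / var)
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogRankResult(observed=obs, expected=exp, variance=var, chi_square=chi2, p_value=p)


def km_strata(cohort, conf_level: float = 0.95, ci_transform: str = "loglog"):
    """Stratified product-limit curves for a two-arm, carrier-split cohort.

    Returns ``(null_model, strata, comparisons)`` where ``null_model`` is the
    pooled-cohort curve, ``strata`` maps (arm, carrier) -> KMResults for each
    non-empty stratum of the analyzed cohort, and ``comparisons`` maps pairs
    of stratum keys to LogRankResult (suppressed when <2 strata are
    non-empty).
    """
    df = cohort.analyzed()
    pooled = KaplanMeier(cohort.frame["time"], cohort.frame["event"], label="null").fit(
        conf_level=conf_level, ci_transform=ci_transform
    )
    strata: dict = {}
    for (arm, carrier), sub in df.groupby(["arm", "carrier"], sort=True):
        if len(sub) == 0:
            continue
        key = (int(arm), bool(carrier))
        strata[key] = KaplanMeier(sub["time"], sub["event"], label=key).fit(
            conf_level=conf_level, ci_transform=ci_transform
        )
    comparisons: dict = {}
    keys = sorted(strata)
    if len(keys) >= 2:
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                a = df[(df["arm"] == ka[0]) & (df["carrier"] == ka[1])]
                b = df[(df["arm"] == kb[0]) & (df["carrier"] == kb[1])]
                if a["event"].sum() + b["event"].sum() == 0:
                    continue
                comparisons[(ka, kb)] = logrank(a["time"], a["event"], b["time"], b["event"])
    return pooled, strata, comparisons
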