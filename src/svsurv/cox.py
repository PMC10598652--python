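"""Cox proportional-hazards regression via maximum partial likelihood.

The model is h(t | x) = h0(t) * exp(x' beta).  beta is estimated by
Newton-Raphson on the log partial likelihood, with the Efron (default) or
Breslow approximation for tied event times.  Standard errors come from the
inverse observed information; Wald z, p-values and CIs follow.

Estimation is fully deterministic: start at beta = 0, iterate until the
score norm drops below ``tol``, halving the step whenever the log
partial likelihood would decrease.  A monotone partial likelihood
(complete separation — some coefficient escaping to +/- infinity with a
non-vanishing score) is detected and flagged on the results rather than
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError
from .km import _check_surv_input

__all__ = ["CoxPH", "CoxResults", "fit_standard_and_multiple", "hazard_ratio_table"]

_SEPARATION_BOUND = 10.0  # |beta| beyond this with a live score => monotone likelihood


class CoxPH:
    """Cox proportional-hazards model for right-censored data.

    Parameters
    ----------
    times, events : 1-d arrays
        Follow-up time (>0) and event indicator (1=event, 0=censored).
    exog : (n, p) array
        Covariate matrix; no intercept (absorbed by the baseline hazard).
        Constant columns are rejected.
    names : optional list of p column names.
    ties : {"efron", "breslow"}
    """

    def __init__(self, times, events, exog, names=None, ties: str = "efron"):
        self.times, self.events = _check_surv_input(times, events)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(self.times):
            raise ValidationError("exog row count must match times")
        if np.any(~np.isfinite(X)):
            raise ValidationError("exog contains non-finite values")
        const = (X.max(axis=0) - X.min(axis=0)) == 0
        if np.any(const):
            bad = [str(names[i]) if names else f"x{i}" for i in np.where(const)[0]]
            raise ValidationError(f"constant covariate column(s) not allowed: {', '.join(bad)}")
        if self.events.sum() < 1:
            raise ValidationError("Cox regression needs at least one observed event")
        if ties not in ("efron", "breslow"):
            raise ValidationError("ties must be 'efron' or 'breslow'")
        self.exog = X
        self.names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
        if len(self.names) != X.shape[1]:
            raise ValidationError("names length must match exog columns")
        self.ties = ties
        self._prepare()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str, event_col: str,
                       covariates: list[str], ties: str = "efron") -> "CoxPH":
        missing = [c for c in (time_col, event_col, *covariates) if c not in df.columns]
        if missing:
            raise ValidationError(
                f"column(s) {missing} not in dataframe; available: {sorted(df.columns)}"
            )
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy(),
                   df[list(covariates)].to_numpy(dtype=float), names=list(covariates), ties=ties)

    # -- partial likelihood machinery ------------------------------------

    def _prepare(self):
        order = np.argsort(self.times, kind="stable")
        self._t = self.times[order]
        self._e = self.events[order]
        self._X = self.exog[order]
        # distinct event times and, for each, the slice [start, stop) of tied
        # event rows and the risk-set start index (all rows with t >= t_j)
        ev_idx = np.where(self._e == 1)[0]
        ev_t = self._t[ev_idx]
        uniq, first = np.unique(ev_t, return_index=True)
        self._event_times = uniq
        groups = []
        for k, tj in enumerate(uniq):
            rows = ev_idx[ev_t == tj]
            risk_start = int(np.searchsorted(self._t, tj, side="left"))
            groups.append((risk_start, rows))
        self._groups = groups

    def _loglik_score_info(self, beta):
        X, t, e = self._X, self._t, self._e
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # stabilize exp; partial likelihood is shift-invariant
        w = np.exp(eta)
        wx = w[:, None] * X
        wxx = wx[:, :, None] * X[:, None, :]
        # reverse cumulative sums: risk-set aggregates for t >= t_i at row i
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for risk_start, rows in self._groups:
            d = len(rows)
            s0r, s1r, s2r = S0[risk_start], S1[risk_start], S2[risk_start]
            ll += float(eta[rows].sum())
            score += X[rows].sum(axis=0)
            if self.ties == "breslow" or d == 1:
                for _ in range(d):
                    zbar = s1r / s0r
                    ll -= np.log(s0r)
                    score -= zbar
                    info += s2r / s0r - np.outer(zbar, zbar)
            else:
                s0d = w[rows].sum()
                s1d = wx[rows].sum(axis=0)
                s2d = wxx[rows].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s0r - f * s0d
                    num1 = s1r - f * s1d
                    num2 = s2r - f * s2d
                    zbar = num1 / denom
                    ll -= np.log(denom)
                    score -= zbar
                    info += num2 / denom - np.outer(zbar, zbar)
        return ll, score, info

    def loglik(self, beta) -> float:
        """Log partial likelihood at an arbitrary coefficient vector."""
        return self._loglik_score_info(np.asarray(beta, dtype=float))[0]

    def score_test(self, beta0=None):
        """Score (Rao) chi-square test of H0: beta = beta0 (default 0).

        With a single binary covariate and Breslow ties on tie-free data this
        reproduces the two-group log-rank chi-square exactly.
        """
        p = self.exog.shape[1]
        b0 = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float)
        _, u, i = self._loglik_score_info(b0)
        chi2 = float(u @ np.linalg.solve(i, u))
        return chi2, float(stats.chi2.sf(chi2, df=p))

    def fit(self, tol: float = 1e-9, max_iter: int = 25, conf_level: float = 0.95,
            config: str = "standard") -> "CoxResults":
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll0, score, info = self._loglik_score_info(beta)
        ll = ll0
        converged = False
        monotone = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            if np.linalg.norm(score) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                self._raise_singular(info)
            # step-halving if the log partial likelihood would decrease
            # (tolerance relative to |ll|: near the optimum the loglik is flat
            # at floating-point precision and tiny spurious decreases occur)
            factor = 1.0
            ll_tol = 1e-12 * max(1.0, abs(ll))
            for _ in range(30):
                cand = beta + factor * step
                ll_new, score_new, info_new = self._loglik_score_info(cand)
                if ll_new >= ll - ll_tol:
                    break
                factor *= 0.5
            beta, ll, score, info = cand, ll_new, score_new, info_new
            if np.any(np.abs(beta) > _SEPARATION_BOUND) and np.linalg.norm(score) > tol:
                monotone = True
                break
        else:
            n_iter = max_iter
        if not monotone and np.linalg.norm(score) < tol:
            converged = True

        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            self._raise_singular(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        z = stats.norm.ppf(0.5 + conf_level / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            wald_z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(wald_z))
        return CoxResults(
            params=beta,
            bse=se,
            cov_params=cov,
            names=list(self.names),
            hazard_ratios=np.exp(beta),
            conf_int=np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)]),
            wald_z=wald_z,
            p_values=pvals,
            loglik0=ll0,
            loglik=ll,
            n=len(self.times),
            n_events=int(self.events.sum()),
            ties=self.ties,
            converged=converged and not monotone,
            monotone_likelihood=monotone,
            n_iter=n_iter,
            conf_level=conf_level,
            config=config,
        )

    def _raise_singular(self, info):
        # name (near-)collinear columns via the null space of the information
        _, s, vt = np.linalg.svd(info)
        bad = np.where(s < s.max() * 1e-10)[0] if s.max() > 0 else range(len(s))
        cols = sorted({self.names[j] for i in bad for j in np.where(np.abs(vt[i]) > 0.3)[0]})
        raise EstimationError(f"singular information matrix; collinear column(s): {cols}")


@dataclass
class CoxResults:
    """Estimates, uncertainties and diagnostics from one Cox fit."""

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    names: list
    hazard_ratios: np.ndarray
    conf_int: np.ndarray  # (p, 2) on the HR scale
    wald_z: np.ndarray
    p_values: np.ndarray
    loglik0: float
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    monotone_likelihood: bool
    n_iter: int
    conf_level: float
    config: str = "standard"

    def summary(self) -> str:
        lines = [
            f"Cox PH fit ({self.config}; ties={self.ties}; n={self.n}, events={self.n_events})",
            f"log partial likelihood: {self.loglik:.6f} (null {self.loglik0:.6f}); "
            f"converged={self.converged} in {self.n_iter} iterations",
        ]
        if self.monotone_likelihood:
            lines.append("WARNING: monotone partial likelihood (separation); "
                         "estimates diverge and SEs are unreliable")
        lines.append(hazard_ratio_table(self).to_string(index=False))
        return "\n".join(lines)


def hazard_ratio_table(fit: CoxResults, decimals: int = 2) -> pd.DataFrame:
    """Per-term report rows: HR, Wald CI, p, and percent effect 100*(HR-1).

    For a continuous covariate the hazard ratio is the multiplicative change
    in risk per +1 unit of the covariate (in its declared unit), so the
    percent column reads e.g. HR 1.02 -> "+2%" per unit.
    """
    rows = []
    for j, name in enumerate(fit.names):
        hr = fit.hazard_ratios[j]
        pct = 100.0 * (hr - 1.0)
        rows.append({
            "term": name,
            "HR": round(float(hr), decimals),
            "CI_low": round(float(fit.conf_int[j, 0]), decimals),
            "CI_high": round(float(fit.conf_int[j, 1]), decimals),
            "p": float(fit.p_values[j]),
            "percent_effect": f"{pct:+.0f}%" if abs(pct) >= 0.5 else "0%",
            "warning": "separation" if fit.monotone_likelihood else "",
        })
    return pd.DataFrame(rows)


def fit_standard_and_multiple(cohort, covariates=(), ties: str = "efron",
                              conf_level: float = 0.95) -> dict:
    """The two dashboard Cox configurations on a carrier-stratified cohort.

    standard          : all analyzed patients; covariates = arm + carrier (+ extras)
    multiple:carrier  : carrier subset only;   covariates = arm (+ extras)
    multiple:noncarrier : non-carrier subset likewise

    Subsets without events (or too small to identify the model) are reported
    as the string "not estimable" rather than raising.
    """
    df = cohort.analyzed()
    covariates = list(covariates)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValidationError(
            f"covariate(s) {missing} not in cohort; available: "
            f"{sorted(set(df.columns) - {'patient_id', 'arm', 'event', 'time', 'sv_count', 'carrier'})}"
        )

    out: dict = {}
    try:
        model = CoxPH.from_dataframe(
            df.assign(carrier=df["carrier"].astype(float)),
            "time", "event", ["arm", "carrier", *covariates], ties=ties)
        out["standard"] = model.fit(conf_level=conf_level, config="standard")
    except (ValidationError, EstimationError) as exc:
        out["standard"] = f"not estimable: {exc}"

    for flag, key in ((True, "multiple:carrier"), (False, "multiple:noncarrier")):
        sub = df[df["carrier"] == flag]
        if len(sub) == 0 or sub["event"].sum() < 1:
            out[key] = "not estimable: no patients or no events in subset"
            continue
        try:
            model = CoxPH.from_dataframe(sub, "time", "event", ["arm", *covariates], ties=ties)
            out[key] = model.fit(conf_level=conf_level, config=key)
        except (ValidationError, EstimationError) as exc:
            out[key] = f"not estimable: {exc}"
    return out
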