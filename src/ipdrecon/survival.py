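"""Time-to-event estimators: product-limit, median CI, log-rank, Cox, RMST.

These are written from first principles because they are the analytical core
of the package; an established survival library is used only as an
independent cross-check in the test suite.

Conventions used throughout:

* Ties between censorings and events at the same time are resolved
  events-first: a record censored at *t* is counted at risk for events at
  *t*. Curve inversion produces many such ties, so the convention is stated
  explicitly rather than left to chance.
* All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import IPDSet, ValidationError

__all__ = [
    "KMEstimate",
    "MedianResult",
    "CoxResult",
    "RMSTResult",
    "RMSTComparison",
    "km_estimate",
    "km_survival_at",
    "median_survival",
    "log_rank",
    "cox_hr",
    "rmst",
    "rmst_diff",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit fit: one entry per distinct event time.

    ``surv[i]`` is S(t) just after ``event_times[i]``; ``greenwood_var[i]`` is
    the Greenwood variance S(t)^2 * sum d_j / (n_j (n_j - d_j)) over event
    times <= t. ``n_total`` is the number of subjects at time 0.
    """

    event_times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    max_time: float  # last observed time, event or censored

    def survival_at(self, t: float) -> float:
        return km_survival_at(self, t)


@dataclass(frozen=True)
class MedianResult:
    """Median survival with a Brookmeyer-Crowley 95% CI (log(-log) transform).

    Components are ``None`` when the relevant curve or confidence band never
    reaches 0.5 within follow-up — undefined, not an error.
    """

    median: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    method: str = "brookmeyer-crowley-loglog"


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate Cox fit; HR < 1 means lower hazard in the non-reference group."""

    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int
    events: int
    ties_method: str = "efron"
    converged: bool = True


@dataclass(frozen=True)
class RMSTResult:
    """Restricted mean survival time: area under S(t) on [0, tau], in months."""

    tau: float
    rmst: float
    var: float


@dataclass(frozen=True)
class RMSTComparison:
    tau: float
    diff: float
    ci_low: float
    ci_high: float
    p: float


def _counts(times: np.ndarray, events: np.ndarray):
    """Risk/event counts at each distinct event time (events-first tie rule)."""
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    n = len(times)
    uniq_all, idx_start = np.unique(times, return_index=True)
    d_all = np.add.reduceat(events, idx_start) if n else np.array([], int)
    keep = d_all > 0
    uniq = uniq_all[keep]
    # at risk at t: records with time >= t (censored-at-t records still at risk)
    n_risk = (n - idx_start[keep]).astype(int)
    return uniq, n_risk, d_all[keep].astype(int)


def km_estimate(ipd: IPDSet) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i.
    Where S(t) reaches 0 the Greenwood variance is reported as 0.
    """
    t, e = ipd.times_events()
    times = np.asarray(t, dtype=float)
    events = np.asarray(e, dtype=int)
    uniq, n_risk, d = _counts(times, events)
    frac = np.ones_like(uniq, dtype=float)
    if len(uniq):
        frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    # Greenwood: S^2 * cumsum(d / (n (n - d))); final term with n == d gives S = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > d, d / (n_risk * (n_risk - d).astype(float)), np.inf)
        gv = surv**2 * np.cumsum(inc)
    gv = np.where(surv <= 0.0, 0.0, gv)
    return KMEstimate(
        event_times=uniq,
        surv=surv,
        n_risk=n_risk,
        n_event=d,
        greenwood_var=gv,
        n_total=len(times),
        max_time=float(np.max(times)),
    )


def km_survival_at(km: KMEstimate, t: float) -> float:
    """S(t) of the step function (right-continuous)."""
    idx = np.searchsorted(km.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(km.surv[idx])


def _loglog_bands(km: KMEstimate, z: float = Z95):
    """Pointwise 95% bands on the log(-log S) scale (exponential Greenwood)."""
    s = km.surv
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    for i, (si, vi) in enumerate(zip(s, km.greenwood_var)):
        if si <= 0.0:
            lo[i] = hi[i] = 0.0
        elif si >= 1.0 or vi <= 0.0:
            lo[i] = hi[i] = si
        else:
            se_theta = math.sqrt(vi) / abs(si * math.log(si))
            lo[i] = si ** math.exp(z * se_theta)
            hi[i] = si ** math.exp(-z * se_theta)
    return lo, hi


def median_survival(km: KMEstimate) -> MedianResult:
    """Median survival = first event time with S(t) <= 0.5.

    The 95% CI is the Brookmeyer-Crowley construction on the log(-log) scale:
    each bound is the first event time at which the corresponding pointwise
    confidence band crosses 0.5. Bounds the bands never reach are ``None``.
    """
    def first_leq(values: np.ndarray) -> Optional[float]:
        idx = np.nonzero(values <= 0.5)[0]
        return float(km.event_times[idx[0]]) if len(idx) else None

    if len(km.event_times) == 0:
        return MedianResult(None, None, None)
    lo_band, hi_band = _loglog_bands(km)
    return MedianResult(
        median=first_leq(km.surv),
        ci_low=first_leq(lo_band),
        ci_high=first_leq(hi_band),
    )


def log_rank(a: IPDSet, b: IPDSet) -> tuple[float, float]:
    """Unweighted two-group log-rank test (hypergeometric variance, df = 1)."""
    ta, ea = a.times_events()
    tb, eb = b.times_events()
    if sum(ea) + sum(eb) == 0:
        raise ValidationError("log-rank undefined: no events in either group")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(int)
    group = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    uniq = np.unique(times[events == 1])
    O = E = V = 0.0
    for t in uniq:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 0)).sum())
        dmask = (times == t) & (events == 1)
        d = int(dmask.sum())
        d1 = int((dmask & (group == 0)).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValidationError("log-rank undefined: zero variance")
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _efron_quantities(beta: float, times: np.ndarray, events: np.ndarray, z: np.ndarray):
    """Partial log-likelihood, score and information for one binary covariate.

    Efron's correction: at an event time with d tied events whose covariate
    sum is s_D, the l-th denominator (l = 0..d-1) is R - (l/d) D where R and D
    are risk-set and tied-set sums of exp(beta z).
    """
    eb = math.exp(beta)
    order = np.argsort(times, kind="stable")
    times, events, z = times[order], events[order], z[order]
    uniq = np.unique(times[events == 1])
    n = len(times)
    ll = score = info = 0.0
    for t in uniq:
        at_risk = times >= t
        n1 = int((z[at_risk] == 1).sum())
        n0 = int(at_risk.sum()) - n1
        r0 = n0 + n1 * eb          # sum exp(beta z) over risk set
        r1 = n1 * eb               # sum z exp(beta z)  (z^2 = z)
        dmask = (times == t) & (events == 1)
        d = int(dmask.sum())
        s1 = int((z[dmask] == 1).sum())
        d0 = (d - s1) + s1 * eb    # tied-set sum of exp(beta z)
        d1 = s1 * eb
        ll += beta * s1
        for l in range(d):
            f = l / d
            phi0 = r0 - f * d0
            phi1 = r1 - f * d1
            ll -= math.log(phi0)
            mu = phi1 / phi0
            score -= mu
            info += mu * (1.0 - mu)  # phi2 = phi1 for a 0/1 covariate
        score += s1
    return ll, score, info


def cox_hr(
    pooled: IPDSet,
    labels: Sequence[int],
    *,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit for one binary group indicator.

    ``labels[i] = 1`` marks the non-reference (experimental) group; the
    returned HR is its hazard relative to the reference. Ties are handled with
    Efron's correction; Newton-Raphson starts at beta = 0. Monotone likelihood
    (complete separation in time) or non-convergence is flagged via
    ``converged=False`` rather than silently reported.
    """
    t, e = pooled.times_events()
    times = np.asarray(t, float)
    events = np.asarray(e, int)
    z = np.asarray(labels, int)
    if len(z) != len(times):
        raise ValidationError("labels must align with records")
    if set(np.unique(z)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(z)) < 2:
        raise ValidationError("both groups must be present")
    if events.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        ll, score, info = _efron_quantities(beta, times, events, z)
        if info <= 0:
            break
        step = score / info
        # dampen absurd steps from near-flat likelihoods
        step = max(min(step, 5.0), -5.0)
        beta += step
        if abs(step) < tol:
            converged = True
            break
    if abs(beta) > 20:  # monotone likelihood: beta runs away
        converged = False
    _, _, info = _efron_quantities(beta, times, events, z)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    hr = math.exp(beta)
    zstat = beta / se if se > 0 and math.isfinite(se) else 0.0
    return CoxResult(
        log_hr=beta,
        se=se,
        hr=hr,
        ci_low=math.exp(beta - 1.96 * se) if math.isfinite(se) else 0.0,
        ci_high=math.exp(beta + 1.96 * se) if math.isfinite(se) else float("inf"),
        wald_p=float(2.0 * stats.norm.sf(abs(zstat))),
        n=len(times),
        events=int(events.sum()),
        converged=converged,
    )


def rmst(km: KMEstimate, tau: float) -> RMSTResult:
    """Restricted mean survival time: area under the KM step curve on [0, tau].

    Raises when tau exceeds the last observed time — the estimate would
    require extrapolating beyond follow-up, which is never done silently.

    The variance is the Greenwood-style area formula
    sum_{t_i <= tau} A_i^2 d_i / (n_i (n_i - d_i)), where A_i is the area
    under S between t_i and tau.
    """
    if tau <= 0:
        raise ValidationError("tau must be positive")
    if tau > km.max_time + 1e-12:
        raise ValidationError(
            f"tau={tau} exceeds last observed time {km.max_time}: refusing to extrapolate"
        )
    mask = km.event_times <= tau
    ts = km.event_times[mask]
    ss = km.surv[mask]
    # integrate the step function: S = 1 on [0, t_1), surv[i] on [t_i, t_{i+1})
    knots = np.concatenate([[0.0], ts, [tau]])
    heights = np.concatenate([[1.0], ss])
    widths = np.diff(knots)
    area = float(np.sum(heights * widths))
    # A_i: area from t_i to tau
    seg = heights * widths
    tail = np.cumsum(seg[::-1])[::-1]  # tail[i] = area from knots[i] to tau
    var = 0.0
    d = km.n_event[mask]
    nr = km.n_risk[mask]
    for i in range(len(ts)):
        A_i = float(tail[i + 1])
        if nr[i] > d[i]:
            var += A_i**2 * d[i] / (nr[i] * (nr[i] - d[i]))
    return RMSTResult(tau=float(tau), rmst=area, var=float(var))


def rmst_diff(a: RMSTResult, b: RMSTResult) -> RMSTComparison:
    """Normal-approximation test of the RMST difference a - b at a common tau."""
    if a.tau != b.tau:
        raise ValidationError(f"tau mismatch: {a.tau} vs {b.tau}")
    diff = a.rmst - b.rmst
    se = math.sqrt(a.var + b.var)
    if se == 0.0:
        p = 1.0 if diff == 0 else 0.0
        return RMSTComparison(a.tau, diff, diff, diff, p)
    zstat = diff / se
    return RMSTComparison(
        tau=a.tau,
        diff=diff,
        ci_low=diff - 1.96 * se,
        ci_high=diff + 1.96 * se,
        p=float(2.0 * stats.norm.sf(abs(zstat))),
    )
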