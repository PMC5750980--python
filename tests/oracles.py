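"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — plain Python loops and textbook
formulas — and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln


def scan_heat_waves(values, t95, t98):
    """Naive day-by-day run scan: maximal runs of values >= t95, kept if
    length >= 3 and any value > t98.  Returns (start_idx, stop_idx) pairs,
    stop exclusive."""
    events = []
    i = 0
    n = len(values)
    while i < n:
        if values[i] >= t95:
            j = i
            while j < n and values[j] >= t95:
                j += 1
            if j - i >= 3 and any(values[k] > t98 for k in range(i, j)):
                events.append((i, j))
            i = j
        else:
            i += 1
    return events


def loop_ehi_sig(values, t95):
    out = [math.nan] * len(values)
    for i in range(2, len(values)):
        out[i] = (values[i] + values[i - 1] + values[i - 2]) / 3 - t95
    return out


def loop_ehi_accl(values):
    out = [math.nan] * len(values)
    for i in range(32, len(values)):
        three = (values[i] + values[i - 1] + values[i - 2]) / 3
        thirty = sum(values[i - k] for k in range(3, 33)) / 30
        out[i] = three - thirty
    return out


def loop_ehf(sig, accl):
    out = []
    for s, a in zip(sig, accl):
        if math.isnan(s) or math.isnan(a):
            out.append(math.nan)
        else:
            out.append(max(0.0, s) * max(1.0, a))
    return out


def quantile_sorted(values, p):
    """Linear interpolation between order statistics at h = (n-1)p."""
    xs = sorted(values)
    h = (len(xs) - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def _log_poisson_cdf(k, mu):
    # log-sum-exp over pmf terms 0..k
    ks = np.arange(k + 1)
    logs = -mu + ks * math.log(mu) - gammaln(ks + 1)
    m = logs.max()
    return m + math.log(np.exp(logs - m).sum())


def poisson_ci_tail_inversion(o, alpha=0.05):
    """Exact Poisson limits by numerically inverting the tail sums:
    lower mu solves P(X >= o | mu) = alpha/2, upper solves P(X <= o | mu)
    = alpha/2."""

    def upper_tail(mu):  # P(X >= o)
        return 1.0 - math.exp(_log_poisson_cdf(o - 1, mu))

    def lower_tail(mu):  # P(X <= o)
        return math.exp(_log_poisson_cdf(o, mu))

    if o == 0:
        lo = 0.0
    else:
        lo = brentq(lambda mu: upper_tail(mu) - alpha / 2, 1e-10, 3 * o + 20, xtol=1e-12)
    hi = brentq(lambda mu: lower_tail(mu) - alpha / 2, max(o, 1e-6) / 10, 3 * o + 50, xtol=1e-12)
    return lo, hi


def ols_line(x, y):
    """Textbook normal-equations OLS: slope, intercept, R^2, two-sided
    slope p-value."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


def welch_t(a, b):
    """Textbook Welch t statistic and two-sided p-value."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, p
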