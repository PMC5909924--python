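"""Independent brute-force reference implementations used only by tests.

Each function is a direct transcription of the defining formula, written as
plain loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def pll_nested(theta, time, event) -> float:
    """Textbook nested-sum Cox partial log-likelihood (Breslow ties)."""
    total = 0.0
    n = len(theta)
    for i in range(n):
        if event[i] != 1:
            continue
        denom = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                denom += math.exp(theta[j])
        total += theta[i] - math.log(denom)
    return total


def harrell_loop(theta, time, event) -> float:
    """Pairwise-loop Harrell C: comparable pair = earlier time has event."""
    num = den = 0.0
    n = len(theta)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                den += 1.0
                if theta[i] > theta[j]:
                    num += 1.0
                elif theta[i] == theta[j]:
                    num += 0.5
    return num / den


def ipcw_loop(theta, time, event, g_before) -> float:
    """Weighted pairwise loop: weight 1/G(t_i-)^2 on the earlier event."""
    num = den = 0.0
    n = len(theta)
    for i in range(n):
        if event[i] != 1 or g_before[i] <= 0:
            continue
        w = 1.0 / g_before[i] ** 2
        for j in range(n):
            if time[i] < time[j]:
                den += w
                if theta[i] > theta[j]:
                    num += w
                elif theta[i] == theta[j]:
                    num += 0.5 * w
    return num / den


def logrank_statistic(time_a, event_a, time_b, event_b) -> float:
    """Two-sample log-rank chi-square, sum over event times of (O-E) with
    the hypergeometric variance: U^2 / V."""
    times = sorted(set(list(time_a[event_a == 1]) + list(time_b[event_b == 1])))
    U = V = 0.0
    for s in times:
        na = np.sum(time_a >= s)
        nb = np.sum(time_b >= s)
        da = np.sum((time_a == s) & (event_a == 1))
        db = np.sum((time_b == s) & (event_b == 1))
        n = na + nb
        d = da + db
        if n < 2 or d == 0:
            continue
        ea = d * na / n
        U += da - ea
        V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return U**2 / V


def brier_at(t, surv_at_t, time, event, g_before, g_at_t) -> float:
    """Definitional IPCW Brier score at a single time point."""
    n = len(time)
    total = 0.0
    for i in range(n):
        if time[i] <= t and event[i] == 1:
            if g_before[i] > 0:
                total += surv_at_t[i] ** 2 / g_before[i]
        elif time[i] > t:
            if g_at_t > 0:
                total += (1.0 - surv_at_t[i]) ** 2 / g_at_t
    return total / n
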