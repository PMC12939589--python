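"""Independent brute-force oracles used to validate the package's
estimators.  Everything here is written with explicit loops and naive
formulas, deliberately sharing no code with the implementation."""

from __future__ import annotations

import numpy as np


def brute_km(time, event):
    """Product-limit estimate via explicit risk-set counting.

    Returns (event_times, survival) with one entry per distinct event time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ts = sorted({t for t, e in zip(time, event) if e == 1})
    surv = []
    for t in ts:
        s = 1.0
        for u in ts:
            if u <= t:
                n = sum(1 for x in time if x >= u)
                d = sum(1 for x, e in zip(time, event) if x == u and e == 1)
                s *= 1.0 - d / n
        surv.append(s)
    return np.array(ts), np.array(surv)


def brute_greenwood(time, event):
    """Greenwood variance of the product-limit estimate, by direct sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ts, surv = brute_km(time, event)
    var = []
    for t, s in zip(ts, surv):
        acc = 0.0
        for u in ts:
            if u <= t:
                n = sum(1 for x in time if x >= u)
                d = sum(1 for x, e in zip(time, event) if x == u and e == 1)
                if n > d:
                    acc += d / (n * (n - d))
        var.append(s * s * acc)
    return ts, np.array(var)


def brute_logrank(time, event, group):
    """Two-group log-rank chi-square via explicit O-E/V sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()), key=str)
    assert len(levels) == 2
    O1 = E1 = V = 0.0
    for t in sorted({t for t, e in zip(time, event) if e == 1}):
        n = sum(1 for x in time if x >= t)
        n1 = sum(1 for x, g in zip(time, group) if x >= t and g == levels[0])
        d = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        d1 = sum(1 for x, e, g in zip(time, event, group)
                 if x == t and e == 1 and g == levels[0])
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0
    return (O1 - E1) ** 2 / V


def permutation_logrank_p(time, event, group, n_perm=10_000, seed=0):
    """Monte-Carlo permutation p-value of the log-rank statistic."""
    rng = np.random.default_rng(seed)
    obs = brute_logrank(time, event, group)
    group = np.asarray(group)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        if brute_logrank(time, event, perm) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def average_ranks(x):
    """Average (midrank) ranks computed by explicit tie grouping."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Spearman rho as the Pearson correlation of midranks."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx * rx).sum() * (ry * ry).sum()))


def breslow_loglik_naive(beta, X, time, event):
    """Breslow log partial likelihood via explicit risk-set loops."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            denom = sum(np.exp(eta[j]) for j in range(len(time))
                        if time[j] >= time[i])
            ll += eta[i] - np.log(denom)
    return ll


def newton_oracle_single(x, time, event, tol=1e-12):
    """Maximize the single-feature Breslow partial likelihood with a scalar
    golden-section search (no gradients shared with the implementation)."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -breslow_loglik_naive([b], np.asarray(x, float)[:, None],
                                        time, event),
        bounds=(-20, 20), method="bounded",
        options={"xatol": tol})
    return float(res.x)
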