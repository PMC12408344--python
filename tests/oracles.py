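"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most literal method available
(index scans, powerset enumeration, repeat-until-stable loops, dense
grids) and deliberately shares no code with the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def growth_features_bruteforce(times, values, window: int = 1) -> dict:
    """Exhaustive index-scan version of the seven growth features."""
    t = np.asarray(times, dtype=float)
    if window > 1:
        half = window // 2
        y = np.array([
            np.mean(values[max(0, i - half): i + half + 1])
            for i in range(len(values))
        ])
    else:
        y = np.asarray(values, dtype=float)
    n = len(y)

    first_local_max = None
    for i in range(n):
        ok_left = (i == 0) or (y[i - 1] <= y[i])
        ok_right = (i == n - 1) or (y[i] >= y[i + 1])
        if ok_left and ok_right:
            first_local_max = y[i]
            break

    initial_density = None
    for i in range(n):
        ok_left = (i == 0) or (y[i - 1] >= y[i])
        ok_right = (i == n - 1) or (y[i] <= y[i + 1])
        if ok_left and ok_right:
            initial_density = y[i]
            break

    auc = 0.0
    for i in range(n - 1):
        auc += 0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i])

    max_density = max(y)
    i_max = min(i for i in range(n) if y[i] == max_density)
    time_to_max = t[i_max]

    half_max = max_density / 2.0
    if y[0] >= half_max:
        midpoint = t[0]
    else:
        midpoint = np.nan
        for i in range(1, n):
            if y[i] >= half_max:
                frac = (half_max - y[i - 1]) / (y[i] - y[i - 1])
                midpoint = t[i - 1] + frac * (t[i] - t[i - 1])
                break

    best_slope, best_i = -np.inf, 0
    for i in range(n - 1):
        s = (y[i + 1] - y[i]) / (t[i + 1] - t[i])
        if s > best_slope:
            best_slope, best_i = s, i
    inflection = t[best_i]

    return {
        "first_local_max": float(first_local_max),
        "initial_density": float(initial_density),
        "auc": float(auc),
        "max_density": float(max_density),
        "time_to_max_density": float(time_to_max),
        "midpoint": float(midpoint),
        "inflection_point": float(inflection),
    }


def scope_naive(reactions, seeds) -> frozenset:
    """Repeat-until-stable rescan; reactions given as
    (substrates, products, reversible) triples."""
    reach = set(seeds)
    while True:
        before = len(reach)
        for subs, prods, rev in reactions:
            if set(subs) <= reach:
                reach |= set(prods)
            if rev and set(prods) <= reach:
                reach |= set(subs)
        if len(reach) == before:
            return frozenset(reach)


def rxn_triples(network) -> list:
    return [(r.substrates, r.products, r.reversible) for r in network.reactions]


def minimal_communities_powerset(networks, seed_mets, targets) -> tuple[int, set]:
    """Scan all 2^n subsets; return (min size, set of minimal subsets)."""
    targets = set(targets)
    if targets <= set(seed_mets):
        return 0, {frozenset()}
    ids = [n.organism for n in networks]
    by_id = {n.organism: n for n in networks}
    feasible_by_size: dict[int, set] = {}
    for r in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            rxns = [tr for org in combo for tr in rxn_triples(by_id[org])]
            if targets <= scope_naive(rxns, seed_mets):
                feasible_by_size.setdefault(r, set()).add(frozenset(combo))
        if r in feasible_by_size:
            return r, feasible_by_size[r]
    raise AssertionError("targets unreachable by the full pool")


def argmax_rate_grid(params, t0: float, t1: float, step: float = 1e-4):
    """Dense-grid maximizer of the closed-form |dy/dt| of the 5-parameter
    generalized logistic, written out directly."""
    y0, yf, k, ti, nu = params
    t = np.arange(t0, t1 + step, step)
    u = np.exp(-k * (t - ti))
    rate = (yf - y0) * (k / nu) * u * (1.0 + u) ** (-1.0 / nu - 1.0)
    i = int(np.argmax(np.abs(rate)))
    return float(t[i]), float(rate[i])


def finite_diff_rate(params, t, h: float = 1e-6):
    """Central finite difference of the model curve."""
    y0, yf, k, ti, nu = params

    def f(tt):
        u = np.exp(-k * (np.asarray(tt) - ti))
        return y0 + (yf - y0) * (1.0 + u) ** (-1.0 / nu)

    return (f(t + h) - f(t - h)) / (2 * h)
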