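"""Independent textbook-formula oracles.

Deliberately naive re-implementations (enumeration, explicit product-limit
recursion, closed-form tail probabilities) used only to cross-check the
package; they share no code with the implementation paths they verify.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.special import stdtr


def auroc_by_enumeration(pos, neg) -> float:
    """P(pos beats neg) over all pairs, ties counted 0.5."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def km_product_limit(times, events):
    """Product-limit estimator computed by explicit recursion.

    Returns (event_times, survival_at_those_times, median).
    """
    order = np.argsort(times, kind="stable")
    t = np.asarray(times, float)[order]
    e = np.asarray(events, bool)[order]
    s = 1.0
    at_risk = len(t)
    out_t, out_s = [], []
    i = 0
    while i < len(t):
        tau = t[i]
        d = int(np.sum((t == tau) & e))
        n_tau = int(np.sum(t == tau))
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(tau)
            out_s.append(s)
        at_risk -= n_tau
        i += n_tau
    median = None
    for tau, sv in zip(out_t, out_s):
        if sv <= 0.5 + 1e-12:  # inclusive at exactly 0.5, robust to fp rounding
            median = tau
            break
    return np.array(out_t), np.array(out_s), median


def mcnemar_chi2_tail(b: int, c: int) -> tuple[float, float]:
    """Continuity-corrected McNemar statistic and one-sided chi2(1) tail."""
    if b + c == 0:
        return 0.0, 1.0
    stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    return stat, chi2_dist.sf(stat, 1) / 2.0


def odds_ratio_cross_product(a: int, b: int, c: int, d: int) -> float:
    """OR of a 2x2 table [[a, b], [c, d]] = ad / bc."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def binomial_sf_at_least(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p), by summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def welch_t_two_tailed(x, y) -> float:
    """Two-tailed Welch t-test p-value from the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 1.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * (1.0 - stdtr(df, abs(t)))


def pearson_r_by_formula(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def rbf_brute_force(wells, drug, marker) -> float:
    """Recompute mean RBF well-by-well from raw counts.

    Averages replicates within concentration, then concentrations —
    written against the raw record fields only.
    """
    ctrl = []
    for w in wells:
        if w.drug == "DMSO":
            pos = w.n_viable_marker_pos[marker]
            neg = w.n_viable_marker_neg[marker]
            if pos + neg > 0:
                ctrl.append(pos / (pos + neg))
    ctrl_mean = sum(ctrl) / len(ctrl)
    per_conc: dict[float, list[float]] = {}
    for w in wells:
        if w.drug == drug:
            pos = w.n_viable_marker_pos[marker]
            neg = w.n_viable_marker_neg[marker]
            if pos + neg > 0:
                per_conc.setdefault(w.concentration_um, []).append(
                    (pos / (pos + neg)) / ctrl_mean
                )
    conc_means = [sum(v) / len(v) for v in per_conc.values()]
    return sum(conc_means) / len(conc_means)
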