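"""Hartigan's dip statistic of unimodality, with a bootstrap test.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function and any unimodal distribution function (cdf convex up
to some mode, concave beyond it, with a possible point mass -- a jump -- at
the mode itself).

Writing the band constraint at each distinct observation (the candidate cdf
must pass within t of both the left limit and the right value of the
empirical step, except at a jump mode where the two sides are constrained
separately), the dip is the smallest feasible t over all mode placements:
either inside a gap between adjacent observations (continuous mode) or at
an observation (jump mode).  This module solves that problem exactly: a
convex-minorant/concave-majorant scan yields a tight lower bound for every
candidate mode placement in O(n) amortized, and candidates are then
resolved in ascending order of the bound by a small linear program until
the remaining bounds cannot beat the best exact value.  The bound is almost
always tight, so typically a single LP is solved.

The significance test bootstraps the null distribution of the dip under a
uniform sample of the same size (the dip is invariant under monotone
rescaling, so the uniform is the canonical unimodal null).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["dip_statistic", "dip_test"]


def _unique_bounds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct sorted values with the low/high empirical cdf value at each."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    xu, idx, cnt = np.unique(xs, return_index=True, return_counts=True)
    return xu, idx / n, (idx + cnt) / n


def _prefix_convex_dev(
    xu: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convex-feasibility deviations for every prefix.

    A convex monotone function fits bands ``[hi_k - t, lo_k + t]`` on the
    prefix 0..p iff the greatest convex minorant of the points (xu, lo)
    clears ``hi - t`` after being shifted up by t, i.e. iff
    ``2 t >= max_k (hi_k - GCM(x_k))``.  Returns ``(full, excl)`` where
    ``full[p]`` is that maximum over k <= p and ``excl[p]`` omits the lower
    band at the endpoint p itself (the relaxation used when the mode jumps
    at p, where only the left limit of the empirical cdf binds).
    """
    m = xu.size
    full = np.empty(m)
    excl = np.empty(m)
    hull = [0]
    best = 0.0  # max deviation excluding current endpoint's own band
    excl[0] = 0.0
    full[0] = hi[0] - lo[0]
    for i in range(1, m):
        best = max(best, hi[i - 1] - lo[i - 1])  # previous endpoint's band
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (lo[i] - lo[i2]) * (xu[i2] - xu[i1]) < (lo[i2] - lo[i1]) * (
                xu[i] - xu[i2]
            ):
                hull.pop()
            else:
                break
        i1 = hull[-1]
        if i - i1 > 1:  # new hull segment re-covers interior points
            sl = slice(i1 + 1, i)
            w = (xu[sl] - xu[i1]) / (xu[i] - xu[i1])
            val = lo[i1] + w * (lo[i] - lo[i1])
            best = max(best, float(np.max(hi[sl] - val)))
        hull.append(i)
        excl[i] = best
        full[i] = max(best, hi[i] - lo[i])
    return full, excl


def _candidate_lp(
    xu: np.ndarray, lo: np.ndarray, hi: np.ndarray, kind: str, idx: int
) -> float:
    """Minimal band half-width t for one mode placement, by linear program.

    ``kind == 'gap'``: continuous mode between x_idx and x_{idx+1} (peak
    slope at segment idx).  ``kind == 'jump'``: point mass at x_idx; the
    convex part ends at a value within t of the left cdf limit there, the
    concave part starts within t of the right cdf value.
    """
    m = xu.size
    dx = np.diff(xu)
    rows: list[np.ndarray] = []
    rhs: list[float] = []

    if kind == "gap":
        nv = m + 1  # g_0..g_{m-1}, t
        # two-sided bands everywhere
        for k in range(m):
            r = np.zeros(nv)
            r[k], r[-1] = 1.0, -1.0
            rows.append(r)
            rhs.append(lo[k])
            r = np.zeros(nv)
            r[k], r[-1] = -1.0, -1.0
            rows.append(r)
            rhs.append(-hi[k])
        # curvature: slopes increase for segments < idx+? : s_k <= s_{k+1}
        # for k < idx, decrease for k >= idx
        for k in range(m - 2):
            r = np.zeros(nv)
            ck, ck1 = 1.0 / dx[k], 1.0 / dx[k + 1]
            sgn = 1.0 if k < idx else -1.0
            r[k] = -sgn * ck
            r[k + 1] = sgn * (ck + ck1)
            r[k + 2] = -sgn * ck1
            rows.append(r)
            rhs.append(0.0)
        mono_pairs = [(k, k + 1) for k in range(m - 1)]
    else:  # jump at knot idx
        n_g = idx + 1
        n_h = m - idx
        nv = n_g + n_h + 1  # g_0..g_idx, h_idx..h_{m-1}, t
        # prefix bands: two-sided for k < idx, left-limit band at idx
        for k in range(idx):
            r = np.zeros(nv)
            r[k], r[-1] = 1.0, -1.0
            rows.append(r)
            rhs.append(lo[k])
            r = np.zeros(nv)
            r[k], r[-1] = -1.0, -1.0
            rows.append(r)
            rhs.append(-hi[k])
        r = np.zeros(nv)
        r[idx], r[-1] = 1.0, -1.0
        rows.append(r)
        rhs.append(lo[idx])
        r = np.zeros(nv)
        r[idx], r[-1] = -1.0, -1.0
        rows.append(r)
        rhs.append(-lo[idx])
        # suffix bands: right-value band at idx, two-sided beyond
        r = np.zeros(nv)
        r[n_g], r[-1] = 1.0, -1.0
        rows.append(r)
        rhs.append(hi[idx])
        r = np.zeros(nv)
        r[n_g], r[-1] = -1.0, -1.0
        rows.append(r)
        rhs.append(-hi[idx])
        for k in range(idx + 1, m):
            j = n_g + (k - idx)
            r = np.zeros(nv)
            r[j], r[-1] = 1.0, -1.0
            rows.append(r)
            rhs.append(lo[k])
            r = np.zeros(nv)
            r[j], r[-1] = -1.0, -1.0
            rows.append(r)
            rhs.append(-hi[k])
        # convexity on the prefix chain, concavity on the suffix chain
        for k in range(idx - 1):
            r = np.zeros(nv)
            ck, ck1 = 1.0 / dx[k], 1.0 / dx[k + 1]
            r[k] = -ck
            r[k + 1] = ck + ck1
            r[k + 2] = -ck1
            rows.append(r)
            rhs.append(0.0)
        for k in range(idx, m - 2):
            j = n_g + (k - idx)
            r = np.zeros(nv)
            ck, ck1 = 1.0 / dx[k], 1.0 / dx[k + 1]
            r[j] = ck
            r[j + 1] = -(ck + ck1)
            r[j + 2] = ck1
            rows.append(r)
            rhs.append(0.0)
        mono_pairs = [(k, k + 1) for k in range(idx)]
        mono_pairs += [(n_g + k, n_g + k + 1) for k in range(n_h - 1)]
        mono_pairs.append((idx, n_g))  # g_idx <= h_idx across the jump
    for a, b in mono_pairs:
        r = np.zeros(nv)
        r[a], r[b] = 1.0, -1.0
        rows.append(r)
        rhs.append(0.0)

    c = np.zeros(nv)
    c[-1] = 1.0
    res = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(None, None)] * (nv - 1) + [(0, None)],
        method="highs",
    )
    return float(res.fun) if res.status == 0 else np.inf


def dip_statistic(x: np.ndarray, stop_above: float | None = None) -> float:
    """Exact dip statistic of a 1-D sample.

    ``stop_above``, if given, allows early exit as soon as the dip is known
    to be smaller than that value (used by the bootstrap test, which only
    needs the comparison against the observed dip); the returned value is
    then an upper bound that is exact whenever it is >= ``stop_above``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one observation")
    xu, lo, hi = _unique_bounds(x)
    m = xu.size
    if m == 1:
        return 0.0  # a point mass is unimodal
    if m == 2:
        return float(min(hi - lo) / 2.0)
    pre_full, pre_excl = _prefix_convex_dev(xu, lo, hi)
    sf, se = _prefix_convex_dev(-xu[::-1], (1.0 - hi)[::-1], (1.0 - lo)[::-1])
    suf_full, suf_excl = sf[::-1], se[::-1]
    cands: list[tuple[float, str, int]] = []
    for j in range(m - 1):  # continuous mode in gap j
        cands.append((max(pre_full[j + 1], suf_full[j]) / 2.0, "gap", j))
    for i in range(m):  # point mass at knot i
        cands.append((max(pre_excl[i], suf_excl[i]) / 2.0, "jump", i))
    cands.sort(key=lambda t: t[0])
    best = np.inf
    tol = 1e-9
    for bound, kind, idx in cands:
        if bound >= best - tol:
            break
        if stop_above is not None and best < stop_above:
            break
        best = min(best, _candidate_lp(xu, lo, hi, kind, idx))
    return float(best)


def dip_test(
    x: np.ndarray,
    n_boot: int = 200,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    p = (1 + #{dip(U_n) >= dip(x)}) / (n_boot + 1) over uniform samples of
    the same size.  Small p indicates departure from unimodality.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least four observations for the dip test")
    d_obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        u = rng.random(x.size)
        if dip_statistic(u, stop_above=d_obs) >= d_obs:
            exceed += 1
    return d_obs, (1.0 + exceed) / (n_boot + 1.0)
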