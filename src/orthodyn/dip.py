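"""Hartigan & Hartigan dip statistic for unimodality testing.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function (convex up to a
mode, concave after it, with an atom permitted at the mode).  It is computed
here by the classical greatest-convex-minorant / least-concave-majorant
(GCM/LCM) fixed-point algorithm: the modal interval [low, high] is shrunk
iteratively to the span where the GCM and LCM of F_n disagree the most, and
the dip is the largest one-sided deviation of F_n from the GCM fit below the
interval and from the LCM fit above it, halved.

P-values are calibrated by Monte Carlo against uniform samples of the same
size (the least-favourable unimodal null), rather than interpolated from
printed tables, so results are reproducible bit-for-bit across platforms.
Null tables are cached per sample size because the null distribution of the
dip depends on n only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test"]

#: dedicated seed for the shared null-calibration tables; fixed so that a
#: given (n, n_boot) always yields the same reference distribution
_NULL_TABLE_SEED = 987654321


@dataclass(frozen=True)
class DipResult:
    statistic: float
    pvalue: float
    n: int
    n_boot: int


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample.

    Returns 0 for samples of size < 2 or with all values identical (a point
    mass is itself unimodal).  For non-degenerate samples the dip is at
    least 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1 or np.isnan(x).any():
        raise ValueError("dip requires a non-empty sample without NaNs")
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # 1-based arrays to mirror the published algorithm exactly
    xv = np.concatenate(([0.0], x))
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)

    # precompute convex-minorant predecessor chain over the whole sample
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (
                (xv[j] - xv[mnj]) * (mnj - mnmnj)
                < (xv[mnj] - xv[mnmnj]) * (j - mnj)
            ):
                break
            mn[j] = mnmnj
    # concave-majorant successor chain
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (
                (xv[k] - xv[mjk]) * (mjk - mjmjk)
                < (xv[mjk] - xv[mjmjk]) * (k - mjk)
            ):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in ECDF count units; enforces the 1/(2n) lower bound
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    while True:
        # GCM change points walked from high down to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = i - 1
        # LCM change points walked from low up to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # largest vertical separation between the GCM and LCM curves
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next knot comes from the LCM: measure there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (
                        (xv[lcmiv] - xv[gcmi1])
                        * (gcmix - gcmi1)
                        / (xv[gcmix] - xv[gcmi1])
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next knot comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (
                        (xv[gcmix] - xv[lcmiv1])
                        * (lcmiv - lcmiv1)
                        / (xv[lcmiv] - xv[lcmiv1])
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # one-sided deviations of the ECDF from the two fits
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xv[je] != xv[jb]:
                C = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xv[jj] - xv[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xv[je] != xv[jb]:
                C = (je - jb) / (xv[je] - xv[jb])
                for jj in range(jb, je + 1):
                    t = (xv[jj] - xv[jb]) * C - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t
        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break  # modal interval stopped shrinking
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


@lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int) -> np.ndarray:
    """Sorted dip statistics of ``n_boot`` uniform(0,1) samples of size n."""
    rng = np.random.default_rng(np.random.SeedSequence((_NULL_TABLE_SEED, n, n_boot)))
    out = np.empty(n_boot)
    for b in range(n_boot):
        out[b] = dip_statistic(rng.random(n))
    out.sort()
    return out


def dip_test(values, *, n_boot: int = 2000) -> DipResult:
    """Test the sample against the unimodal null.

    The p-value is (1 + #{null dips >= observed}) / (n_boot + 1), with null
    dips drawn from uniform samples of the same size under a fixed internal
    seed, so repeated calls are deterministic.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"dip test needs at least 4 observations, got {x.size}")
    stat = dip_statistic(x)
    null = _null_dips(int(x.size), int(n_boot))
    n_ge = int(null.size - np.searchsorted(null, stat, side="left"))
    p = (1.0 + n_ge) / (n_boot + 1.0)
    return DipResult(statistic=stat, pvalue=p, n=int(x.size), n_boot=int(n_boot))
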