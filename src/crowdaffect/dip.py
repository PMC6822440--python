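"""Hartigan's dip statistic and a Monte-Carlo unimodality test.

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and the class of unimodal (convex-then-concave) CDFs.
It is computed by the classical interval-shrinking algorithm: fit the
greatest convex minorant (GCM) and least concave majorant (LCM) of the
empirical CDF on a candidate modal interval, measure their largest
discrepancy, record the maximal deviation of the ECDF from the two
envelopes outside the discrepancy region, and shrink the interval to
the enclosing touch points until no larger discrepancy remains.

Conventions (the ones used by the reference R implementation with its
default ``min.is.0 = FALSE``): the dip is floored at 1/(2n), so a
single observation has dip 0.5 and n tied observations have dip
1/(2n).

The null distribution for the p-value is sampled from the uniform
distribution on (0, 1) — the asymptotically least favourable unimodal
null — with the add-one Monte-Carlo estimator
``p = (1 + #{null >= observed}) / (B + 1)``.

The inner loops are numba-compiled; the first call in a process pays a
short JIT cost.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from numba import njit

from .exceptions import DegenerateInputError

DEFAULT_ALPHA = 0.05
DEFAULT_REPLICATES = 2000


@dataclass
class DipResult:
    dip: float
    p_value: float
    n: int
    n_replicates: int
    call: str  # "unimodal" | "multimodal"
    alpha: float

    def to_dict(self) -> dict:
        return asdict(self)


@njit(cache=True)
def _dip_sorted(x):  # pragma: no cover - exercised via dip_statistic
    """Dip of a sorted 1-D float array, in CDF units (floored at 1/(2n))."""
    n = x.shape[0]
    if n == 1 or x[n - 1] == x[0]:
        return 0.5 / n

    # Predecessor/successor links for the GCM and LCM fits over 0..n-1.
    mn = np.empty(n, np.int64)
    mj = np.empty(n, np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                x[mjk] - x[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low = 0
    high = n - 1
    dip = 1.0  # in count units; divided by 2n on return (1/(2n) floor)
    gcm = np.empty(n + 2, np.int64)  # 1-based change-point lists
    lcm = np.empty(n + 2, np.int64)

    while True:
        # GCM change points walked down from high to low,
        # LCM change points walked up from low to high.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = l_gcm
        ix = l_gcm - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = l_lcm
        iv = 2

        # Largest discrepancy (in counts) between the GCM and the LCM.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next envelope point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next envelope point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
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

        # Maximal deviation of the ECDF from the GCM (below the modal
        # interval) and from the LCM (above it), in counts.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break  # modal interval cannot shrink further
        low = gcm[ig]
        high = lcm[ih]
        if low >= high:
            break

    return dip / (2.0 * n)


@njit(cache=True)
def _dip_batch(rows):  # pragma: no cover - exercised via dip_pvalue
    """Dip of each (sorted) row of a 2-D array."""
    m = rows.shape[0]
    out = np.empty(m)
    for i in range(m):
        out[i] = _dip_sorted(rows[i])
    return out


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-D sample (sorted internally).

    Satisfies ``dip >= 1/(2n)``, with equality for maximally uniform
    samples; a single point has dip 0.5.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateInputError("dip statistic of an empty sample")
    if not np.isfinite(x).all():
        raise DegenerateInputError("sample contains non-finite values")
    return float(_dip_sorted(np.sort(x)))


@lru_cache(maxsize=64)
def _null_dips(n: int, n_replicates: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    u = rng.random((n_replicates, n))
    u.sort(axis=1)
    null = _dip_batch(u)
    null.sort()
    return null


def dip_pvalue(
    dip: float, n: int, n_replicates: int = DEFAULT_REPLICATES, seed: int = 0
) -> float:
    """Monte-Carlo p-value of an observed dip under the uniform null.

    Replicate dips are computed on ``n_replicates`` uniform(0,1)
    samples of size ``n``; deterministic for a fixed seed.
    """
    if n < 2:
        raise DegenerateInputError("p-value requires n >= 2")
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    null = _null_dips(n, n_replicates, int(seed))
    n_ge = n_replicates - int(np.searchsorted(null, dip, side="left"))
    return (1 + n_ge) / (n_replicates + 1)


def classify_modality(
    sample,
    alpha: float = DEFAULT_ALPHA,
    tie_policy: str = "jitter",
    seed: int = 0,
    n_replicates: int = DEFAULT_REPLICATES,
) -> DipResult:
    """Unimodal/multimodal call for one item's rating distribution.

    ``tie_policy='jitter'`` adds uniform noise in (-0.5, 0.5) to break
    the heavy ties of the discrete 1..9 scale before computing the dip
    (``'raw'`` uses the ratings as they are).  The call is multimodal
    iff the Monte-Carlo p-value falls below ``alpha``.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise DegenerateInputError(
            f"need >= 4 ratings for a modality call, got {x.size}"
        )
    jitter_seed, null_seed = np.random.SeedSequence(int(seed)).spawn(2)
    if tie_policy == "jitter":
        rng = np.random.default_rng(jitter_seed)
        x = x + rng.uniform(-0.5, 0.5, size=x.size)
    elif tie_policy != "raw":
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    dip = dip_statistic(x)
    p = dip_pvalue(
        dip, x.size, n_replicates=n_replicates, seed=int(null_seed.generate_state(1)[0] % 2**31)
    )
    return DipResult(
        dip=dip,
        p_value=p,
        n=int(x.size),
        n_replicates=n_replicates,
        call="multimodal" if p < alpha else "unimodal",
        alpha=alpha,
    )
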