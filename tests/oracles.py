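"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths:

* ``icc_oracle`` recomputes the two-way ANOVA decomposition with
  explicit python loops that materialize every (i, j) deviation.
* ``dip_oracle`` minimizes the sup-norm distance between the empirical
  CDF and the unimodal (convex-then-concave) CDF class by linear
  programming, enumerating every candidate mode location, and applies
  the 1/(2n) floor convention.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------- ICC oracle
def anova_oracle(values):
    """Two-way mean squares by explicit loops (no vectorization)."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i]) / k for i in range(n)]
    col_means = [sum(values[:, j]) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (values[i][j] - row_means[i] - col_means[j] + grand) ** 2
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1)), n, k


def icc_oracle(values, definition):
    msr, msc, mse, n, k = anova_oracle(values)
    if definition == "consistency":
        denom = msr + (k - 1) * mse
    elif definition == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        raise ValueError(definition)
    return (msr - mse) / denom


# ---------------------------------------------------------------- dip oracle
#
# A unimodal CDF G with mode m is convex on (-inf, m] and concave on
# [m, inf); it may jump only at m.  For the sup-norm distance to the
# ECDF only the values of G at the unique sample points matter (between
# points G can always be routed monotonically), with one subtlety: the
# chord connecting the blocks.  A mode strictly inside a gap
# (x_j, x_{j+1}) is feasible iff the bridging chord's slope is at least
# min(last convex chord, first concave chord), which is exactly the
# union of the two "continuous mode at x_j / at x_{j+1}" problems.  So
# enumerating, for every unique point j,
#   (a) a continuous mode at x_j  (convex chain 0..j, concave j..K-1,
#       sharing g_j), and
#   (b) an atom at x_j            (left/right limits g-, g+ decoupled),
# covers the whole class.  Each candidate is a small LP in the g values
# and the sup-distance t.


def _solve_lp(n_vars, constraints, bounds):
    """minimize t (last variable) subject to A x <= b."""
    c = np.zeros(n_vars)
    c[-1] = 1.0
    a_ub = np.array([row for row, _ in constraints])
    b_ub = np.array([rhs for _, rhs in constraints])
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return res.fun if res.success else np.inf


def _dip_lp(vals, c_right, c_left, mode, atom):
    K = len(vals)
    if atom:
        # g_0..g_{K-1} (g[mode] is the right limit), gminus, t
        n_vars = K + 2
        gm, ti = K, K + 1
        left_idx = list(range(mode)) + [gm]
        right_idx = list(range(mode, K))
        left_x = [vals[i] for i in range(mode)] + [vals[mode]]
        right_x = [vals[i] for i in range(mode, K)]
        chain = list(range(mode)) + [gm] + list(range(mode, K))
    else:
        n_vars = K + 1
        ti = K
        left_idx = list(range(mode + 1))
        right_idx = list(range(mode, K))
        left_x = [vals[i] for i in left_idx]
        right_x = [vals[i] for i in right_idx]
        chain = list(range(K))

    cons = []

    def dev(var, target):  # |g_var - target| <= t
        row = np.zeros(n_vars)
        row[var], row[ti] = 1.0, -1.0
        cons.append((row.copy(), target))
        row[var] = -1.0
        cons.append((row, -target))

    for i in range(K):
        if atom and i == mode:
            dev(i, c_right[i])   # right limit vs F(x)
            dev(gm, c_left[i])   # left limit vs F(x-)
        else:
            dev(i, c_right[i])
            dev(i, c_left[i])

    for a, b in zip(chain[:-1], chain[1:]):  # monotone nondecreasing
        row = np.zeros(n_vars)
        row[a], row[b] = 1.0, -1.0
        cons.append((row, 0.0))

    def shape_chain(idx, xs, convex):
        # chord-slope monotonicity as a linear constraint on each triple
        for (a, xa), (b, xb), (c, xc) in zip(
            zip(idx[:-2], xs[:-2]), zip(idx[1:-1], xs[1:-1]), zip(idx[2:], xs[2:])
        ):
            row = np.zeros(n_vars)
            row[a] += xc - xb
            row[b] += -(xc - xa)
            row[c] += xb - xa
            # row . g >= 0 is convexity; <= 0 is concavity
            cons.append((-row, 0.0) if convex else (row, 0.0))

    shape_chain(left_idx, left_x, convex=True)
    shape_chain(right_idx, right_x, convex=False)

    bounds = [(0.0, 1.0)] * (n_vars - 1) + [(0.0, None)]
    return _solve_lp(n_vars, cons, bounds)


def dip_oracle(sample):
    """Exact dip by LP minimization over unimodal CDFs, floored at 1/(2n)."""
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    vals, counts = np.unique(x, return_counts=True)
    c_right = np.cumsum(counts) / n
    c_left = np.concatenate([[0.0], c_right[:-1]])
    best = np.inf
    for mode in range(len(vals)):
        best = min(best, _dip_lp(vals, c_right, c_left, mode, atom=False))
        best = min(best, _dip_lp(vals, c_right, c_left, mode, atom=True))
    return max(float(best), 0.5 / n)
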