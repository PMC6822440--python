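"""Two-way random-effects, single-rater intraclass correlations.

Given an items x raters matrix the two-way crossed ANOVA (no
interaction replicates) decomposes the total sum of squares into a
row (subject/picture) term, a column (rater/run) term and a residual:

    SSR = k * sum_i (r_i - m)^2          msr = SSR / (n - 1)
    SSC = n * sum_j (c_j - m)^2          msc = SSC / (k - 1)
    SSE = sum_ij (x_ij - r_i - c_j + m)^2  mse = SSE / ((n-1)(k-1))

and the single-measurement ICCs are

    consistency  (msr - mse) / (msr + (k-1) mse)
    agreement    (msr - mse) / (msr + (k-1) mse + (k/n)(msc - mse))

The consistency form ignores additive per-rater shifts; the absolute
agreement form penalizes them.  Average-measure forms and confidence
intervals are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DegenerateInputError, MissingDataError, UndefinedICCError
from .ratings_io import RatingsMatrix

#: interpretation bands: estimate >= .75 is excellent, >= .4 fair, else poor
DEFAULT_BANDS = ((0.75, "excellent"), (0.4, "fair"))


@dataclass
class ICCResult:
    estimate: float
    definition: str  # "consistency" | "agreement"
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_raters: int
    n_dropped_rows: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, RatingsMatrix):
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def _complete_case(values: np.ndarray, missing_policy: str) -> tuple[np.ndarray, int]:
    missing_rows = ~np.isfinite(values).all(axis=1)
    if missing_rows.any():
        if missing_policy == "error":
            raise MissingDataError(
                f"{int(missing_rows.sum())} rows contain missing cells"
            )
        if missing_policy != "complete_case":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        values = values[~missing_rows]
    return values, int(missing_rows.sum())


def anova_mean_squares(
    matrix, missing_policy: str = "complete_case"
) -> tuple[float, float, float, int, int]:
    """Exact two-way mean squares (msr, msc, mse, n, k) of a matrix.

    Missing cells are handled by complete-case row deletion (default)
    or rejected outright with ``missing_policy='error'``.
    """
    values = _as_array(matrix)
    if values.ndim != 2:
        raise DegenerateInputError("expected a 2-D items x raters matrix")
    values, _ = _complete_case(values, missing_policy)
    n, k = values.shape
    if n < 2 or k < 2:
        raise DegenerateInputError(
            f"need >= 2 complete rows and >= 2 columns, got {n} x {k}"
        )
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    resid = values - row_means[:, None] - col_means[None, :] + grand
    sse = float((resid**2).sum())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def _icc(matrix, definition: str, missing_policy: str) -> ICCResult:
    values = _as_array(matrix)
    if values.ndim != 2:
        raise DegenerateInputError("expected a 2-D items x raters matrix")
    values, n_dropped = _complete_case(values, missing_policy)
    msr, msc, mse, n, k = anova_mean_squares(values, missing_policy="error")
    if definition == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise UndefinedICCError(f"zero-variance matrix: ICC {definition} undefined")
    return ICCResult(
        estimate=(msr - mse) / denom,
        definition=definition,
        msr=msr,
        msc=msc,
        mse=mse,
        n_subjects=n,
        k_raters=k,
        n_dropped_rows=n_dropped,
    )


def icc_consistency(matrix, missing_policy: str = "complete_case") -> ICCResult:
    """ICC(consistency), single measurement: rater shifts are ignored."""
    return _icc(matrix, "consistency", missing_policy)


def icc_agreement(matrix, missing_policy: str = "complete_case") -> ICCResult:
    """ICC(absolute agreement), single measurement: shifts are penalized."""
    return _icc(matrix, "agreement", missing_policy)


def interpret(estimate: float, bands=DEFAULT_BANDS) -> str:
    """Map an ICC estimate to a reliability band label.

    Defaults: >= .75 "excellent", >= .4 "fair", below "poor".
    """
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    for threshold, label in bands:
        if estimate >= threshold:
            return label
    return "poor"
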