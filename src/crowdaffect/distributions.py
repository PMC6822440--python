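"""Characterizing rating distributions.

Three analyses of how crowd opinions spread:

* :func:`sd_profile` — per-picture rating SD against the picture
  mean's distance from the neutral midpoint (ratings scatter most in
  the neutral range and least at the scale extremes);
* :func:`modality_summary` — per-picture unimodal/multimodal dip-test
  calls and the fraction of unimodal pictures per dimension;
* :func:`transfer_counts` — for a pair of pictures, how many workers
  stayed below (0-0) / above (1-1) the neutral value on both, switched
  sides, or were excluded (a neutral rating on either picture), the
  binarized opinion-transfer bookkeeping.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dip import DEFAULT_ALPHA, DEFAULT_REPLICATES, classify_modality
from .exceptions import EmptySelectionError, ValidationError
from .ratings_io import NEUTRAL, RATING_MAX, RATING_MIN, RatingsMatrix, RatingsTable, pivot_matrix

logger = logging.getLogger("crowdaffect")

#: sentinel returned by :func:`binarize` for the neutral rating
EXCLUDED = "excluded"


@dataclass
class TransferCounts:
    """Binarized opinion-transfer counts for one picture pair.

    Only workers who rated both pictures are counted; ``n_excluded``
    holds those with a neutral rating on either picture, so
    ``n00 + n11 + n_change + n_excluded`` equals the both-raters count.
    """

    picture_a: str
    picture_b: str
    n00: int
    n11: int
    n_change: int
    n_excluded: int

    @property
    def n_both(self) -> int:
        return self.n00 + self.n11 + self.n_change + self.n_excluded

    def switch_fraction(self) -> float:
        decided = self.n00 + self.n11 + self.n_change
        return self.n_change / decided if decided else float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def sd_profile(matrix: RatingsMatrix, n_bins: int = 4):
    """Per-picture (mean, sd) plus SD binned by distance from neutral.

    Pictures with fewer than 2 ratings are excluded (count logged).
    Returns ``(per_picture, binned, n_excluded)``.
    """
    values = np.asarray(matrix.values, dtype=float)
    counts = np.isfinite(values).sum(axis=1)
    ok = counts >= 2
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("sd_profile: %d picture(s) with < 2 ratings excluded", n_excluded)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(values[ok], axis=1)
        sds = np.nanstd(values[ok], axis=1, ddof=1)
    per_picture = pd.DataFrame(
        {
            "picture": [p for p, keep in zip(matrix.items, ok) if keep],
            "dimension": matrix.dimension,
            "population": matrix.population,
            "n": counts[ok].astype(int),
            "mean": means,
            "sd": sds,
        }
    )
    extremity = np.abs(means - NEUTRAL)
    edges = np.linspace(0.0, 4.0, n_bins + 1)
    bins = np.clip(np.digitize(extremity, edges) - 1, 0, n_bins - 1)
    binned = (
        pd.DataFrame({"bin": bins, "extremity": extremity, "sd": sds})
        .groupby("bin")
        .agg(extremity=("extremity", "mean"), mean_sd=("sd", "mean"), n_pictures=("sd", "size"))
        .reset_index()
    )
    binned["bin_low"] = edges[binned["bin"]]
    binned["bin_high"] = edges[binned["bin"] + 1]
    return per_picture, binned, n_excluded


def modality_summary(
    table: RatingsTable,
    dimension: str,
    population: str = "all",
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    tie_policy: str = "jitter",
    n_replicates: int = DEFAULT_REPLICATES,
):
    """Dip-test modality call for every picture of one dimension.

    Returns ``(fraction_unimodal, calls)`` where ``calls`` has one row
    per picture (n, dip, p_value, call).  Pictures with fewer than 4
    ratings are reported with call ``"insufficient"`` and do not enter
    the fraction.  Bit-reproducible for fixed seed and tie policy.
    """
    matrix = pivot_matrix(table, dimension, population)
    values = np.asarray(matrix.values, dtype=float)
    ss = np.random.SeedSequence(entropy=int(seed))
    children = ss.spawn(len(matrix.items))
    rows = []
    for i, picture in enumerate(matrix.items):
        sample = values[i][np.isfinite(values[i])]
        pic_seed = int(children[i].generate_state(1)[0] % 2**31)
        if sample.size < 4:
            rows.append(
                {
                    "picture": picture,
                    "dimension": dimension,
                    "population": population,
                    "n": int(sample.size),
                    "dip": float("nan"),
                    "p_value": float("nan"),
                    "call": "insufficient",
                }
            )
            continue
        res = classify_modality(
            sample, alpha=alpha, tie_policy=tie_policy, seed=pic_seed, n_replicates=n_replicates
        )
        rows.append(
            {
                "picture": picture,
                "dimension": dimension,
                "population": population,
                "n": res.n,
                "dip": res.dip,
                "p_value": res.p_value,
                "call": res.call,
            }
        )
    calls = pd.DataFrame(rows)
    valid = calls[calls["call"] != "insufficient"]
    if valid.empty:
        raise EmptySelectionError("no picture had enough ratings for a modality call")
    fraction_unimodal = float((valid["call"] == "unimodal").mean())
    return fraction_unimodal, calls


def binarize(rating: int, neutral: int = NEUTRAL):
    """Map a rating to 0 (below neutral), 1 (above), or ``EXCLUDED``."""
    rating = int(rating)
    if rating < RATING_MIN or rating > RATING_MAX:
        raise ValidationError(f"rating {rating} outside [{RATING_MIN}, {RATING_MAX}]")
    if rating == neutral:
        return EXCLUDED
    return int(rating > neutral)


def transfer_counts(
    table: RatingsTable, picture_a: str, picture_b: str, dimension: str
) -> TransferCounts:
    """Opinion-transfer counts over workers who rated both pictures."""
    df = table.records
    sub = df[(df["dimension"] == dimension) & (df["picture"].isin([picture_a, picture_b]))]
    for p in (picture_a, picture_b):
        if not (sub["picture"] == p).any():
            raise EmptySelectionError(f"picture {p!r} absent for dimension {dimension!r}")
    wide = sub.pivot_table(
        index="worker", columns="picture", values="rating", aggfunc="first"
    ).dropna()
    a = wide[picture_a].astype(int)
    b = wide[picture_b].astype(int)
    neutral = (a == NEUTRAL) | (b == NEUTRAL)
    below = (a < NEUTRAL) & (b < NEUTRAL) & ~neutral
    above = (a > NEUTRAL) & (b > NEUTRAL) & ~neutral
    change = ~neutral & ~below & ~above
    return TransferCounts(
        picture_a=picture_a,
        picture_b=picture_b,
        n00=int(below.sum()),
        n11=int(above.sum()),
        n_change=int(change.sum()),
        n_excluded=int(neutral.sum()),
    )


def multimodal_pairs(calls: pd.DataFrame, dimension: str | None = None) -> list[tuple]:
    """All unordered pairs of pictures called multimodal."""
    sub = calls
    if dimension is not None and "dimension" in calls.columns:
        sub = calls[calls["dimension"] == dimension]
    pictures = list(dict.fromkeys(sub[sub["call"] == "multimodal"]["picture"]))
    return list(itertools.combinations(pictures, 2))


def transfer_table(
    table: RatingsTable, pairs: list[tuple], dimension: str
) -> pd.DataFrame:
    """Transfer counts for a list of picture pairs, as a flat frame."""
    rows = [transfer_counts(table, a, b, dimension).to_dict() for a, b in pairs]
    return pd.DataFrame(
        rows, columns=["picture_a", "picture_b", "n00", "n11", "n_change", "n_excluded"]
    )
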