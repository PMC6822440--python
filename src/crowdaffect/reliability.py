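"""Rater-subsampling reliability curves.

A "crowdsourcing run" of size k is built by drawing, for every
picture, k ratings uniformly without replacement from that picture's
pool; repeating gives a pictures x runs grid of run means whose
ICC(consistency) measures how repeatable a campaign with k ratings per
picture would be.  Under the additive homoscedastic model the curve
has the closed form

    ICC(k) = sigma_p^2 / (sigma_p^2 + sigma_w^2 / k)

(:func:`analytic_icc`), which serves as the testing oracle.

Runs are drawn independently of each other, so they overlap in sampled
ratings whenever n_runs * k exceeds the pool — unavoidable for pools
of 30-50 ratings resampled into 30 runs of up to 15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InsufficientPoolError
from .icc import ICCResult, icc_consistency
from .ratings_io import RatingsMatrix

logger = logging.getLogger("crowdaffect")

DEFAULT_THRESHOLDS = {"excellent": 0.75, "fair": 0.4}


@dataclass
class SimConfig:
    """Run-simulation design: rating sizes, runs per size, seeding."""

    k_range: tuple = (1, 15)
    runs_per_k: int = 30
    seed: int = 0
    sampling: str = "per_picture_ratings"  # or "per_run_workers"
    n_dispersion: int = 10  # run-set replicates behind the icc_sd column
    strict: bool = False

    def ks(self) -> list[int]:
        lo, hi = self.k_range
        if lo < 1 or self.runs_per_k < 2:
            raise DegenerateInputError("k_range min >= 1 and runs_per_k >= 2 required")
        return list(range(lo, hi + 1))


@dataclass
class RunSet:
    """Per-run, per-picture means and SDs for one rating size k."""

    k: int
    means: np.ndarray  # pictures x runs
    sds: np.ndarray
    items: list[str] = field(default_factory=list)


@dataclass
class ReliabilityCurve:
    """Across-run ICC(consistency) per rating size k."""

    table: pd.DataFrame  # columns: k, icc, icc_sd, n_runs
    dimension: str = ""
    population: str = "all"

    def icc_at(self, k: int) -> float:
        row = self.table[self.table["k"] == k]
        return float(row["icc"].iloc[0]) if len(row) else float("nan")


def _pools(pool: RatingsMatrix) -> list[np.ndarray]:
    values = np.asarray(pool.values, dtype=float)
    return [row[np.isfinite(row)] for row in values]


def simulate_runs(
    pool: RatingsMatrix,
    k: int,
    n_runs: int,
    seed: int = 0,
    sampling: str = "per_picture_ratings",
) -> RunSet:
    """Draw ``n_runs`` simulated runs of k ratings per picture.

    Each run draws k ratings per picture uniformly without replacement
    from that picture's pool; runs are mutually independent.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if sampling == "per_run_workers":
        return _simulate_runs_workers(pool, k, n_runs, rng)
    if sampling != "per_picture_ratings":
        raise ValueError(f"unknown sampling mode {sampling!r}")

    values = np.asarray(pool.values, dtype=float)
    n_pics = values.shape[0]
    counts = np.isfinite(values).sum(axis=1)
    short = np.flatnonzero(counts < k)
    if short.size:
        names = [pool.items[i] for i in short[:5]]
        raise InsufficientPoolError(
            f"{short.size} picture(s) have fewer than k={k} ratings (e.g. {names})"
        )

    if np.isfinite(values).all():
        # rectangular pool: one vectorized draw
        m = values.shape[1]
        order = rng.random((n_runs, n_pics, m)).argpartition(k - 1, axis=2)[:, :, :k]
        sampled = np.take_along_axis(
            np.broadcast_to(values, (n_runs, n_pics, m)), order, axis=2
        )
        means = sampled.mean(axis=2).T
        sds = sampled.std(axis=2, ddof=1).T if k > 1 else np.zeros((n_pics, n_runs))
    else:
        pools = _pools(pool)
        means = np.empty((n_pics, n_runs))
        sds = np.zeros((n_pics, n_runs))
        for i, p in enumerate(pools):
            order = rng.random((n_runs, p.size)).argpartition(k - 1, axis=1)[:, :k]
            sampled = p[order]
            means[i] = sampled.mean(axis=1)
            if k > 1:
                sds[i] = sampled.std(axis=1, ddof=1)
    return RunSet(k=k, means=means, sds=sds, items=list(pool.items))


def _simulate_runs_workers(pool, k, n_runs, rng):
    """Sensitivity mode: sample k whole workers (columns) per run.

    With page-structured coverage a picture may end up with fewer than
    k (or zero) ratings in a run; run means average what is available
    and pictures with no rating get NaN (dropped complete-case by the
    ICC layer).
    """
    values = np.asarray(pool.values, dtype=float)
    n_pics, n_raters = values.shape
    if k > n_raters:
        raise InsufficientPoolError(f"k={k} exceeds the {n_raters} raters in the pool")
    means = np.full((n_pics, n_runs), np.nan)
    sds = np.zeros((n_pics, n_runs))
    for r in range(n_runs):
        cols = rng.choice(n_raters, size=k, replace=False)
        sub = values[:, cols]
        cnt = np.isfinite(sub).sum(axis=1)
        with np.errstate(invalid="ignore"):
            means[:, r] = np.where(cnt > 0, np.nanmean(sub, axis=1), np.nan)
            sds[:, r] = np.where(cnt > 1, np.nanstd(sub, axis=1, ddof=1), 0.0)
    return RunSet(k=k, means=means, sds=sds, items=list(pool.items))


def across_run_icc(runset: RunSet) -> ICCResult:
    """ICC(consistency) of the pictures x runs grid of run means."""
    if runset.means.shape[0] < 2 or runset.means.shape[1] < 2:
        raise DegenerateInputError("need >= 2 pictures and >= 2 runs")
    return icc_consistency(runset.means)


def analytic_icc(sigma2_picture: float, sigma2_within: float, k: int) -> float:
    """Closed-form across-run ICC under the additive homoscedastic model."""
    if sigma2_picture < 0 or sigma2_within < 0:
        raise ValueError("variances must be >= 0")
    if sigma2_picture == 0 and sigma2_within == 0:
        raise DegenerateInputError("both variance components are zero")
    if k < 1:
        raise ValueError("k must be >= 1")
    return sigma2_picture / (sigma2_picture + sigma2_within / k)


def reliability_curve(pool: RatingsMatrix, config: SimConfig) -> ReliabilityCurve:
    """Across-run ICC for every k in the configured range.

    The per-k estimate comes from one run set; its dispersion (the
    ``icc_sd`` column) from ``n_dispersion`` further independent run
    sets.  Rating sizes the pool cannot support are dropped with a
    warning (or raise in strict mode).
    """
    counts = np.isfinite(np.asarray(pool.values, dtype=float)).sum(axis=1)
    max_k = int(counts.min()) if counts.size else 0
    rows = []
    ss = np.random.SeedSequence(config.seed)
    ks = config.ks()
    seeds = ss.spawn(len(ks))
    for k, k_seed in zip(ks, seeds):
        if k > max_k and config.sampling == "per_picture_ratings":
            if config.strict:
                raise InsufficientPoolError(f"pool supports at most k={max_k}")
            logger.warning("k=%d exceeds the smallest pool (%d); truncated", k, max_k)
            continue
        reps = k_seed.spawn(max(config.n_dispersion, 0) + 1)
        estimates = [
            across_run_icc(
                simulate_runs(
                    pool,
                    k,
                    config.runs_per_k,
                    seed=rep,
                    sampling=config.sampling,
                )
            ).estimate
            for rep in reps
        ]
        rows.append(
            {
                "k": k,
                "icc": estimates[0],
                "icc_sd": float(np.std(estimates[1:], ddof=1))
                if len(estimates) >= 3
                else float("nan"),
                "n_runs": config.runs_per_k,
            }
        )
    return ReliabilityCurve(
        table=pd.DataFrame(rows, columns=["k", "icc", "icc_sd", "n_runs"]),
        dimension=pool.dimension,
        population=pool.population,
    )


def min_ratings(curve: ReliabilityCurve, threshold: float = 0.75):
    """Smallest k whose across-run ICC reaches ``threshold`` (else None)."""
    if curve.table.empty:
        raise DegenerateInputError("empty reliability curve")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    hits = curve.table[curve.table["icc"] >= threshold]
    return int(hits["k"].iloc[0]) if len(hits) else None
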