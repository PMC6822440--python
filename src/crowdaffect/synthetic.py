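"""Synthetic crowd-rating generator.

Emulates a crowdsourced affect-annotation campaign on the 9-point SAM
scale: a fixed picture set is split into pages; workers from two
populations (a careful "specialized" tier and a noisier "general"
tier) each rate whole pages on up to three dimensions (valence,
arousal, dominance).

Latent model for worker w rating picture p on dimension d:

    rating = round(clip(loc + b_w + eps, 1, 9))
    loc    = mu_pd                      (unimodal picture)
           = mu_pd + s_{w,theme(p)} * delta   (two-opinion picture)
    eps ~ N(0, sigma(mu_pd) * multiplier_pop)
    sigma(mu) = sigma_min + (sigma_max - sigma_min) * (1 - |mu - 5| / 4)

so rating noise peaks at the neutral midpoint of the scale and shrinks
toward the extremes.  b_w is a per-worker additive bias.  A configured
fraction of pictures carries a two-subgroup ("divisive") structure:
each such picture belongs to a theme, and every worker holds one
opinion sign s in {-1, +1} per theme, constant across all pictures of
that theme — this is the latent structure behind opinion transfer.

Gold labels are produced from an independent reference panel of
simulated raters (own seed stream, unit noise multiplier), with a
finite per-picture panel size akin to normative lab studies; gold
means are therefore themselves finite-sample estimates, not the
analytic mu.

Rounding uses numpy's round-half-to-even; ratings falling outside the
scale before clipping are counted and reported (kept rare by the
default noise levels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .ratings_io import DIMENSIONS, GoldTable, RatingsMatrix, RatingsTable

_CRowD, _GOLD, _LATENT = 1, 2, 0  # fixed sub-stream labels off the master seed


def sigma_profile(mu, sigma_min: float, sigma_max: float):
    """Residual rating SD as a function of the item's true mean."""
    mu = np.asarray(mu, dtype=float)
    return sigma_min + (sigma_max - sigma_min) * (1.0 - np.abs(mu - 5.0) / 4.0)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the simulated annotation campaign.

    Defaults mirror the reference campaign shape: 60 pictures in pages
    of 20, 30-50 ratings per picture and population, three SAM
    dimensions, a quarter of the pictures divisive with subgroup means
    mu +/- 2, and noise peaking at the neutral midpoint.
    """

    n_pictures: int = 60
    n_workers: int = 80  # per population
    populations: dict = field(
        default_factory=lambda: {"specialized": 1.0, "general": 1.3}
    )
    pool_range: tuple = (30, 50)  # target ratings per picture (per population)
    dimensions: tuple = DIMENSIONS
    mean_range: tuple = (2.0, 8.0)
    sigma_min: float = 0.4
    sigma_max: float = 0.6  # at the neutral midpoint
    rater_bias_sd: float = 0.25
    multimodal_fraction: float = 0.25
    separation: float = 2.0  # half-distance delta between subgroup means
    n_themes: int = 4
    page_size: int = 20
    gold_panel_size: int = 25
    gold_n_range: tuple = (8, 25)  # reference raters per picture
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.multimodal_fraction <= 1.0):
            raise ConfigurationError("multimodal_fraction must be in [0, 1]")
        if self.sigma_min > self.sigma_max:
            raise ConfigurationError("sigma_min must be <= sigma_max")
        if self.separation < 0:
            raise ConfigurationError("separation must be >= 0")
        lo, hi = self.mean_range
        if not (1.0 <= lo <= hi <= 9.0):
            raise ConfigurationError("mean_range must lie within [1, 9]")
        if self.pool_range[0] > self.pool_range[1] or self.pool_range[0] < 1:
            raise ConfigurationError("invalid pool_range")
        if self.pool_range[1] > self.n_workers:
            raise ConfigurationError(
                f"pool target up to {self.pool_range[1]} ratings/picture exceeds "
                f"the {self.n_workers} workers available per population"
            )
        unknown = set(self.dimensions) - set(DIMENSIONS)
        if unknown:
            raise ConfigurationError(f"unknown dimensions {sorted(unknown)}")
        if self.gold_n_range[1] > self.gold_panel_size:
            raise ConfigurationError("gold_n_range exceeds gold_panel_size")


@dataclass
class TruthTable:
    """Latent parameters behind a generated dataset (for assertions)."""

    pictures: pd.DataFrame  # picture, dimension, mu, multimodal, theme
    workers: pd.DataFrame  # population, worker, bias
    signs: pd.DataFrame  # population, worker, theme, sign
    config: dict
    clip_fraction: float = 0.0

    def theme_of(self, picture: str) -> str:
        row = self.pictures[self.pictures["picture"] == picture]
        return row["theme"].iloc[0]

    def multimodal_pictures(self) -> list[str]:
        sub = self.pictures[self.pictures["multimodal"]]
        return list(dict.fromkeys(sub["picture"]))

    def unimodal_pictures(self) -> list[str]:
        sub = self.pictures[~self.pictures["multimodal"]]
        return list(dict.fromkeys(sub["picture"]))

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "clip_fraction": self.clip_fraction,
            "pictures": self.pictures.to_dict(orient="records"),
            "workers": self.workers.to_dict(orient="records"),
            "signs": self.signs.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(label,)))


def _draw_latents(config: GeneratorConfig, rng: np.random.Generator):
    n = config.n_pictures
    pictures = [f"p{i:03d}" for i in range(n)]
    n_mm = int(round(config.multimodal_fraction * n))
    mm_idx = np.sort(rng.choice(n, size=n_mm, replace=False))
    mm_mask = np.zeros(n, dtype=bool)
    mm_mask[mm_idx] = True
    themes = np.array([""] * n, dtype=object)
    themes[mm_idx] = [f"t{rng.integers(config.n_themes)}" for _ in range(n_mm)]

    lo, hi = config.mean_range
    delta = config.separation
    # divisive pictures keep both subgroup means away from the scale ends
    mlo, mhi = max(lo, 1.0 + delta + 1.0), min(hi, 9.0 - delta - 1.0)
    if n_mm and mlo > mhi:
        raise ConfigurationError(
            f"separation {delta} leaves no room for subgroup means in {config.mean_range}"
        )
    rows = []
    for d in config.dimensions:
        mu = rng.uniform(lo, hi, size=n)
        if n_mm:
            mu[mm_idx] = rng.uniform(mlo, mhi, size=n_mm)
        for i, p in enumerate(pictures):
            rows.append(
                {
                    "picture": p,
                    "dimension": d,
                    "mu": float(mu[i]),
                    "multimodal": bool(mm_mask[i]),
                    "theme": themes[i],
                }
            )
    return pictures, pd.DataFrame(rows), mm_mask, themes


def _draw_population(config, rng, tag):
    ids = [f"w_{tag}_{i:03d}" for i in range(config.n_workers)]
    bias = rng.normal(0.0, config.rater_bias_sd, size=config.n_workers)
    signs = rng.choice([-1, 1], size=(config.n_workers, config.n_themes))
    return ids, bias, signs


def generate(config: GeneratorConfig) -> tuple[RatingsTable, TruthTable, GoldTable]:
    """Generate a ratings table, its latent truth, and matching gold labels.

    Deterministic: identical config (including seed) gives identical
    tables.  The crowd and the gold reference panel use separate
    sub-streams of the master seed.
    """
    config.validate()
    latent_rng = _rng(config.seed, _LATENT)
    crowd_rng = _rng(config.seed, _CRowD)
    gold_rng = _rng(config.seed, _GOLD)

    pictures, picture_df, mm_mask, themes = _draw_latents(config, latent_rng)
    dims = list(config.dimensions)
    n_dims = len(dims)
    mu_grid = (
        picture_df.pivot(index="picture", columns="dimension", values="mu")
        .loc[pictures, dims]
        .to_numpy()
    )
    theme_idx = np.array(
        [int(t[1:]) if t else -1 for t in themes], dtype=int
    )  # -1 = no theme

    n_pages = -(-config.n_pictures // config.page_size)
    page_of = np.arange(config.n_pictures) // config.page_size

    frames = []
    worker_rows, sign_rows = [], []
    n_clipped = n_total = 0
    for tag, multiplier in config.populations.items():
        ids, bias, signs = _draw_population(config, crowd_rng, tag)
        for i, w in enumerate(ids):
            worker_rows.append({"population": tag, "worker": w, "bias": float(bias[i])})
            for t in range(config.n_themes):
                sign_rows.append(
                    {
                        "population": tag,
                        "worker": w,
                        "theme": f"t{t}",
                        "sign": int(signs[i, t]),
                    }
                )
        # page-structured assignment: whole pages, 30-50 workers per page
        assign_w, assign_p = [], []
        for page in range(n_pages):
            count = int(crowd_rng.integers(config.pool_range[0], config.pool_range[1] + 1))
            chosen = crowd_rng.choice(config.n_workers, size=count, replace=False)
            page_pics = np.flatnonzero(page_of == page)
            for widx in chosen:
                assign_w.append(np.full(page_pics.size, widx))
                assign_p.append(page_pics)
        widx = np.concatenate(assign_w)
        pidx = np.concatenate(assign_p)

        widx_r = np.repeat(widx, n_dims)
        pidx_r = np.repeat(pidx, n_dims)
        didx_r = np.tile(np.arange(n_dims), widx.size)
        mu = mu_grid[pidx_r, didx_r]
        mm = mm_mask[pidx_r]
        sgn = np.where(
            theme_idx[pidx_r] >= 0,
            signs[widx_r, np.maximum(theme_idx[pidx_r], 0)],
            0,
        )
        values = mu + np.where(mm, sgn * config.separation, 0.0) + bias[widx_r]
        sd = sigma_profile(mu, config.sigma_min, config.sigma_max) * multiplier
        raw = values + crowd_rng.normal(0.0, 1.0, size=values.shape) * sd
        clipped = np.clip(raw, 1.0, 9.0)
        n_clipped += int((raw != clipped).sum())
        n_total += raw.size
        frames.append(
            pd.DataFrame(
                {
                    "worker": np.array(ids, dtype=object)[widx_r],
                    "picture": np.array(pictures, dtype=object)[pidx_r],
                    "dimension": np.array(dims, dtype=object)[didx_r],
                    "rating": np.rint(clipped).astype(int),
                    "population": tag,
                    "batch": np.char.add("page", (page_of[pidx_r]).astype(str)),
                }
            )
        )

    records = pd.concat(frames, ignore_index=True)
    truth = TruthTable(
        pictures=picture_df,
        workers=pd.DataFrame(worker_rows),
        signs=pd.DataFrame(sign_rows),
        config=_config_dict(config),
        clip_fraction=n_clipped / max(n_total, 1),
    )

    gold = _generate_gold(config, gold_rng, pictures, dims, mu_grid, mm_mask, theme_idx)
    table = RatingsTable(records=records, provenance=f"synthetic(seed={config.seed})")
    return table, truth, gold


def _generate_gold(config, rng, pictures, dims, mu_grid, mm_mask, theme_idx):
    """Gold labels from an independent finite reference panel."""
    m = config.gold_panel_size
    bias = rng.normal(0.0, config.rater_bias_sd, size=m)
    signs = rng.choice([-1, 1], size=(m, config.n_themes))
    rows = []
    for i, p in enumerate(pictures):
        n_ref = int(rng.integers(config.gold_n_range[0], config.gold_n_range[1] + 1))
        panel = rng.choice(m, size=n_ref, replace=False)
        for j, d in enumerate(dims):
            mu = mu_grid[i, j]
            sgn = signs[panel, max(theme_idx[i], 0)] if mm_mask[i] else 0.0
            loc = mu + (sgn * config.separation if mm_mask[i] else 0.0) + bias[panel]
            sd = sigma_profile(mu, config.sigma_min, config.sigma_max)
            raw = loc + rng.normal(0.0, 1.0, size=n_ref) * sd
            ratings = np.rint(np.clip(raw, 1.0, 9.0))
            rows.append(
                {
                    "picture": p,
                    "dimension": d,
                    "mean": float(ratings.mean()),
                    "sd": float(ratings.std(ddof=1)) if n_ref > 1 else 0.0,
                    "n": n_ref,
                }
            )
    return GoldTable(entries=pd.DataFrame(rows))


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["pool_range"] = list(d["pool_range"])
    d["dimensions"] = list(d["dimensions"])
    d["mean_range"] = list(d["mean_range"])
    d["gold_n_range"] = list(d["gold_n_range"])
    return d


def empirical_sd_check(table: RatingsTable, truth: TruthTable, n_bins: int = 4):
    """Generator self-check: per-picture rating SD binned by |mu - 5|.

    Restricted to unimodal pictures (subgroup structure inflates SD for
    reasons other than the noise profile).  Returns a frame with one
    row per bin: mean |mu-5|, mean per-picture SD, picture count.
    """
    uni = truth.pictures[~truth.pictures["multimodal"]]
    grouped = table.records.groupby(["picture", "dimension"])["rating"]
    stats = grouped.agg(["std", "count"]).reset_index()
    stats = stats.merge(
        uni[["picture", "dimension", "mu"]], on=["picture", "dimension"], how="inner"
    )
    stats["extremity"] = (stats["mu"] - 5.0).abs()
    edges = np.linspace(0.0, 4.0, n_bins + 1)
    stats["bin"] = np.clip(np.digitize(stats["extremity"], edges) - 1, 0, n_bins - 1)
    out = (
        stats.groupby("bin")
        .agg(extremity=("extremity", "mean"), mean_sd=("std", "mean"), n=("std", "size"))
        .reset_index()
    )
    return out


def gaussian_pool(
    n_pictures: int,
    pool_size: int,
    sigma2_picture: float,
    sigma2_within: float,
    seed: int = 0,
    center: float = 5.0,
) -> RatingsMatrix:
    """Additive homoscedastic rating pool with planted variance components.

    Picture means are standardized draws scaled to a sample variance of
    exactly ``sigma2_picture`` (planted, so reliability curves can be
    compared against the closed form sigma_p^2 / (sigma_p^2 +
    sigma_w^2 / k) without between-replicate variance in the planted
    component); ratings are real-valued, mean + N(0, sigma2_within),
    clipped to the scale (negligible at the default scales).
    """
    if n_pictures < 2:
        raise ConfigurationError("need >= 2 pictures")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_pictures)
    z = (z - z.mean()) / z.std(ddof=1)
    mu = center + z * np.sqrt(sigma2_picture)
    values = mu[:, None] + rng.normal(
        0.0, np.sqrt(sigma2_within), size=(n_pictures, pool_size)
    )
    values = np.clip(values, 1.0, 9.0)
    return RatingsMatrix(
        values=values,
        items=[f"p{i:03d}" for i in range(n_pictures)],
        raters=[f"r{i:03d}" for i in range(pool_size)],
        dimension="synthetic",
        population="all",
    )
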