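"""Quality of aggregated crowd labels against gold labels.

The crowd label of a picture is the mean over simulated runs of the
k-rating run mean (k = 8 by default, the typical normative-panel
size).  Quality is the absolute-agreement ICC between the crowd and
gold mean vectors (a pictures x 2 rater matrix), complemented by
per-picture deviation flags and a paired location test of systematic
shift per dimension with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, SchemaError
from .icc import ICCResult, icc_agreement, icc_consistency
from .ratings_io import GoldTable, RatingsMatrix
from .reliability import simulate_runs

DEFAULT_K = 8
DEFAULT_DEVIATION_THRESHOLD = 1.5


def aggregate_crowd(
    pool: RatingsMatrix, k: int = DEFAULT_K, n_runs: int = 30, seed: int = 0
) -> pd.Series:
    """Per-picture crowd mean over ``n_runs`` simulated k-rating runs."""
    runset = simulate_runs(pool, k, n_runs, seed=seed)
    return pd.Series(runset.means.mean(axis=1), index=runset.items, name="crowd_mean")


def _paired(crowd: pd.Series, gold: GoldTable, dimension: str) -> pd.DataFrame:
    gold_means = gold.lookup(dimension)["mean"]
    missing = [p for p in crowd.index if p not in gold_means.index]
    if missing:
        raise SchemaError(f"pictures without gold entry: {missing[:10]}")
    return pd.DataFrame({"crowd": crowd, "gold": gold_means.reindex(crowd.index)})


def agreement_with_gold(crowd: pd.Series, gold: GoldTable, dimension: str) -> ICCResult:
    """Absolute-agreement ICC of the pictures x (crowd, gold) matrix."""
    pair = _paired(crowd, gold, dimension)
    return icc_agreement(pair.to_numpy())


def consistency_with_gold(crowd: pd.Series, gold: GoldTable, dimension: str) -> ICCResult:
    """Consistency ICC of the same two-column matrix (shifts ignored)."""
    pair = _paired(crowd, gold, dimension)
    return icc_consistency(pair.to_numpy())


def deviation_flags(
    crowd: pd.Series,
    gold: GoldTable,
    dimension: str,
    threshold: float = DEFAULT_DEVIATION_THRESHOLD,
) -> pd.DataFrame:
    """Pictures whose crowd mean deviates from gold by >= threshold.

    Sorted by absolute deviation, largest first; ``delta`` is signed
    (crowd minus gold).
    """
    pair = _paired(crowd, gold, dimension)
    pair["delta"] = pair["crowd"] - pair["gold"]
    flagged = pair[pair["delta"].abs() >= threshold].copy()
    flagged = flagged.reindex(flagged["delta"].abs().sort_values(ascending=False).index)
    flagged.index.name = "picture"
    return flagged.reset_index().rename(columns={"crowd": "crowd_mean", "gold": "gold_mean"})


def mean_shift_test(
    crowd_by_dimension: dict[str, pd.Series],
    gold: GoldTable,
    correction: str = "bonferroni",
    test: str = "t",
) -> pd.DataFrame:
    """Paired location test of crowd vs gold means, per dimension.

    ``test='t'`` is a paired two-sided t-test on per-picture means;
    ``'wilcoxon'`` the signed-rank alternative (the choice is recorded
    in the output).  Bonferroni multiplies raw p-values by the number
    of dimensions tested (the family size).
    """
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    m = len(crowd_by_dimension)
    if m == 0:
        raise DegenerateInputError("no dimensions to test")
    rows = []
    for dimension, crowd in crowd_by_dimension.items():
        pair = _paired(crowd, gold, dimension)
        if len(pair) < 2:
            raise DegenerateInputError(f"{dimension}: need >= 2 matched pictures")
        diff = (pair["crowd"] - pair["gold"]).to_numpy()
        if np.allclose(diff.std(ddof=1), 0.0):
            raise DegenerateInputError(
                f"{dimension}: zero variance of crowd-gold differences"
            )
        if test == "t":
            stat, p_raw = stats.ttest_rel(pair["crowd"], pair["gold"])
        elif test == "wilcoxon":
            stat, p_raw = stats.wilcoxon(diff)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "dimension": dimension,
                "n": len(pair),
                "mean_diff": float(diff.mean()),
                "direction": "crowd_higher" if diff.mean() > 0 else "crowd_lower",
                "statistic": float(stat),
                "p_raw": float(p_raw),
                "p_corrected": float(min(1.0, p_raw * m)),
                "test": "paired_t" if test == "t" else "wilcoxon_signed_rank",
                "family_size": m,
            }
        )
    return pd.DataFrame(rows)
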