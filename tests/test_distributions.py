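import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import crowdaffect as ca


def _table(rows):
    df = pd.DataFrame(rows, columns=["worker", "picture", "dimension", "rating"])
    df["population"] = "all"
    df["batch"] = ""
    return ca.RatingsTable(records=df)


# ------------------------------------------------------------- sd_profile
def test_sd_profile_zero_for_unanimous_ratings():
    values = np.tile(np.array([[2.0], [8.0]]), (1, 6))
    m = ca.RatingsMatrix(values=values, items=["a", "b"], raters=list("rstuvw"),
                         dimension="valence")
    per_picture, binned, n_excluded = ca.sd_profile(m)
    assert (per_picture["sd"] == 0).all()
    assert (binned["mean_sd"] == 0).all()
    assert n_excluded == 0


def test_sd_profile_single_bin_is_average_of_sds():
    rng = np.random.default_rng(0)
    values = rng.integers(1, 10, size=(12, 9)).astype(float)
    m = ca.RatingsMatrix(values=values, items=[f"p{i}" for i in range(12)],
                         raters=[f"r{j}" for j in range(9)], dimension="valence")
    per_picture, binned, _ = ca.sd_profile(m, n_bins=1)
    assert binned["mean_sd"].iloc[0] == pytest.approx(per_picture["sd"].mean())


def test_sd_profile_excludes_underrated_pictures():
    values = np.full((3, 4), 5.0)
    values[2, 1:] = np.nan  # single rating
    m = ca.RatingsMatrix(values=values, items=list("abc"), raters=list("wxyz"),
                         dimension="valence")
    per_picture, _, n_excluded = ca.sd_profile(m)
    assert n_excluded == 1 and list(per_picture["picture"]) == ["a", "b"]


def test_sd_profile_heteroscedastic_neutral_above_extreme():
    cfg = ca.GeneratorConfig(
        sigma_min=0.5, sigma_max=2.0, rater_bias_sd=0.0, multimodal_fraction=0.0,
        n_pictures=200, page_size=20, n_workers=80,
        populations={"specialized": 1.0}, dimensions=("valence",), seed=14,
    )
    table, _, _ = ca.generate(cfg)
    _, binned, _ = ca.sd_profile(ca.pivot_matrix(table, "valence"))
    assert binned["mean_sd"].iloc[0] > binned["mean_sd"].iloc[-1]


# ------------------------------------------------------------- modality
def test_modality_summary_reproducible_and_mostly_unimodal():
    cfg = ca.GeneratorConfig(
        n_pictures=40, page_size=20, n_workers=50, pool_range=(35, 40),
        populations={"specialized": 1.0}, dimensions=("valence",),
        multimodal_fraction=0.0, seed=15,
    )
    table, _, _ = ca.generate(cfg)
    frac1, calls1 = ca.modality_summary(table, "valence", seed=99)
    frac2, calls2 = ca.modality_summary(table, "valence", seed=99)
    assert frac1 == frac2 and calls1.equals(calls2)
    # all pictures unimodal: false-positive rate near alpha
    assert frac1 >= 0.85


def test_modality_summary_insufficient_pictures_reported():
    rows = [("w%d" % i, "p1", "valence", 5) for i in range(10)]
    rows += [("w0", "p2", "valence", 4), ("w1", "p2", "valence", 6)]
    frac, calls = ca.modality_summary(_table(rows), "valence", seed=1)
    assert calls.set_index("picture").loc["p2", "call"] == "insufficient"
    assert frac == 1.0  # only p1 enters the fraction


def test_modality_summary_empty_selection():
    rows = [("w0", "p1", "valence", 5)] * 1
    with pytest.raises(ca.EmptySelectionError):
        ca.modality_summary(_table(rows), "arousal", seed=1)


# ------------------------------------------------------------- binarize
@pytest.mark.parametrize("rating,expected", [(1, 0), (2, 0), (4, 0), (6, 1), (8, 1), (9, 1)])
def test_binarize_sides(rating, expected):
    assert ca.binarize(rating) == expected


def test_binarize_neutral_excluded_and_range_checked():
    assert ca.binarize(5) is ca.EXCLUDED
    with pytest.raises(ca.ValidationError):
        ca.binarize(10)


# ------------------------------------------------------------- transfer
def test_transfer_counts_constructed_fixture():
    rows = []
    for i in range(6):
        rows += [(f"lo{i}", "pa", "arousal", 2), (f"lo{i}", "pb", "arousal", 2)]
    for i in range(4):
        rows += [(f"hi{i}", "pa", "arousal", 8), (f"hi{i}", "pb", "arousal", 8)]
    rows += [("sw", "pa", "arousal", 2), ("sw", "pb", "arousal", 8)]
    rows += [("nt", "pa", "arousal", 5), ("nt", "pb", "arousal", 7)]
    rows += [("only_a", "pa", "arousal", 3)]  # not counted at all
    tc = ca.transfer_counts(_table(rows), "pa", "pb", "arousal")
    assert (tc.n00, tc.n11, tc.n_change, tc.n_excluded) == (6, 4, 1, 1)
    assert tc.n_both == 12
    assert tc.switch_fraction() == pytest.approx(1 / 11)


def test_transfer_counts_missing_picture():
    rows = [("w", "pa", "arousal", 3)]
    with pytest.raises(ca.EmptySelectionError):
        ca.transfer_counts(_table(rows), "pa", "pz", "arousal")


@given(st.integers(0, 5_000))
def test_transfer_symmetry_and_conservation(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(rng.integers(2, 12)):
        for p in ("pa", "pb"):
            if rng.random() < 0.8:
                rows.append((f"w{w}", p, "arousal", int(rng.integers(1, 10))))
    table = _table(rows)
    df = table.records
    both = set(df[df.picture == "pa"].worker) & set(df[df.picture == "pb"].worker)
    try:
        ab = ca.transfer_counts(table, "pa", "pb", "arousal")
        ba = ca.transfer_counts(table, "pb", "pa", "arousal")
    except ca.EmptySelectionError:
        assert not (df.picture == "pa").any() or not (df.picture == "pb").any()
        return
    assert (ab.n00, ab.n11, ab.n_change, ab.n_excluded) == (
        ba.n00, ba.n11, ba.n_change, ba.n_excluded)
    assert ab.n_both == len(both)


@pytest.mark.parametrize("n_multimodal,n_pairs", [(0, 0), (1, 0), (3, 3), (5, 10)])
def test_multimodal_pairs_counts(n_multimodal, n_pairs):
    calls = pd.DataFrame(
        {
            "picture": [f"p{i}" for i in range(8)],
            "dimension": "arousal",
            "call": ["multimodal"] * n_multimodal + ["unimodal"] * (8 - n_multimodal),
        }
    )
    pairs = ca.multimodal_pairs(calls, "arousal")
    assert len(pairs) == n_pairs
    assert all(a != b for a, b in pairs)


def test_same_theme_pairs_switch_less_than_cross_theme():
    cfg = ca.GeneratorConfig(
        n_pictures=24, n_workers=60, populations={"specialized": 1.0},
        pool_range=(40, 40), dimensions=("arousal",), page_size=12,
        multimodal_fraction=0.5, separation=2.0, n_themes=3, seed=16,
    )
    table, truth, _ = ca.generate(cfg)
    mm = truth.multimodal_pictures()
    theme = {p: truth.theme_of(p) for p in mm}
    same, cross = [], []
    for a, b in itertools.combinations(mm, 2):
        tc = ca.transfer_counts(table, a, b, "arousal")
        (same if theme[a] == theme[b] else cross).append(tc.switch_fraction())
    assert np.nanmean(same) < np.nanmean(cross)
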