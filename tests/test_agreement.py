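import numpy as np
import pandas as pd
import pytest

import crowdaffect as ca
from oracles import icc_oracle


def _gold(pictures, means, dimension="valence"):
    return ca.GoldTable(entries=pd.DataFrame({
        "picture": pictures, "dimension": dimension,
        "mean": means, "sd": 1.0, "n": 10,
    }))


def _crowd(pictures, means):
    return pd.Series(means, index=pictures, name="crowd_mean")


def test_aggregate_crowd_exhaustive_equals_pool_mean():
    pool = ca.gaussian_pool(30, 12, 0.4, 0.4, seed=0)
    crowd = ca.aggregate_crowd(pool, k=12, n_runs=5, seed=1)
    np.testing.assert_allclose(crowd.to_numpy(), pool.values.mean(axis=1))


def test_aggregate_crowd_noise_free_pool():
    values = np.tile(np.array([[2.0], [7.0]]), (1, 10))
    pool = ca.RatingsMatrix(values=values, items=["a", "b"], raters=[f"r{i}" for i in range(10)],
                            dimension="valence")
    crowd = ca.aggregate_crowd(pool, k=4, n_runs=8, seed=2)
    assert crowd.tolist() == [2.0, 7.0]


def test_identical_crowd_and_gold_agree_perfectly():
    pics = [f"p{i}" for i in range(60)]
    means = np.linspace(1.5, 8.5, 60)
    res = ca.agreement_with_gold(_crowd(pics, means), _gold(pics, means), "valence")
    assert res.estimate == pytest.approx(1.0)
    assert ca.consistency_with_gold(
        _crowd(pics, means), _gold(pics, means), "valence").estimate == pytest.approx(1.0)


def test_constant_shift_separates_definitions():
    pics = [f"p{i}" for i in range(60)]
    gold_means = np.linspace(1.5, 7.5, 60)
    crowd = _crowd(pics, gold_means + 1.0)
    gold = _gold(pics, gold_means)
    assert ca.consistency_with_gold(crowd, gold, "valence").estimate == pytest.approx(1.0)
    assert ca.agreement_with_gold(crowd, gold, "valence").estimate < 1.0


@pytest.mark.parametrize("seed", range(4))
def test_agreement_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    pics = [f"p{i}" for i in range(20)]
    crowd_means = rng.uniform(2, 8, 20)
    gold_means = rng.uniform(2, 8, 20)
    res = ca.agreement_with_gold(_crowd(pics, crowd_means), _gold(pics, gold_means), "valence")
    expected = icc_oracle(np.column_stack([crowd_means, gold_means]), "agreement")
    assert res.estimate == pytest.approx(expected, abs=1e-10)


def test_unmatched_pictures_is_join_error():
    pics = ["p0", "p1", "p2"]
    crowd = _crowd(pics + ["p3"], [2, 3, 4, 5.0])
    with pytest.raises(ca.SchemaError, match="p3"):
        ca.agreement_with_gold(crowd, _gold(pics, [2, 3, 4.0]), "valence")


def test_deviation_flags_thresholding_and_order():
    pics = [f"p{i}" for i in range(10)]
    gold_means = np.full(10, 5.0)
    crowd_means = gold_means.copy()
    crowd_means[3] += 2.0
    crowd_means[7] -= 1.7
    gold = _gold(pics, gold_means)
    flags = ca.deviation_flags(_crowd(pics, crowd_means), gold, "valence", threshold=1.5)
    assert flags["picture"].tolist() == ["p3", "p7"]
    assert flags["delta"].tolist() == pytest.approx([2.0, -1.7])
    assert ca.deviation_flags(_crowd(pics, gold_means), gold, "valence").empty
    everything = ca.deviation_flags(_crowd(pics, crowd_means), gold, "valence", threshold=0.0)
    assert len(everything) == 10
    assert everything["delta"].abs().is_monotonic_decreasing


def test_deviation_flags_invariant_to_input_order():
    rng = np.random.default_rng(1)
    pics = [f"p{i}" for i in range(12)]
    crowd_means = rng.uniform(2, 8, 12)
    gold = _gold(pics, np.full(12, 5.0))
    a = ca.deviation_flags(_crowd(pics, crowd_means), gold, "valence", 0.5)
    perm = rng.permutation(12)
    b = ca.deviation_flags(
        _crowd([pics[i] for i in perm], crowd_means[perm]), gold, "valence", 0.5)
    assert a["picture"].tolist() == b["picture"].tolist()


def test_mean_shift_zero_variance_is_degenerate():
    pics = [f"p{i}" for i in range(10)]
    means = np.linspace(2, 8, 10)
    with pytest.raises(ca.DegenerateInputError):
        ca.mean_shift_test({"valence": _crowd(pics, means)}, _gold(pics, means))


def test_mean_shift_detects_planted_shift():
    rng = np.random.default_rng(2)
    pics = [f"p{i}" for i in range(60)]
    gold_means = rng.uniform(2, 7, 60)
    crowd = _crowd(pics, gold_means + 0.5 + rng.normal(0, 0.2, 60))
    out = ca.mean_shift_test({"valence": crowd}, _gold(pics, gold_means))
    row = out.iloc[0]
    assert row["p_corrected"] < 0.05
    assert row["direction"] == "crowd_higher"
    assert row["p_corrected"] >= row["p_raw"]
    assert row["family_size"] == 1 and row["p_corrected"] == row["p_raw"]


def test_mean_shift_bonferroni_family_and_wilcoxon():
    rng = np.random.default_rng(3)
    pics = [f"p{i}" for i in range(40)]
    entries = []
    crowd = {}
    for dim in ("valence", "arousal"):
        gm = rng.uniform(2, 7, 40)
        entries.append(pd.DataFrame({
            "picture": pics, "dimension": dim, "mean": gm, "sd": 1.0, "n": 10}))
        crowd[dim] = _crowd(pics, gm + rng.normal(0, 0.3, 40))
    gold = ca.GoldTable(entries=pd.concat(entries, ignore_index=True))
    out_t = ca.mean_shift_test(crowd, gold)
    assert (out_t["family_size"] == 2).all()
    assert (out_t["p_corrected"] >= out_t["p_raw"]).all()
    out_w = ca.mean_shift_test(crowd, gold, test="wilcoxon")
    assert set(out_w["test"]) == {"wilcoxon_signed_rank"}


def test_mean_shift_type_i_rate_near_alpha():
    rng = np.random.default_rng(4)
    pics = [f"p{i}" for i in range(60)]
    rejections = 0
    trials = 200
    for _ in range(trials):
        gm = rng.uniform(2, 7, 60)
        crowd = _crowd(pics, gm + rng.normal(0, 0.3, 60))
        out = ca.mean_shift_test({"valence": crowd}, _gold(pics, gm))
        rejections += out["p_raw"].iloc[0] < 0.05
    assert 0.01 <= rejections / trials <= 0.10
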