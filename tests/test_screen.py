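import numpy as np
import pandas as pd
import pytest

from texrad.pipeline import FeatureTable
from texrad.screen import holm_bonferroni, mann_whitney_u, screen_table

from _oracles import oracle_mann_whitney_u


def test_u_example_exact():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_u_identical_samples_symmetry():
    x = [1.0, 2.0, 3.0]
    u, _ = mann_whitney_u(x, x)
    assert u == pytest.approx(len(x) * len(x) / 2)


def test_u_empty_sample_raises():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@pytest.mark.parametrize("seed", range(10))
def test_u_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.permutation(np.arange(10, dtype=float))[:4]
    y = rng.normal(size=5) + 50  # distinct values, no ties
    u, p = mann_whitney_u(x, y)
    u_want, p_want = oracle_mann_whitney_u(list(x), list(y))
    assert u == pytest.approx(u_want)
    assert p == pytest.approx(p_want, abs=1e-12)


def test_u_monotone_transform_invariance(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=25) + 0.5
    u1, p1 = mann_whitney_u(x, y)
    u2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
    assert u1 == u2 and p1 == pytest.approx(p2)


def test_holm_all_rejected():
    reject, adj = holm_bonferroni([0.001, 0.01, 0.04], alpha=0.05)
    assert reject.all()
    np.testing.assert_allclose(adj, [0.003, 0.02, 0.04])


def test_holm_none_rejected():
    reject, _ = holm_bonferroni([0.04, 0.04, 0.04], alpha=0.05)
    assert not reject.any()


def test_holm_single_test_plain_alpha():
    reject, adj = holm_bonferroni([0.04], alpha=0.05)
    assert reject[0] and adj[0] == pytest.approx(0.04)


def test_holm_stepdown_stops_at_first_failure():
    # second-smallest fails its threshold (0.03 > 0.05/2): everything at or
    # after it is retained, even 0.04 which passes the plain-alpha test
    reject, _ = holm_bonferroni([0.001, 0.03, 0.04], alpha=0.05)
    assert reject.tolist() == [True, False, False]


def test_holm_rejects_between_bonferroni_and_uncorrected(rng):
    for _ in range(20):
        p = rng.random(15)
        alpha = 0.05
        holm, _ = holm_bonferroni(p, alpha)
        bonf = p <= alpha / len(p)
        raw = p < alpha
        assert (holm | ~bonf).all()  # Holm superset of Bonferroni
        assert (~holm | raw).all()   # Holm subset of uncorrected


def test_holm_invalid_p_raises():
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.2])


def make_screen_table(rng, n_per_class=20, n_features=10, shift=None,
                      sequences=("T2W",), tissues=("NAWM",)):
    n = 2 * n_per_class
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    cols = {}
    for seq in sequences:
        for tis in tissues:
            for j in range(n_features):
                col = rng.normal(size=n)
                if shift is not None and j == 0:
                    col[labels == 1] += shift
                cols[f"{seq}:{tis}:F{j:02d}"] = col
    data = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return FeatureTable(data=data, labels=pd.Series(labels, index=data.index))


def test_screen_injected_shift_detected(rng):
    t = make_screen_table(rng, n_per_class=30, shift=3.0)
    res = screen_table(t)
    assert res.per_feature.loc["T2W:NAWM:F00", "reject_holm"]
    assert res.n_rejected <= res.n_significant_raw


def test_screen_summary_shape(rng):
    t = make_screen_table(rng, sequences=("FLAIR", "T2W"), tissues=("NAWM", "WMH"))
    res = screen_table(t)
    assert res.summary.shape == (2, 2)
    assert set(res.summary.index) == {"FLAIR", "T2W"}
    cell = res.summary.loc["T2W", "WMH"]
    before, after = (int(v) for v in cell.split(" / "))
    assert after <= before


def test_screen_single_class_raises(rng):
    t = make_screen_table(rng)
    t = FeatureTable(t.data, pd.Series(0, index=t.data.index), t.provenance)
    with pytest.raises(ValueError):
        screen_table(t)


def test_screen_pooled_family_more_conservative(rng):
    t = make_screen_table(rng, n_per_class=30, shift=1.5,
                          sequences=("FLAIR", "T2W"))
    per_dataset = screen_table(t, family="per_dataset")
    pooled = screen_table(t, family="pooled")
    assert pooled.n_rejected <= per_dataset.n_rejected


def test_screen_duplicating_rows_keeps_ordering_invariant(rng):
    t = make_screen_table(rng, n_per_class=15, shift=2.0)
    data2 = pd.concat([t.data, t.data.set_axis([f"d{i}" for i in range(len(t.data))])])
    labels2 = pd.Series(np.concatenate([t.labels, t.labels]), index=data2.index)
    t2 = FeatureTable(data=data2, labels=labels2)
    res2 = screen_table(t2)
    assert res2.n_rejected <= res2.n_significant_raw
    assert res2.per_feature.loc["T2W:NAWM:F00", "reject_holm"]
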