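import numpy as np
import pandas as pd
import pytest

from neuroherd.stats import (
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    median_ci,
    significance_stars,
    summarize_study,
)


def test_kruskal_wallis_hand_ranked_example():
    """Three tie-free groups with rank sums 6, 15, 24 give H = 7.2."""
    H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert H == pytest.approx(7.2)
    assert 0 < p < 0.05


def test_kruskal_wallis_degenerate_and_errors():
    assert kruskal_wallis([[5, 5], [5, 5, 5], [5]]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


def test_two_group_equivalence_h_equals_z_squared():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
    H, _ = kruskal_wallis([a, b])
    z = dunn_posthoc([a, b]).z.iloc[0]
    assert H == pytest.approx(z ** 2, rel=1e-9)


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(1)
    groups = [rng.normal(i * 0.3, 1, 9) for i in range(3)]
    H1, p1 = kruskal_wallis(groups)
    H2, p2 = kruskal_wallis([np.exp(g) for g in groups])
    assert H1 == pytest.approx(H2) and p1 == pytest.approx(p2)
    d1 = dunn_posthoc(groups)
    d2 = dunn_posthoc([np.exp(g) for g in groups])
    assert np.allclose(d1.z, d2.z)


def test_permutation_symmetry():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i, 1, 8) for i in range(3)]
    H1, _ = kruskal_wallis(groups)
    H2, _ = kruskal_wallis(groups[::-1])
    assert H1 == pytest.approx(H2)
    p1 = sorted(dunn_posthoc(groups).p_raw)
    p2 = sorted(dunn_posthoc(groups[::-1]).p_raw)
    assert np.allclose(p1, p2)


def test_dunn_identical_groups():
    d = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
    assert d.z.iloc[0] == pytest.approx(0.0)
    assert d.p_raw.iloc[0] == pytest.approx(1.0)


def test_dunn_separation_monotonicity():
    d = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], labels=["a", "b", "c"])
    p_far = d[(d.group_a == "a") & (d.group_b == "c")].p_raw.iloc[0]
    p_near = d[(d.group_a == "a") & (d.group_b == "b")].p_raw.iloc[0]
    assert p_far < p_near


def test_dunn_holm_adjustment_never_smaller():
    rng = np.random.default_rng(3)
    groups = [rng.normal(i * 0.7, 1, 10) for i in range(4)]
    raw = dunn_posthoc(groups, adjust="none")
    holm = dunn_posthoc(groups, adjust="holm")
    assert np.all(holm.p_adj.to_numpy() >= raw.p_raw.to_numpy() - 1e-12)
    with pytest.raises(ValueError):
        dunn_posthoc(groups, adjust="fdr")


def test_median_ci_degenerate_inputs():
    med, lo, hi = median_ci([7.0] * 10, seed=0)
    assert med == lo == hi == 7.0
    med, lo, hi = median_ci(list(range(1, 10)), seed=0)
    assert med == 5.0 and 1.0 <= lo <= 5.0 <= hi <= 9.0
    with pytest.warns(UserWarning):
        med, lo, hi = median_ci([1.0, 2.0], seed=0)
    assert np.isnan(lo) and np.isnan(hi)


def test_median_ci_deterministic_under_seed():
    x = np.random.default_rng(4).normal(0, 1, 25)
    assert median_ci(x, seed=11) == median_ci(x, seed=11)


def test_median_ci_coverage_simulation():
    """Percentile-bootstrap CI of the median covers the true median close
    to the nominal 95 % for normal samples of n = 20."""
    rng = np.random.default_rng(7)
    cov = 0
    n_sim = 1000
    for _ in range(n_sim):
        x = rng.normal(0, 1, 20)
        _, lo, hi = median_ci(x, n_boot=2000, seed=int(rng.integers(1 << 30)))
        cov += lo <= 0.0 <= hi
    assert 0.93 <= cov / n_sim <= 0.97


def test_significance_stars():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.05) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(1e-3) == "***"
    assert significance_stars(1e-5) == "****"


def _toy_results(shift=0.0, n=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in enumerate([0.0, 0.0, shift]):
        for v in rng.normal(mu, 1.0, n):
            rows.append({"label": f"g{g}", "G": v})
    return pd.DataFrame(rows)


def test_compare_groups_and_summary_layout():
    df = _toy_results(shift=2.0, seed=5)
    gc = compare_groups(df, "label", "G", seed=0)
    assert set(gc.summary["group"]) == {"g0", "g1", "g2"}
    assert gc.H is not None and gc.p < 0.05
    assert len(gc.dunn) == 3
    summary, comps = summarize_study(df, axes=["label"], metrics=["G"], seed=0)
    assert len(summary) == 3
    assert ("label", "G") in comps
    with pytest.raises(KeyError):
        compare_groups(df, "nope", "G")
    with pytest.raises(KeyError):
        compare_groups(df, "label", "nope")


def test_single_group_skips_omnibus():
    df = _toy_results().query("label == 'g0'")
    gc = compare_groups(df, "label", "G", seed=0)
    assert gc.H is None and gc.dunn is None
    assert len(gc.summary) == 1


def test_power_at_large_shift():
    """A 1.5 sigma group shift is flagged by Dunn in >= 80 % of replicate
    studies at alpha = 0.05 (n = 12 per group)."""
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(50):
        groups = [rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)]
        d = dunn_posthoc(groups, labels=["a", "b", "c"])
        p = d[(d.group_a == "a") & (d.group_b == "c")].p_raw.iloc[0]
        hits += p < 0.05
    assert hits / 50 >= 0.8
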