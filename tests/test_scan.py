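"""Z-transformation, ΔSNP contrast, top-quantile selection and NJ utilities."""

import numpy as np
import pandas as pd
import pytest

import divscan as ds
from divscan.scan import pair_key


# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------

def test_z_transform_linear_example():
    z = ds.z_transform(np.array([0.01, 0.02, 0.03]))
    assert z == pytest.approx([-1.0, 0.0, 1.0])


def test_z_transform_degenerate_stratum_rejected():
    with pytest.raises(ValueError, match="zero standard deviation"):
        ds.z_transform(np.array([0.5, 0.5, 0.5]))
    with pytest.raises(ValueError, match=">=2"):
        ds.z_transform(np.array([0.5]))


def test_z_transform_standardizes_each_stratum():
    rng = np.random.default_rng(2)
    x = rng.normal(0.03, 0.005, size=10_000)
    cls = np.where(np.arange(10_000) % 2 == 0, "autosome", "Z")
    z = ds.z_transform(x, cls)
    for c in ("autosome", "Z"):
        sub = z[cls == c]
        assert abs(sub.mean()) < 0.02
        assert 0.98 <= sub.std(ddof=1) <= 1.02


# ---------------------------------------------------------------------------
# delta
# ---------------------------------------------------------------------------

def test_delta_is_focal_minus_max_control():
    assert ds.delta_snp(2.0, [0.5, -1.0, 0.3]) == pytest.approx(1.5)


def test_delta_zero_when_focal_equals_controls():
    assert ds.delta_snp(0.7, [0.7, 0.7]) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _delta_frame(deltas, cls="autosome"):
    n = len(deltas)
    df = pd.DataFrame({
        "window_id": [f"c:{i}" for i in range(n)],
        "chrom": "c", "start": np.arange(n) * 10_000,
        "end": (np.arange(n) + 1) * 10_000,
        "class": cls, "pass_filter": True,
        "delta:f|o": np.asarray(deltas, dtype=float),
    })
    return df


def _design():
    return ds.ComparisonDesign("f", [("f", "o")], [("o2", "o3")],
                               classes=("autosome",))


def test_top_quantile_matches_sort_oracle():
    rng = np.random.default_rng(3)
    deltas = rng.permutation(np.linspace(-3, 3, 100))
    sel = ds.select_top_quantile(_delta_frame(deltas), _design())
    thr = np.quantile(deltas, 0.99)
    oracle = {f"c:{i}" for i, d in enumerate(deltas) if d >= thr}
    assert sel.per_focal["f|o"] == oracle
    assert 1 <= len(oracle) <= 2
    # argmax always selected
    assert f"c:{int(np.argmax(deltas))}" in sel.per_focal["f|o"]


def test_all_equal_deltas_all_selected():
    sel = ds.select_top_quantile(_delta_frame([1.0] * 10), _design())
    assert len(sel.per_focal["f|o"]) == 10


def test_median_quantile_on_four_values():
    design = _design()
    design.quantile = 0.5
    sel = ds.select_top_quantile(_delta_frame([1, 2, 3, 4]), design)
    assert sel.per_focal["f|o"] == {"c:2", "c:3"}  # threshold 2.5


def test_small_stratum_warns_but_selects(caplog):
    with caplog.at_level("WARNING", logger="divscan"):
        sel = ds.select_top_quantile(_delta_frame([1.0, 5.0]), _design())
    assert len(sel.per_focal["f|o"]) >= 1
    assert "selecting at least" in caplog.text


def test_intersection_examples():
    assert ds.intersect_selected([{"A", "B"}, {"B", "C"}, {"B"}]) == {"B"}
    assert ds.intersect_selected([{"A"}, {"B"}]) == set()


def test_design_validation():
    with pytest.raises(ValueError):
        ds.ComparisonDesign("f", [("a", "b")], [("c", "d")])
    with pytest.raises(ValueError):
        ds.ComparisonDesign("f", [("f", "b")], [])
    with pytest.raises(ValueError):
        ds.ComparisonDesign("f", [("f", "b")], [("f", "c")])


def _toy_stats(rng, n=400):
    df = pd.DataFrame({
        "window_id": [f"c:{i}" for i in range(n)],
        "chrom": "c", "start": np.arange(n) * 10_000,
        "end": (np.arange(n) + 1) * 10_000,
        "class": "autosome", "pass_filter": True,
    })
    for pair in ("f|a", "f|b", "a|b"):
        df[f"prop:{pair}"] = rng.normal(0.03, 0.005, n)
        df[f"aligned:{pair}"] = 9_000
        df[f"snp:{pair}"] = (df[f"prop:{pair}"] * 9_000).astype(int)
    return df


def test_shift_equivariance_of_scan():
    """Adding a constant to every proportion of one comparison changes no
    z value, delta or selection (location invariance of standardization)."""
    rng = np.random.default_rng(8)
    stats = _toy_stats(rng)
    design = ds.ComparisonDesign("f", [("f", "a"), ("f", "b")], [("a", "b")],
                                 classes=("autosome",))
    base = ds.compute_delta_table(stats, design)
    shifted = stats.copy()
    shifted["prop:f|a"] = shifted["prop:f|a"] + 0.017
    other = ds.compute_delta_table(shifted, design)
    for col in ("z:f|a", "delta:f|a", "delta:f|b"):
        assert np.allclose(base[col], other[col], equal_nan=True)
    assert (ds.select_top_quantile(base, design).intersection
            == ds.select_top_quantile(other, design).intersection)


def test_windows_failing_filter_never_selected():
    rng = np.random.default_rng(9)
    stats = _toy_stats(rng)
    stats.loc[stats.index[:50], "pass_filter"] = False
    design = ds.ComparisonDesign("f", [("f", "a")], [("a", "b")],
                                 classes=("autosome",))
    delta = ds.compute_delta_table(stats, design)
    assert delta.loc[~delta["pass_filter"], "delta:f|a"].isna().all()
    sel = ds.select_top_quantile(delta, design)
    failed = set(delta.loc[~delta["pass_filter"], "window_id"])
    assert not (sel.per_focal["f|a"] & failed)


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

def test_paf_distance_examples():
    rec = ds.PafRecord("q", 100, 0, 100, "+", "t", 100, 0, 100, 95, 100, 60)
    assert ds.estimate_pairwise_distance([rec]) == pytest.approx(0.05)
    same = ds.PafRecord("q", 100, 0, 100, "+", "t", 100, 0, 100, 100, 100, 60)
    assert ds.estimate_pairwise_distance([same]) == 0.0
    with pytest.raises(ValueError):
        ds.estimate_pairwise_distance([])


def _dm(d, taxa):
    return pd.DataFrame(d, index=taxa, columns=taxa)


def test_nj_three_taxon_closed_form():
    # d(A,B)=0.2, d(A,C)=d(B,C)=0.4 -> branches 0.1, 0.1, 0.3
    dm = _dm([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]], list("ABC"))
    newick = ds.build_nj_tree(dm)
    pat = ds.tree_patristic_distances(newick)
    assert np.allclose(pat.loc[list("ABC"), list("ABC")].to_numpy(),
                       dm.to_numpy(), atol=1e-9)


def _random_tree_distances(rng, n):
    """Random binary tree by sequential joining; returns exact leaf distances."""
    taxa = [f"t{i}" for i in range(n)]
    # depth[x] accumulates distance from leaf x up to its current cluster root
    clusters = [{t: 0.0 for t in taxa[i:i + 1]} for i in range(n)]
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(0.05, 1.0, size=2)
        ci, cj = clusters[i], clusters[j]
        for a, da in ci.items():
            for b, db in cj.items():
                d.loc[a, b] = d.loc[b, a] = da + bi + db + bj
        merged = {a: da + bi for a, da in ci.items()}
        merged.update({b: db + bj for b, db in cj.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return d


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_nj_recovers_additive_matrices_exactly(n):
    rng = np.random.default_rng(40 + n)
    for _ in range(5):
        dm = _random_tree_distances(rng, n)
        pat = ds.tree_patristic_distances(ds.build_nj_tree(dm))
        taxa = list(dm.index)
        assert np.allclose(pat.loc[taxa, taxa].to_numpy(), dm.to_numpy(),
                           atol=1e-8)


def test_nj_star_distances_give_zero_internal_branch():
    dm = _dm([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]],
             list("ABCD"))
    pat = ds.tree_patristic_distances(ds.build_nj_tree(dm))
    assert np.allclose(pat.to_numpy()[~np.eye(4, dtype=bool)], 1.0, atol=1e-9)


def test_nj_two_taxa_single_branch():
    newick = ds.build_nj_tree(_dm([[0, 0.3], [0.3, 0]], ["A", "B"]))
    pat = ds.tree_patristic_distances(newick)
    assert pat.loc["A", "B"] == pytest.approx(0.3)


def test_nj_deterministic_under_taxon_reordering():
    dm = _random_tree_distances(np.random.default_rng(99), 5)
    taxa = list(dm.index)
    shuffled = dm.loc[taxa[::-1], taxa[::-1]]
    assert ds.build_nj_tree(dm) == ds.build_nj_tree(shuffled)
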