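import numpy as np
import pytest
from scipy.stats import ks_2samp, kstest, mannwhitneyu

from clonalcircuits import spatial_clonal as sp
from clonalcircuits.errors import ValidationError
from clonalcircuits.simcircuit import CloneSet, make_clonal_pattern


def _cs(points, ids=None, labels=None):
    points = np.asarray(points, float)
    n = len(points)
    ids = np.arange(n) if ids is None else np.asarray(ids)
    labels = np.array(["EGFP"] * n) if labels is None else np.asarray(labels)
    return CloneSet(points, ids, labels)


def test_collinear_nnd():
    cs = _cs([[0, 0, 0], [10, 0, 0], [30, 0, 0]])
    assert np.array_equal(sp.nnd(cs, "all").distances_um, [10.0, 10.0, 20.0])


def test_nnd_needs_two_points():
    with pytest.raises(ValidationError):
        sp.nnd(_cs([[0, 0, 0]]), "all")


def test_nnd_cdf_properties():
    rng = np.random.default_rng(0)
    cs = _cs(rng.uniform(0, 100, (50, 3)))
    res = sp.nnd(cs, "all")
    d, F = res.cdf_table()
    assert np.all(np.diff(F) >= 0)
    assert F[-1] == 1.0
    assert res.cdf(-1.0)[0] == 0.0
    assert res.cdf(d.max())[0] == 1.0


def test_nnd_rigid_motion_invariance():
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 100, (60, 3))
    theta = 0.7
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = pts @ R.T + np.array([5.0, -3.0, 10.0])
    d1 = np.sort(sp.nnd(_cs(pts), "all").distances_um)
    d2 = np.sort(sp.nnd(_cs(moved), "all").distances_um)
    assert np.allclose(d1, d2)


def test_poisson_nnd_matches_analytic_law():
    rng = np.random.default_rng(4)
    L, n = 400.0, 5000
    cs = _cs(rng.uniform(0, L, (n, 3)))
    d = sp.nnd(cs, "all").distances_um
    ks = kstest(d, lambda x: sp.poisson_nnd_cdf(x, n / L**3))
    assert ks.statistic < 0.05


def test_clustered_within_vs_cross_label_contrast():
    cs = make_clonal_pattern(
        40, 4, 50.0, 800.0**3, 1.0, seed=5, labels=("EGFP", "mCherry")
    )
    w = sp.nnd(cs, "within-label").distances_um
    x = sp.nnd(cs, "cross-label").distances_um
    assert ks_2samp(w, x).pvalue < 0.001
    assert np.median(w) < np.median(x)


def test_cross_label_requires_two_labels():
    with pytest.raises(ValidationError):
        sp.nnd(_cs([[0, 0, 0], [1, 0, 0]]), "cross-label")
    with pytest.raises(ValidationError):
        sp.nnd(_cs([[0, 0, 0], [1, 0, 0]]), "bogus-rule")


def test_clonal_distance_counting():
    cs = _cs(
        [[0, 0, 0], [1, 0, 0], [100, 0, 0], [101, 0, 0]], ids=[1, 1, 2, 2]
    )
    r = sp.clonal_distances(cs)
    assert len(r.intra_um) == 2 and len(r.inter_um) == 4
    n = len(cs)
    assert len(r.intra_um) + len(r.inter_um) == n * (n - 1) // 2


def test_degenerate_clones_have_zero_intra():
    cs = make_clonal_pattern(5, 3, 0.0, 500.0**3, 1.0, seed=6)
    r = sp.clonal_distances(cs)
    assert np.allclose(r.intra_um, 0.0)
    assert np.all(r.inter_um > 0)


def test_no_multicell_clone_warns():
    cs = _cs([[0, 0, 0], [50, 0, 0]], ids=[1, 2])
    with pytest.warns(UserWarning):
        r = sp.clonal_distances(cs)
    assert r.intra_um.size == 0


def test_clustered_intra_shorter_and_shuffle_abolishes_it():
    base = make_clonal_pattern(20, 4, 50.0, 600.0**3, 1.0, seed=7)
    r = sp.clonal_distances(base)
    assert mannwhitneyu(r.intra_um, r.inter_um).pvalue < 0.001
    n_sig = 0
    for s in range(20):
        ids = np.random.default_rng(s).permutation(base.clone_ids)
        rs = sp.clonal_distances(CloneSet(base.points_um, ids, base.fluor_labels))
        if mannwhitneyu(rs.intra_um, rs.inter_um).pvalue < 0.05:
            n_sig += 1
    assert n_sig <= 3  # ~5% nominal false-positive rate under the shuffle null


def test_same_barcode_fraction_trivials():
    one_clone = _cs([[0, 0, 0], [1, 0, 0], [2, 0, 0]], ids=[1, 1, 1])
    assert sp.same_barcode_fraction(one_clone, 10.0) == (1.0, 3)
    singletons = _cs([[0, 0, 0], [1, 0, 0], [2, 0, 0]], ids=[1, 2, 3])
    assert sp.same_barcode_fraction(singletons, 10.0) == (0.0, 3)
    frac, n = sp.same_barcode_fraction(singletons, 0.5)
    assert frac is None and n == 0


def test_same_barcode_fraction_matches_brute_force():
    cs = make_clonal_pattern(15, 3, 40.0, 500.0**3, 1.0, seed=8)
    frac, n_pairs = sp.same_barcode_fraction(cs, 200.0)
    same = tot = 0
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            if np.linalg.norm(cs.points_um[i] - cs.points_um[j]) <= 200.0:
                tot += 1
                same += cs.clone_ids[i] == cs.clone_ids[j]
    assert n_pairs == tot
    assert frac == pytest.approx(same / tot)


def test_linkage_single_hand_example():
    cs = _cs([[0, 0, 0], [1, 0, 0], [10, 0, 0]])
    Z = sp.linkage_dendrogram(cs)
    assert np.allclose(Z[:, 2], [1.0, 9.0])


def test_linkage_matches_brute_force_single_linkage():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 100, (15, 3))
    Z = sp.linkage_dendrogram(_cs(pts))
    # O(n^3) reimplementation of single linkage merge heights
    clusters = [{i} for i in range(len(pts))]
    heights = []
    from scipy.spatial.distance import cdist

    D = cdist(pts, pts)
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    assert np.allclose(np.sort(Z[:, 2]), np.sort(heights))


def test_newick_structure():
    cs = _cs([[0, 0, 0], [1, 0, 0], [10, 0, 0]])
    nwk = sp.linkage_to_newick(sp.linkage_dendrogram(cs), ["a", "b", "c"])
    assert nwk.endswith(";")
    assert nwk.count(",") == 2  # n leaves -> n-1 internal merges


def test_cloneset_csv_round_trip(tmp_path):
    cs = make_clonal_pattern(8, 3, 30.0, 400.0**3, 1.0, seed=10, labels=("EGFP", "mCherry"))
    p = tmp_path / "cs.csv"
    sp.write_cloneset_csv(cs, p)
    back = sp.read_cloneset_csv(p)
    assert np.array_equal(back.points_um, cs.points_um)
    assert (back.clone_ids.astype(str) == cs.clone_ids.astype(str)).all()
    assert (back.fluor_labels == cs.fluor_labels).all()


def test_barcoded_ingestion(tmp_path):
    p = tmp_path / "bc.csv"
    p.write_text("x,y,z,barcode,region\n0,0,0,A,ctx\n1,1,0,A,ctx\n500,0,0,B,ctx\n")
    cs = sp.read_barcoded_csv(p)
    assert len(cs) == 3 and cs.region == "ctx"
    frac, n = sp.same_barcode_fraction(cs, 450.0)
    assert frac == 1.0 and n == 1
    bad = tmp_path / "bad.csv"
    bad.write_text("x,y\n0,0\n")
    with pytest.raises(ValidationError):
        sp.read_barcoded_csv(bad)


def test_barcoded_column_mapping(tmp_path):
    p = tmp_path / "bc.csv"
    p.write_text("pos_x,pos_y,pos_z,tag\n0,0,0,A\n5,0,0,A\n")
    cs = sp.read_barcoded_csv(
        p, column_map={"pos_x": "x", "pos_y": "y", "pos_z": "z", "tag": "barcode"}
    )
    assert len(cs) == 2 and (cs.clone_ids == "A").all()
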