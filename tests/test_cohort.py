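import numpy as np
import pandas as pd
import pytest

from clonalcircuits import cohort_stats as cs
from clonalcircuits.connectivity_detect import (
    ChemicalResult,
    ConnectionResult,
)
from clonalcircuits.errors import DegenerateTableError, ValidationError
from clonalcircuits.simcircuit import simulate_pair_cohort


def test_rate_rounding_half_up():
    assert cs.rate(27, 80) == 33.8
    assert cs.rate(0, 10) == 0.0
    assert cs.rate(49, 79) == 62.0
    assert cs.rate(11, 34) == 32.4
    assert cs.rate(1, 16) == 6.3  # 6.25 rounds up, not to even
    assert cs.rate(10, 10) == 100.0


def test_rate_validation():
    with pytest.raises(ValidationError):
        cs.rate(1, 0)
    with pytest.raises(ValidationError):
        cs.rate(5, 4)
    with pytest.raises(ValidationError):
        cs.rate(-1, 4)


def test_significance_label_boundaries():
    assert cs.significance_label(0.0005) == "p<0.001"
    assert cs.significance_label(0.005) == "p<0.01"
    assert cs.significance_label(0.03) == "p<0.05"
    assert cs.significance_label(0.05) == "NS"
    assert cs.significance_label(0.9) == "NS"


def test_compare_rates_identical_groups():
    r = cs.compare_rates([(10, 40), (10, 40)])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)
    assert not r.significant


def test_compare_rates_matches_scipy_2x2():
    from scipy.stats import chi2_contingency

    r = cs.compare_rates([(27, 80), (59, 462)])
    stat, p, *_ = chi2_contingency([[27, 53], [59, 403]], correction=False)
    assert r.statistic == pytest.approx(stat)
    assert r.p_value == pytest.approx(p)
    assert cs.significance_label(r.p_value) == "p<0.001"


def test_compare_rates_fisher_and_validation():
    r = cs.compare_rates([(9, 31), (6, 60)], method="fisher")
    assert r.test == "fisher" and r.p_value < 0.05
    with pytest.raises(ValidationError):
        cs.compare_rates([(1, 5)])
    with pytest.raises(ValidationError):
        cs.compare_rates([(1, 5), (2, 5), (3, 5)], method="fisher")
    with pytest.raises(ValidationError):
        cs.compare_rates([(1, 5), (2, 5)], method="bogus")
    with pytest.raises(ValidationError):
        cs.compare_rates([(6, 5), (2, 5)])


def test_compare_rates_degenerate_margin():
    with pytest.raises(DegenerateTableError):
        cs.compare_rates([(0, 10), (0, 5)])
    with pytest.raises(DegenerateTableError):
        cs.compare_rates([(10, 10), (5, 5)])


def test_pair_record_vocabulary():
    ok = dict(
        pair_id=0,
        lineage_class="sparse_cluster",
        subtype_pair="nonFS_nonFS",
        intersoma_dist_um=30.0,
        age_P=14,
        layer="L2_3",
        area="SCX",
        electrical=True,
        chemical="uni",
    )
    cs.PairRecord(**ok)
    with pytest.raises(ValidationError):
        cs.PairRecord(**{**ok, "lineage_class": "other"})
    with pytest.raises(ValidationError):
        cs.PairRecord(**{**ok, "chemical": "yes"})
    with pytest.raises(ValidationError):
        cs.PairRecord(**{**ok, "intersoma_dist_um": -1.0})


def test_stratified_rates_conserve_counts():
    df = simulate_pair_cohort(
        {"sparse_cluster": 120, "non_lineage": 200},
        {"sparse_cluster": 0.4, "non_lineage": 0.12},
        seed=3,
    )
    for strat in ("lineage", "subtype", "distance_bins", "age_bins", "layer"):
        out = cs.stratified_rates(df, strat)
        assert out["n"].sum() == len(df)
        assert out["k"].sum() == int(df["electrical"].sum())


def test_stratified_rates_recover_generating_rates():
    df = simulate_pair_cohort(
        {"sparse_cluster": 400, "non_lineage": 400},
        {"sparse_cluster": 0.5, "non_lineage": 0.1},
        seed=4,
    )
    out = cs.stratified_rates(df, "lineage")
    by_cls = out.set_index("lineage_class")
    assert by_cls.loc["sparse_cluster", "rate_percent"] == pytest.approx(50.0, abs=6)
    assert by_cls.loc["non_lineage", "rate_percent"] == pytest.approx(10.0, abs=4)
    assert out["p_value"].iloc[0] < 0.001


def test_stratified_rates_empty_strata_and_errors():
    df = simulate_pair_cohort({"sparse_cluster": 40}, {"sparse_cluster": 0.5}, seed=5)
    out = cs.stratified_rates(df, "distance_bins")
    absent = out[out["lineage_class"] == "non_lineage"]
    assert (absent["n"] == 0).all()
    # only one class present: no contrast to run
    assert out[out["n"] > 0]["p_value"].isna().all()
    with pytest.raises(ValidationError):
        cs.stratified_rates(df, "bogus")
    with pytest.raises(ValidationError):
        cs.stratified_rates(df, "lineage", outcome="bogus")
    with pytest.raises(ValidationError):
        cs.stratified_rates(df.iloc[:0], "lineage")


def test_independence_on_independent_cohorts():
    """When electrical and chemical outcomes are generated independently the
    cross-modality tests should be NS in all but ~5% of cohorts."""
    n_ns = 0
    for seed in range(20):
        df = simulate_pair_cohort(
            {"sparse_cluster": 150, "non_lineage": 150},
            {"sparse_cluster": 0.35, "non_lineage": 0.35},
            seed=1000 + seed,
        )
        res = cs.electrical_chemical_independence(df)
        if res["electrical_by_chemical"].p_value >= 0.05:
            n_ns += 1
    assert n_ns >= 17


def test_independence_detects_nested_dependence():
    """If chemical connections occur only among coupled pairs, both tests
    must come out strongly significant."""
    rows = []
    rng = np.random.default_rng(6)
    for i in range(300):
        elec = bool(rng.random() < 0.4)
        chem = "uni" if (elec and rng.random() < 0.6) else "none"
        rows.append(
            cs.PairRecord(i, "sparse_cluster", "nonFS_nonFS", 30.0, 14,
                          "L2_3", "SCX", elec, chem)
        )
    res = cs.electrical_chemical_independence(rows)
    assert res["electrical_by_chemical"].p_value < 0.001
    assert res["chemical_by_electrical"].p_value < 0.001


def _fake_result(pair, elec, chem_edges):
    chem = {
        d: ChemicalResult(d[0], d[1], d in chem_edges, 5.0, 2.0, 3.0, 20, 30)
        for d in (pair, pair[::-1])
    }
    return ConnectionResult(pair, elec, 0.1 if elec else 0.0,
                            chemical_by_direction=chem)


def _quadruple_session(elec, i_to_pn, j_to_pn, pn_ids=(2,)):
    """Two interneurons (0, 1) plus optional PNs, with chosen chemistry."""
    chem_edges = set()
    if i_to_pn:
        chem_edges |= {(0, p) for p in pn_ids}
    if j_to_pn:
        chem_edges |= {(1, p) for p in pn_ids}
    cells = [0, 1, *pn_ids]
    results = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            pair = (cells[a], cells[b])
            results.append(_fake_result(pair, elec and pair == (0, 1), chem_edges))
    meta = {"lineage_class": "sparse_cluster"}
    return (meta, (0, 1), tuple(pn_ids), results)


def test_pair_records_from_connections():
    sessions = [
        _quadruple_session(True, True, True),     # coupled, coordinated
        _quadruple_session(True, True, False),    # coupled, not coordinated
        _quadruple_session(False, True, True),    # uncoupled, coordinated
        (_quadruple_session(False, False, False)[0], (0, 1), (), []),  # no PN
    ]
    df, excluded = cs.pair_records_from_connections(sessions)
    assert excluded == 1 and len(df) == 3
    assert list(df["both_output_to_common_PN"]) == [True, False, True]
    assert list(df["electrical"]) == [True, True, False]
    with pytest.raises(ValidationError):
        cs.pair_records_from_connections([({}, (0,), (2,), [])])


def test_coordinated_output_contrast():
    sessions = []
    rng = np.random.default_rng(7)
    for _ in range(120):
        elec = bool(rng.random() < 0.5)
        p_coord = 0.7 if elec else 0.1
        both = rng.random() < p_coord
        sessions.append(_quadruple_session(elec, True, both))
    df, _ = cs.pair_records_from_connections(sessions)
    out = cs.coordinated_output(df)
    sub = out.set_index("coupling")
    assert sub.loc["coupled", "rate_percent"] > sub.loc["uncoupled", "rate_percent"]
    assert sub["p_value"].iloc[0] < 0.001
    assert sub.loc["coupled", "n"] + sub.loc["uncoupled", "n"] == len(df)


def test_coordinated_output_requires_pn_calls():
    rec = cs.PairRecord(0, "sparse_cluster", "nonFS_nonFS", 30.0, 14, "L2_3",
                        "SCX", True, "none", both_output_to_common_PN=None)
    with pytest.raises(ValidationError):
        cs.coordinated_output([rec])


def test_fixture_counts_are_self_consistent():
    counts = cs.load_paper_counts()
    assert set(counts.columns) >= {"analysis", "group", "k", "n", "printed_pct"}
    for _, row in counts.dropna(subset=["printed_pct"]).iterrows():
        assert cs.rate(int(row.k), int(row.n)) == float(row.printed_pct), row.group


def test_fixture_distance_rate():
    counts = cs.load_paper_counts()
    d = counts[counts.analysis == "coupling_by_distance"].set_index("group")
    far = d[d.index.str.contains("far|150|non", case=False, regex=True)]
    assert (far.printed_pct == 4.5).any()


def test_fixture_independence_tests_are_ns():
    counts = cs.load_paper_counts().set_index(["analysis", "group"])

    def kn(analysis):
        sub = counts.loc[analysis]
        return [(int(r.k), int(r.n)) for _, r in sub.iterrows()]

    assert cs.compare_rates(kn("electrical_by_chemical_status")).p_value >= 0.05
    assert cs.compare_rates(kn("chemical_by_electrical_status")).p_value >= 0.05


def test_reproduce_paper_report_no_failures():
    rep = cs.reproduce_paper_report()
    assert set(rep["status"]) <= {"PASS", "NOT_PRINTED"}
    assert (rep["status"] == "PASS").sum() >= 30
    assert not (rep["status"] == "FAIL").any()
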