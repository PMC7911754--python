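import numpy as np
import pytest
from scipy.stats import binom, fisher_exact

from _oracles import exact_fisher_two_sided
from poccnv.classify import CnvCall, SpecimenResult
from poccnv.cohort import (
    age_bin,
    build_cohort_tables,
    cluster_recurrent_cnvs,
    compare_cnv_frequency,
    compare_counts,
    fisher_exact_2x2,
    round_half_up,
    stratify_by_age,
    tables_from_counts,
)
from poccnv.io import load_table1_counts, load_table2_counts
from poccnv.simulate import SpecimenMeta


def make_result(sid, category):
    return SpecimenResult(specimen_id=sid, category=category)


def make_meta(sid, group="SA", count=1, age=30.0):
    return SpecimenMeta(sid, group, count, age, "snp_array")


def dup(chrom, start, end, band="16q11", mosaic=1.0):
    return CnvCall(chrom, start, end, "dup", end - start, mosaic, band)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def test_half_up_rounding_boundaries():
    assert round_half_up(2.5, 0) == 3
    assert round_half_up(0.625, 2) == 0.63
    assert round_half_up(63.905, 0) == 64


def test_packaged_counts_reproduce_printed_percentages():
    """The fixture counts reproduce the series' printed whole-cohort rates."""
    tables = tables_from_counts(load_table1_counts(), load_table2_counts())
    assert tables.n_cohort == 1556 and tables.n_abnormal == 895
    t1 = tables.table1.set_index("stratum")
    assert t1.loc["total", "abnormal_pct"] == 57.52
    assert t1.loc["total", "normal_pct"] == 42.48
    assert t1.loc["1", "frequency_pct"] == 34.70
    assert t1.loc["2", "frequency_pct"] == 37.66
    assert t1.loc["4+", "frequency_pct"] == 9.45
    # normal / abnormal columns, whole-cohort denominator
    assert t1.loc["1", "normal_pct"] == 16.84 and t1.loc["1", "abnormal_pct"] == 17.87
    assert t1.loc["2", "normal_pct"] == 13.37 and t1.loc["2", "abnormal_pct"] == 24.29
    assert t1.loc["3", "normal_pct"] == 7.84 and t1.loc["3", "abnormal_pct"] == 10.35
    assert t1.loc["4+", "normal_pct"] == 4.43 and t1.loc["4+", "abnormal_pct"] == 5.01
    # the 283/1556 stratum is 18.19 under half-up arithmetic
    assert t1.loc["3", "frequency_pct"] == 18.19


def test_packaged_counts_reproduce_category_percentages():
    tables = tables_from_counts(load_table1_counts(), load_table2_counts())
    t2 = tables.table2.set_index("stratum")
    total = t2.loc["total"]
    assert total["autosomal_trisomy_n"] == 572 and total["autosomal_trisomy_pct"] == 64
    assert total["monosomy_x_n"] == 91 and total["monosomy_x_pct"] == 10
    assert total["partial_imbalance_n"] == 173 and total["partial_imbalance_pct"] == 19
    assert total["mosaic_or_triploidy_n"] == 46 and total["mosaic_or_triploidy_pct"] == 5
    assert total["autosomal_monosomy_pct"] == 1 and total["other_pct"] == 1
    # per-stratum abnormal shares of all abnormal specimens
    assert t2.loc["1", "abnormal_pct"] == 31
    assert t2.loc["2", "abnormal_pct"] == 42
    assert t2.loc["3", "abnormal_pct"] == 18
    assert t2.loc["4+", "abnormal_pct"] == 9


def test_all_normal_cohort_zero_abnormal():
    results = [make_result(f"s{i}", "normal") for i in range(4)]
    metas = [make_meta(f"s{i}") for i in range(4)]
    tables = build_cohort_tables(results, metas)
    total = tables.table1.set_index("stratum").loc["total"]
    assert total["abnormal_n"] == 0 and total["abnormal_pct"] == 0.0


def test_build_tables_matches_fixture_route():
    """Specimen-level aggregation and count-level recomputation agree."""
    results, metas = [], []
    i = 0
    for count, cats in [(1, ["normal", "autosomal_trisomy"]), (2, ["monosomy_x"] * 3), (5, ["normal"])]:
        for cat in cats:
            results.append(make_result(f"s{i}", cat))
            group = "SA" if count == 1 else "RPL"
            metas.append(make_meta(f"s{i}", group, count, 30.0))
            i += 1
    tables = build_cohort_tables(results, metas)
    t1 = tables.table1.set_index("stratum")
    assert t1.loc["1", "n"] == 2 and t1.loc["2", "n"] == 3 and t1.loc["4+", "n"] == 1
    assert tables.n_abnormal == 4
    t2 = tables.table2.set_index("stratum")
    assert t2.loc["2", "monosomy_x_n"] == 3
    assert t2.loc["2", "monosomy_x_pct"] == 75  # 3 of 4 abnormal


def test_qc_excluded_specimens_dropped_with_count():
    results = [make_result("a", "normal"), make_result("b", None)]
    metas = [make_meta("a"), make_meta("b")]
    tables = build_cohort_tables(results, metas)
    assert tables.n_cohort == 1 and tables.excluded == 1


# ---------------------------------------------------------------------------
# age stratification
# ---------------------------------------------------------------------------

def test_age_bin_edges_closed_on_left():
    assert [age_bin(a) for a in (29, 30, 34, 35)] == ["<30", "30-34", "30-34", ">=35"]


def test_single_age_populates_one_bin():
    results = [make_result(f"s{i}", "normal") for i in range(5)]
    metas = [make_meta(f"s{i}", age=32.0) for i in range(5)]
    table = stratify_by_age(results, metas)
    sa = table[table["group"] == "SA"].set_index("age_bin")
    assert sa.loc["30-34", "n"] == 5
    assert sa.loc["<30", "n"] == 0 and np.isnan(sa.loc["<30", "rate"])


def test_generated_rate_pattern_recovered_within_ci():
    """Planted abnormality rates (0.5, 0.3, 0.6) per RPL age bin are recovered
    within the binomial 95% CI of each cell."""
    rng = np.random.default_rng(5)
    rates = {"<30": 0.5, "30-34": 0.3, ">=35": 0.6}
    ages = {"<30": 25.0, "30-34": 32.0, ">=35": 38.0}
    results, metas = [], []
    n_cell = 120
    for label, rate in rates.items():
        for i in range(n_cell):
            sid = f"{label}{i}"
            cat = "autosomal_trisomy" if rng.random() < rate else "normal"
            results.append(make_result(sid, cat))
            metas.append(make_meta(sid, "RPL", 2, ages[label]))
    table = stratify_by_age(results, metas)
    rpl = table[table["group"] == "RPL"].set_index("age_bin")
    for label, rate in rates.items():
        lo, hi = binom.ppf([0.025, 0.975], n_cell, rate) / n_cell
        assert lo <= rpl.loc[label, "rate"] <= hi


# ---------------------------------------------------------------------------
# recurrent-CNV clustering
# ---------------------------------------------------------------------------

def test_identical_intervals_form_recurrent_cluster():
    calls = [dup("chr16", 100, 200), dup("chr16", 100, 200)]
    clusters = cluster_recurrent_cnvs(calls, ["RPL", "SA"])
    assert len(clusters) == 1
    c = clusters[0]
    assert c.n == 2 and c.recurrent and (c.count_rpl, c.count_sa) == (1, 1)
    assert (c.start, c.end) == (100, 200)


def test_forty_percent_overlap_splits_at_default_threshold():
    a = dup("chr16", 0, 100)
    b = dup("chr16", 60, 160)  # 40% reciprocal overlap
    clusters = cluster_recurrent_cnvs([a, b], ["RPL", "RPL"])
    assert len(clusters) == 2 and not any(c.recurrent for c in clusters)
    # at 0.4 threshold they merge
    merged = cluster_recurrent_cnvs([a, b], ["RPL", "RPL"], overlap_frac=0.4)
    assert len(merged) == 1


def test_dup_and_del_never_cluster_together():
    a = dup("chr16", 0, 100)
    b = CnvCall("chr16", 0, 100, "del", 100, 1.0, "16q11")
    assert len(cluster_recurrent_cnvs([a, b], ["RPL", "RPL"])) == 2


def test_cluster_membership_order_invariant():
    rng = np.random.default_rng(9)
    calls, groups = [], []
    for i in range(30):
        s = int(rng.integers(0, 1000)) * 100
        calls.append(dup("chr3", s, s + int(rng.integers(50, 300)) * 100))
        groups.append("RPL" if rng.random() < 0.6 else "SA")
    base = cluster_recurrent_cnvs(calls, groups)
    perm = rng.permutation(len(calls))
    shuffled = cluster_recurrent_cnvs([calls[i] for i in perm], [groups[i] for i in perm])
    key = lambda c: (c.chrom, c.start, c.end, c.type, c.count_rpl, c.count_sa, c.n)
    assert [key(c) for c in base] == [key(c) for c in shuffled]


def test_planted_rpl_only_duplication_cluster_is_significant(mini_genome):
    """A 16q duplication carried by 19 RPL and 0 SA specimens clusters into a
    single recurrent CNV whose carrier excess is statistically significant."""
    start, end = 3_900_000, 4_000_000
    calls = [dup("chr16", start, end) for _ in range(19)]
    groups = ["RPL"] * 19
    clusters = cluster_recurrent_cnvs(calls, groups, genome=mini_genome)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.count_rpl, c.count_sa) == (19, 0) and c.cytoband.startswith("16q")
    t = compare_cnv_frequency(c, n_rpl=1016, n_sa=540)
    assert t.test_name == "fisher" and t.p_value < 0.05


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def test_zero_margin_gives_p_one():
    t = compare_counts(0, 10, 0, 10)
    assert t.p_value == 1.0 and t.test_name == "fisher"


def test_symmetric_table_gives_p_one_or_one():
    t = compare_counts(5, 100, 5, 100)
    assert t.p_value == 1.0 and t.odds_ratio == pytest.approx(1.0)


def test_chi2_branch_used_when_expected_counts_large():
    t = compare_counts(40, 100, 20, 100)
    assert t.test_name == "chi2" and t.p_value < 0.05 and t.statistic is not None


def test_fisher_matches_exact_enumeration_on_random_tables():
    """Implementation agrees with Fraction-exact enumeration to 1e-12."""
    rng = np.random.default_rng(13)
    for _ in range(100):
        r1, r2 = rng.integers(1, 201, size=2)
        a = int(rng.integers(0, r1 + 1))
        c = int(rng.integers(0, r2 + 1))
        table = ((a, int(r1) - a), (c, int(r2) - c))
        assert fisher_exact_2x2(table) == pytest.approx(
            float(exact_fisher_two_sided(table)), abs=1e-12
        )


def test_fisher_agrees_with_scipy_away_from_ties():
    for table in [((19, 997), (0, 540)), ((3, 7), (6, 4)), ((10, 30), (2, 50))]:
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_exact(np.array(table))[1], rel=1e-9
        )


def test_infinite_odds_ratio_for_rpl_only_carrier():
    t = compare_counts(19, 1016, 0, 540)
    assert np.isinf(t.odds_ratio)
    assert t.p_value == pytest.approx(float(exact_fisher_two_sided(((19, 997), (0, 540)))), abs=1e-15)
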