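import math

import numpy as np
import pandas as pd
import pytest

from vstriage.summary import (
    SUMMARY_COLUMNS,
    FilterError,
    apply_filters,
    build_summary,
    parse_filter,
    read_summary,
    summarize_distribution,
    top_n_by_dG,
    write_summary,
)


@pytest.fixture()
def small_summary(descriptor_set):
    rng = np.random.default_rng(17)
    descriptors = {}
    energies = []
    for i in range(50):
        lid = f"lig{i:03d}"
        descriptors[lid] = descriptor_set(
            MW=float(rng.uniform(150, 550)),
            PSA=float(rng.uniform(10, 160)),
            NHEA=int(rng.integers(10, 40)),
            NPOL=int(rng.integers(1, 9)),
        )
        energies.append((lid, float(rng.uniform(-11, -4))))
    rows, failures = build_summary(descriptors, energies)
    assert failures == []
    return rows


class TestBuildSummary:
    def test_sixteen_parameter_columns_in_order(self, descriptor_set):
        descriptors = {f"l{i}": descriptor_set() for i in range(5)}
        rows, _ = build_summary(descriptors, [(f"l{i}", -6.0 - i) for i in range(5)])
        assert list(rows.columns) == list(SUMMARY_COLUMNS)
        assert len(rows.columns) == 16
        assert len(rows) == 5
        assert list(rows.index) == [f"l{i}" for i in range(5)]

    def test_empty_input_gives_header_only_table(self, tmp_path):
        rows, failures = build_summary({}, [])
        assert len(rows) == 0 and failures == []
        csv_path, tsv_path = write_summary(rows, tmp_path)
        assert csv_path.read_text().splitlines()[0].split(",")[1:] == list(SUMMARY_COLUMNS)

    def test_unmatched_ligand_becomes_failure_entry(self, descriptor_set):
        descriptors = {f"l{i}": descriptor_set() for i in range(4)}
        energies = [(f"l{i}", -6.0) for i in range(4)] + [("orphan", -9.0)]
        rows, failures = build_summary(descriptors, energies)
        assert len(rows) == 4
        assert failures == [("orphan", "no descriptors for docked ligand")]

    def test_index_ties_hold_row_wise(self, small_summary):
        pki = -np.log10(small_summary["Ki"])
        np.testing.assert_allclose(small_summary["BEI"] * small_summary["MW"] / 1000, pki, rtol=1e-9)
        np.testing.assert_allclose(small_summary["SEI"] * small_summary["PSA"] / 100, pki, rtol=1e-9)
        np.testing.assert_allclose(small_summary["NSEI"] * small_summary["HBA"], pki, rtol=1e-9)


class TestFilters:
    def test_psa_filter_matches_brute_force_count(self, small_summary):
        filtered = apply_filters(small_summary, ["PSA<50"])
        assert len(filtered) == int((small_summary["PSA"] < 50).sum())
        assert list(filtered.index) == list(small_summary.index[small_summary["PSA"] < 50])

    def test_empty_chain_is_identity(self, small_summary):
        pd.testing.assert_frame_equal(apply_filters(small_summary, []), small_summary)

    def test_contradictory_chain_empties_table(self, small_summary):
        assert len(apply_filters(small_summary, ["MW<100", "MW>200"])) == 0

    def test_unknown_parameter_error_lists_valid_names(self, small_summary):
        with pytest.raises(FilterError, match="MW.*mBEI"):
            apply_filters(small_summary, ["XLOGP<5"])

    def test_chain_is_idempotent(self, small_summary):
        chain = ["PSA<120", "cLogP<4"]
        once = apply_filters(small_summary, chain)
        pd.testing.assert_frame_equal(apply_filters(once, chain), once)

    def test_filters_on_distinct_parameters_commute(self, small_summary):
        ab = apply_filters(small_summary, ["PSA<100", "MW>250"])
        ba = apply_filters(small_summary, ["MW>250", "PSA<100"])
        pd.testing.assert_frame_equal(ab, ba)

    def test_nan_rows_survive_other_filters_but_fail_own(self, descriptor_set):
        descriptors = {
            "polar": descriptor_set(PSA=80.0, NPOL=4),
            "greasy": descriptor_set(PSA=0.0, NPOL=0),  # SEI/NSEI undefined
        }
        rows, _ = build_summary(descriptors, [("polar", -7.0), ("greasy", -7.0)])
        assert len(apply_filters(rows, ["MW<1000"])) == 2
        assert list(apply_filters(rows, ["SEI>0"]).index) == ["polar"]

    def test_parse_filter_comparators(self):
        cond = parse_filter(" cLogP <= 5 ")
        assert (cond.parameter, cond.comparator, cond.threshold) == ("cLogP", "<=", 5.0)
        with pytest.raises(FilterError):
            parse_filter("PSA?50")


class TestTopN:
    def test_cut_verified_against_full_sort(self, small_summary):
        top = top_n_by_dG(small_summary, 10)
        assert len(top) == 10
        assert list(top["dG"]) == sorted(top["dG"])
        excluded = small_summary.drop(top.index)
        assert top["dG"].max() <= excluded["dG"].min()
        brute = small_summary["dG"].sort_values().head(10)
        assert set(top.index) == set(brute.index)

    def test_n_zero_and_oversized_n(self, small_summary):
        assert len(top_n_by_dG(small_summary, 0)) == 0
        assert len(top_n_by_dG(small_summary, 10_000)) == len(small_summary)

    def test_ties_broken_by_ligand_id(self, descriptor_set):
        descriptors = {lid: descriptor_set() for lid in ("c", "a", "b", "d")}
        rows, _ = build_summary(descriptors, [(lid, -6.0) for lid in ("c", "a", "b", "d")])
        top = top_n_by_dG(rows, 3)
        assert list(top.index) == ["a", "b", "c"]

    def test_output_is_subset_of_input(self, small_summary):
        top = top_n_by_dG(small_summary, 25)
        assert set(top.index) <= set(small_summary.index)


class TestDistribution:
    def test_fraction_below_threshold(self, descriptor_set):
        descriptors = {f"l{i}": descriptor_set(PSA=30.0 if i < 13 else 90.0) for i in range(100)}
        rows, _ = build_summary(descriptors, [(f"l{i}", -6.0) for i in range(100)])
        assert summarize_distribution(rows, "PSA", 50.0) == pytest.approx(13.0)

    def test_all_and_none_below(self, small_summary):
        assert summarize_distribution(small_summary, "MW", 1e6) == 100.0
        assert summarize_distribution(small_summary, "MW", 0.0) == 0.0

    def test_empty_table_is_undefined(self, small_summary):
        assert math.isnan(summarize_distribution(small_summary.iloc[:0], "PSA", 50.0))


def test_csv_tsv_round_trip_to_six_significant_digits(small_summary, tmp_path):
    csv_path, tsv_path = write_summary(small_summary, tmp_path)
    for path in (csv_path, tsv_path):
        reread = read_summary(path)
        assert list(reread.columns) == list(SUMMARY_COLUMNS)
        pd.testing.assert_frame_equal(reread, small_summary, rtol=1e-5, check_dtype=False)
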