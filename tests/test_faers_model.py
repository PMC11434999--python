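import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from faerspv.errors import SchemaError
from faerspv.faers_model import (
    TsdReportCounts,
    build_table_a,
    build_table_b,
    count_tsd_reports,
    deduplicate,
    read_faers_table,
)

from conftest import demo_frame, drug_frame, reac_frame, write_faers_file


class TestReadFaersTable:
    def test_demo_field_mapping_and_age_coercion(self, demo_file):
        df = read_faers_table(demo_file, "DEMO")
        assert list(df["primary_id"]) == ["101", "201", "301"]
        assert df.loc[0, "age_unit"] == "MON"
        assert df.loc[1, "age_value"] == 64.0 and df.loc[1, "age_unit"] == "YR"
        assert np.isnan(df.loc[2, "age_value"])  # "abc" becomes missing
        assert list(df["gender"]) == ["F", "M", "F"]

    def test_drug_rows_share_primary_id(self, tmp_path):
        path = write_faers_file(
            tmp_path / "DRUG.txt",
            ["primaryid", "drugname"],
            [["7", "Sunitinib"], ["7", " ERLOTINIB "]],
        )
        df = read_faers_table(path, "DRUG")
        assert list(df["primary_id"]) == ["7", "7"]
        assert list(df["generic_name"]) == ["sunitinib", "erlotinib"]

    def test_missing_required_column_names_it(self, tmp_path):
        path = write_faers_file(
            tmp_path / "REAC.txt", ["primaryid", "reaction"], [["1", "nausea"]]
        )
        with pytest.raises(SchemaError, match="pt"):
            read_faers_table(path, "REAC")

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "REAC.txt"
        path.write_text("primaryid$pt\n")
        with pytest.warns(UserWarning):
            df = read_faers_table(path, "REAC")
        assert df.empty


class TestDeduplicate:
    def test_demo_keeps_highest_case_version(self):
        demo = demo_frame(
            [("71", "7", 1, 50, "YR", "M"), ("72", "7", 2, 51, "YR", "M")]
        )
        out = deduplicate(demo, "DEMO")
        assert list(out["primary_id"]) == ["72"]

    def test_reac_exact_duplicates_collapse(self):
        reac = reac_frame([("1", "dysgeusia"), ("1", "dysgeusia")])
        assert len(deduplicate(reac, "REAC")) == 1

    def test_five_demo_rows_three_cases(self):
        # versions per case: A:{1}, B:{1,2}, C:{1,1} -> keep A1, B2, C (highest id)
        demo = demo_frame(
            [
                ("a1", "A", 1, 40, "YR", "F"),
                ("b1", "B", 1, 41, "YR", "F"),
                ("b2", "B", 2, 42, "YR", "F"),
                ("c1", "C", 1, 43, "YR", "F"),
                ("c2", "C", 1, 44, "YR", "F"),
            ]
        )
        out = deduplicate(demo, "DEMO")
        assert sorted(out["primary_id"]) == ["a1", "b2", "c2"]

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 4),  # case
                st.integers(0, 3),  # version
                st.integers(0, 9),  # primary id disambiguator
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_demo_dedup_is_idempotent_and_one_row_per_case(self, rows):
        demo = demo_frame(
            [
                (f"p{case}{version}{i}", f"c{case}", version, 50, "YR", "F")
                for case, version, i in rows
            ]
        )
        once = deduplicate(demo, "DEMO")
        twice = deduplicate(once, "DEMO")
        pd.testing.assert_frame_equal(once, twice)
        assert once["case_id"].is_unique
        # keep-latest rule: the retained version is the max per case
        expected = demo.groupby("case_id")["case_version"].max()
        kept = once.set_index("case_id")["case_version"]
        assert kept.sort_index().equals(expected.sort_index())


class TestTableA:
    def test_inner_join_drops_reports_missing_a_table(self):
        demo = demo_frame([("1", "1", 1, 60, "YR", "F"), ("2", "2", 1, 61, "YR", "M")])
        drug = drug_frame([("1", "alphanib")])  # report 2 has no drug row
        reac = reac_frame([("1", "dysgeusia"), ("2", "dysgeusia")])
        table_a = build_table_a(demo, drug, reac)
        assert list(table_a.report_ids) == ["1"]

    def test_flags_from_smq_membership(self):
        demo = demo_frame([("1", "1", 1, 60, "YR", "F")])
        drug = drug_frame([("1", "alphanib")])
        reac = reac_frame([("1", "Dysgeusia"), ("1", "Nausea")])
        flags = build_table_a(demo, drug, reac).flags
        assert bool(flags.loc["1", "has_taste"])
        assert not bool(flags.loc["1", "has_smell"])
        assert bool(flags.loc["1", "has_tsd"])

    def test_ten_report_fixture_matches_hand_enumeration(self, ten_report_tables):
        table_a = build_table_a(*ten_report_tables)
        f = table_a.flags
        assert table_a.n_reports == 10
        assert set(f.index[f["has_taste"] & ~f["has_smell"]]) == {"1", "2", "3", "4"}
        assert set(f.index[f["has_smell"] & ~f["has_taste"]]) == {"5", "6", "7"}
        assert set(f.index[f["has_taste"] & f["has_smell"]]) == {"8", "9"}
        assert set(f.index[~f["has_tsd"]]) == {"10"}
        assert (f["has_tsd"] == (f["has_taste"] | f["has_smell"])).all()

    def test_no_duplicate_triples(self, ten_report_tables):
        triples = build_table_a(*ten_report_tables).triples()
        assert not triples.duplicated().any()


class TestCountTsdReports:
    def test_partition_on_fixture(self, ten_report_tables):
        table_a = build_table_a(*ten_report_tables)
        counts = count_tsd_reports(table_a, {"alphanib", "betamab"})
        assert counts.n_taste_only == 4
        assert counts.n_smell_only == 3
        assert counts.n_both == 2
        assert counts.n_tsd_any == 9
        assert counts.n_taste_any == 6 and counts.n_smell_any == 5

    def test_unmatched_exposure_gives_zero_counts(self, ten_report_tables):
        table_a = build_table_a(*ten_report_tables)
        counts = count_tsd_reports(table_a, {"gammaximab"})
        assert counts.n_tsd_any == 0 and counts.n_both == 0

    def test_empty_exposure_rejected(self, ten_report_tables):
        with pytest.raises(ValueError):
            count_tsd_reports(build_table_a(*ten_report_tables), set())

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=40
        )
    )
    def test_partition_identity_over_random_flag_sets(self, flags):
        demo = demo_frame(
            [(str(i), str(i), 1, 50, "YR", "F") for i in range(len(flags) + 1)]
        )
        drug = drug_frame([(str(i), "alphanib") for i in range(len(flags) + 1)])
        reac_rows = [(str(len(flags)), "nausea")]  # anchor report, no TSD
        for i, (taste, smell) in enumerate(flags):
            reac_rows.append((str(i), "dysgeusia" if taste else "nausea"))
            if smell:
                reac_rows.append((str(i), "anosmia"))
        table_a = build_table_a(demo, drug, reac_frame(reac_rows))
        c = count_tsd_reports(table_a, {"alphanib"})
        assert c.n_taste_only + c.n_smell_only + c.n_both == c.n_tsd_any
        assert c.n_taste_any == c.n_taste_only + c.n_both
        assert c.n_smell_any == c.n_smell_only + c.n_both

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValueError):
            TsdReportCounts(5, 3, 3, 1, 1, 2)


class TestTableB:
    @staticmethod
    def _tables(demo_rows):
        n = len(demo_rows)
        drug = drug_frame([(str(i), "alphanib") for i in range(n)])
        reac = reac_frame([(str(i), "dysgeusia" if i % 2 else "nausea") for i in range(n)])
        return demo_frame(demo_rows), drug, reac

    def test_out_of_range_and_non_year_ages_removed(self):
        demo, drug, reac = self._tables(
            [
                ("0", "0", 1, 250, "YR", "F"),  # age > 120
                ("1", "1", 1, 18, "MON", "F"),  # months: dropped, not converted
                ("2", "2", 1, 64, "YR", "M"),
                ("3", "3", 1, 6, "DEC", "F"),  # decades x 10 retained
            ]
        )
        tb = build_table_b(demo, drug, reac, {"alphanib"})
        assert list(tb["primary_id"]) == ["2", "3"]
        assert list(tb["age_years"]) == [64.0, 60.0]

    def test_unknown_gender_removed(self):
        demo, drug, reac = self._tables(
            [("0", "0", 1, 50, "YR", "UNK"), ("1", "1", 1, 50, "YR", "M")]
        )
        tb = build_table_b(demo, drug, reac, {"alphanib"})
        assert list(tb["primary_id"]) == ["1"]

    def test_unexposed_reports_excluded(self):
        demo = demo_frame([("0", "0", 1, 50, "YR", "F"), ("1", "1", 1, 50, "YR", "F")])
        drug = drug_frame([("0", "alphanib"), ("1", "acetaminophen")])
        reac = reac_frame([("0", "nausea"), ("1", "nausea")])
        tb = build_table_b(demo, drug, reac, {"alphanib"})
        assert list(tb["primary_id"]) == ["0"]

    def test_twenty_report_fixture_hand_filtered(self):
        # 20 reports; 8 planted failures: 3 invalid ages, 2 non-year units,
        # 2 unknown gender, 1 unexposed -> 12 rows survive
        rows, drug_rows, reac_rows = [], [], []
        for i in range(20):
            age, unit, sex, exposed = 50, "YR", "M", True
            if i in (0, 1):
                age = 130 + i
            elif i == 2:
                age = -1
            elif i in (3, 4):
                unit = "MON"
            elif i in (5, 6):
                sex = "UNK"
            elif i == 7:
                exposed = False
            rows.append((str(i), str(i), 1, age, unit, sex))
            drug_rows.append((str(i), "alphanib" if exposed else "other"))
            reac_rows.append((str(i), "dysgeusia" if i % 3 == 0 else "nausea"))
        tb = build_table_b(
            demo_frame(rows), drug_frame(drug_rows), reac_frame(reac_rows), {"alphanib"}
        )
        assert len(tb) == 12
        assert tb["tsd"].tolist() == [(int(p) % 3 == 0) for p in tb["primary_id"]]
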