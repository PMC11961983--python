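"""Parsing, case deduplication, target selection, and universe assembly."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pvsignal as pv
from pvsignal.ingest import ParseError, parse_full_date, date_year, read_quarter_dir


class TestParseTable:
    def test_positional_mapping(self):
        df = pv.parse_table("primaryid$caseid$fda_dt\n100$1$20230105")
        assert df.shape == (1, 3)
        row = df.iloc[0]
        assert (row["primaryid"], row["caseid"], row["fda_dt"]) == ("100", "1", "20230105")
        assert parse_full_date(row["fda_dt"]).isoformat() == "2023-01-05"

    def test_header_only_gives_empty_frame(self):
        df = pv.parse_table("primaryid$caseid$fda_dt\n")
        assert len(df) == 0
        assert list(df.columns) == ["primaryid", "caseid", "fda_dt"]

    def test_field_count_mismatch_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            pv.parse_table("primaryid$caseid$fda_dt\n100$1")

    def test_permissive_mode_skips_bad_rows(self):
        text = "primaryid$caseid$fda_dt\n100$1\n101$2$20230101"
        df = pv.parse_table(text, strict=False)
        assert list(df["primaryid"]) == ["101"]

    def test_trailing_delimiter_tolerated(self):
        df = pv.parse_table("primaryid$pt\n100$Pyrexia$\n")
        assert df.iloc[0]["pt"] == "Pyrexia"

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ParseError, match="schema"):
            pv.parse_table("foo$bar\n1$2", schema=["primaryid", "pt"])

    def test_extra_columns_preserved(self):
        df = pv.parse_table("primaryid$pt$extra\n1$X$z", schema=["primaryid", "pt"])
        assert df.iloc[0]["extra"] == "z"


class TestDates:
    @pytest.mark.parametrize("raw,expect", [
        ("20230105", "2023-01-05"), ("202301", None), ("2023", None),
        ("", None), ("20231345", None),
    ])
    def test_full_date(self, raw, expect):
        d = parse_full_date(raw)
        assert (d.isoformat() if d else None) == expect

    @pytest.mark.parametrize("raw,year", [
        ("20230105", 2023), ("202301", 2023), ("2023", 2023), ("", None), ("x", None),
    ])
    def test_year_extraction_from_partial(self, raw, year):
        assert date_year(raw) == year


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])


class TestDeduplicate:
    def test_latest_fda_date_wins(self):
        out = pv.deduplicate(_demo([("1", "A", "20230101"), ("2", "A", "20230601")]))
        assert list(out["primaryid"]) == ["2"]

    def test_fda_tie_broken_by_highest_primaryid(self):
        out = pv.deduplicate(_demo([("5", "B", "20230101"), ("9", "B", "20230101")]))
        assert list(out["primaryid"]) == ["9"]

    def test_distinct_cases_both_kept(self):
        out = pv.deduplicate(_demo([("1", "A", "20230101"), ("2", "B", "20230101")]))
        assert len(out) == 2

    def test_unparseable_fda_dt_raises(self):
        with pytest.raises(ValueError, match="fda_dt"):
            pv.deduplicate(_demo([("1", "A", "202301")]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 50), st.sampled_from("ABCDE"),
                  st.integers(0, 364)),
        min_size=1, max_size=25, unique_by=lambda r: r[0],
    ))
    def test_idempotent_and_survivor_is_lexicographic_max(self, rows):
        df = _demo([(str(pid), case, f"2023{1 + day // 31:02d}{1 + day % 28:02d}")
                    for pid, case, day in rows])
        once = pv.deduplicate(df)
        twice = pv.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once["caseid"].is_unique
        # brute-force survivor: max (fda_dt, int(primaryid)) within each case
        for case, grp in df.groupby("caseid"):
            best = max(grp.itertuples(), key=lambda r: (r.fda_dt, int(r.primaryid)))
            kept = once[once["caseid"] == case]
            assert list(kept["primaryid"]) == [best.primaryid]


def _drugs(rows):
    return pd.DataFrame(rows, columns=["primaryid", "drug_seq", "role_cod", "drugname"])


class TestTargetSelection:
    def test_brand_name_matches_default_lexicon(self):
        assert pv.select_target_reports(_drugs([("1", "1", "PS", "Vidaza")])) == {"1"}

    def test_concomitant_role_not_selected(self):
        assert pv.select_target_reports(_drugs([("1", "1", "C", "AZACITIDINE")])) == set()

    def test_punctuation_stripped_before_match(self):
        assert pv.select_target_reports(_drugs([("1", "1", "PS", "azacitidine.")])) == {"1"}

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            pv.select_target_reports(_drugs([("1", "1", "PS", "X")]), lexicon=set())

    def test_normalize_drug_name(self):
        assert pv.normalize_drug_name(" Vidaza®  (inj.) ") == "VIDAZA INJ"


class TestEventUniverse:
    def _reports(self, ids):
        return pd.DataFrame({"primaryid": list(ids)})

    def test_duplicate_pt_mentions_collapse(self):
        reports = self._reports(["r1", "r2"])
        drugs = _drugs([("r1", "1", "PS", "AZACITIDINE"), ("r2", "1", "PS", "OTHER")])
        reac = pd.DataFrame({"primaryid": ["r1", "r1", "r1", "r2"],
                             "pt": ["P1", "P1", "P2", "P1"]})
        u = pv.assemble_event_universe(reports, drugs, reac)
        assert u.n_events == 3
        assert u.n_target_events == 2
        assert u.n_target_events + u.n_other_events == u.n_events

    def test_no_reactions_gives_empty_universe(self):
        u = pv.assemble_event_universe(
            self._reports(["r1"]), _drugs([("r1", "1", "PS", "AZACITIDINE")]),
            pd.DataFrame(columns=["primaryid", "pt"]))
        assert u.n_events == 0 and u.n_target_events == 0

    def test_orphan_reaction_dropped_and_counted(self):
        reports = self._reports(["r1"])
        drugs = _drugs([("r1", "1", "PS", "AZACITIDINE")])
        reac = pd.DataFrame({"primaryid": ["r1", "ghost"], "pt": ["P1", "P2"]})
        u = pv.assemble_event_universe(reports, drugs, reac)
        assert u.n_events == 1
        assert u.n_dropped_orphan == 1


def test_round_trip_generator_to_parser(tmp_path, synthetic_db):
    """Written quarterly files parse back to the generator's row counts."""
    synthetic_db.write(tmp_path)
    for name, expected in synthetic_db.ledger["row_counts"].items():
        df = read_quarter_dir(tmp_path, name)
        assert len(df) == expected
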