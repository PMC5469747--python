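import io

import numpy as np
import pandas as pd
import pytest

from finmove import argos, simulate
from finmove.argos import (
    ArgosFix,
    RowError,
    apply_exclusions,
    assemble_tracks,
    read_argos_table,
    split_on_gaps,
)

from conftest import make_fix, track_with_duration

HEADER = "ptt,date,lon,lat,lc\n"


class TestReadArgosTable:
    def test_empty_body_gives_empty_list(self):
        assert read_argos_table(io.StringIO(HEADER)) == []

    def test_single_row(self):
        fixes = read_argos_table(
            io.StringIO(HEADER + "87780,2015-03-14T06:00:00,12.5,35.2,B\n")
        )
        assert len(fixes) == 1
        f = fixes[0]
        assert (f.ptt, f.lc) == ("87780", "B")
        assert f.time == pd.Timestamp("2015-03-14 06:00:00")

    def test_missing_column_is_config_error(self):
        with pytest.raises(KeyError, match="lc"):
            read_argos_table(io.StringIO("ptt,date,lon,lat\n1,2015-01-01,0,0\n"))

    def test_bad_rows_carry_line_numbers(self):
        bad_time = HEADER + "1,2015-01-01,0,0,3\n1,not-a-date,0,0,3\n"
        with pytest.raises(RowError, match="row 3"):
            read_argos_table(io.StringIO(bad_time))
        with pytest.raises(RowError, match="row 2"):
            read_argos_table(io.StringIO(HEADER + "1,2015-01-01,east,0,3\n"))

    def test_class_z_rejected(self):
        with pytest.raises(RowError, match="Z"):
            read_argos_table(io.StringIO(HEADER + "1,2015-01-01,0,0,Z\n"))

    def test_column_mapping_and_custom_format(self):
        body = "tag;when;x;y;q\n87780;14/03/2015 06:00;12.5;35.2;A\n"
        fixes = read_argos_table(
            io.StringIO(body),
            columns={"ptt": "tag", "date": "when", "lon": "x", "lat": "y", "lc": "q"},
            sep=";",
            date_format="%d/%m/%Y %H:%M",
        )
        assert fixes[0].lc == "A" and fixes[0].time.day == 14

    def test_writer_reader_round_trip(self):
        truth = simulate.simulate_dcrws(n_steps=30, seed=3)
        fixes = simulate.observe_argos(truth, seed=4, ptt="87780")
        buf = io.StringIO()
        argos.write_argos_csv(buf, fixes)
        buf.seek(0)
        again = read_argos_table(buf)
        assert again == fixes


class TestAssembleTracks:
    def test_interleaved_platforms_are_separated_and_sorted(self):
        fixes = [
            make_fix("A", 10), make_fix("B", 2), make_fix("A", 0), make_fix("B", 8),
        ]
        tracks = assemble_tracks(fixes)
        assert set(tracks) == {"A", "B"}
        for tr in tracks.values():
            times = [f.time for f in tr]
            assert times == sorted(times)

    def test_equal_time_keeps_better_class(self):
        fixes = [make_fix("A", 0, lc="A"), make_fix("A", 0, lc="1")]
        (kept,) = assemble_tracks(fixes)["A"]
        assert kept.lc == "1"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        track = track_with_duration("X", 10)
        perm = [track[i] for i in rng.permutation(len(track))]
        assert assemble_tracks(perm)["X"] == assemble_tracks(track)["X"]


class TestSplitOnGaps:
    def test_no_gaps_single_segment(self):
        segs = split_on_gaps("X", track_with_duration("X", 10))
        assert [s.segment_label for s in segs] == ["a"]

    def test_five_day_gap_splits_a_b(self):
        track = [make_fix("X", 0), make_fix("X", 24), make_fix("X", 24 + 5 * 24), make_fix("X", 24 + 5 * 24 + 12)]
        segs = split_on_gaps("X", track)
        assert [s.segment_label for s in segs] == ["a", "b"]
        assert [len(s) for s in segs] == [2, 2]

    def test_exact_four_day_gap_does_not_split(self):
        track = [make_fix("X", 0), make_fix("X", 4 * 24.0)]
        assert len(split_on_gaps("X", track)) == 1

    def test_empty_track_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            split_on_gaps("X", [])

    def test_split_concat_round_trip_and_count(self):
        rng = np.random.default_rng(23)
        hours = np.cumsum(rng.uniform(1.0, 140.0, size=40))
        track = [make_fix("X", h) for h in hours]
        segs = split_on_gaps("X", track, gap_threshold_days=4.0)
        rejoined = [f for s in segs for f in s.fixes]
        assert rejoined == track
        gaps = np.diff(hours) / 24.0
        assert len(segs) == 1 + int((gaps > 4.0).sum())


class TestApplyExclusions:
    def _segments(self, deployments):
        return {
            ptt: (split_on_gaps(ptt, tr) if tr else [])
            for ptt, tr in deployments.items()
        }

    def test_pelagos_deployments_exclude_two(self, pelagos_deployments):
        report = apply_exclusions(self._segments(pelagos_deployments))
        assert len(report.excluded) == 2
        reasons = dict(report.excluded)
        assert reasons["112707"] == "no_locations"
        assert reasons["112709"] == "too_short"

    def test_all_long_nothing_excluded(self):
        segs = self._segments({p: track_with_duration(p, 30) for p in "abc"})
        assert apply_exclusions(segs).excluded == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        deployments = {
            f"P{i}": track_with_duration(f"P{i}", float(d), n_fixes=int(n))
            for i, (d, n) in enumerate(zip(rng.uniform(0.5, 10, 12), rng.integers(2, 60, 12)))
        }
        segs = self._segments(deployments)
        report = apply_exclusions(segs, min_duration_days=3.0, min_fixes=10)
        expected_excluded = {
            ptt
            for ptt, tr in deployments.items()
            if (tr[-1].time - tr[0].time).total_seconds() / 86400.0 < 3.0 or len(tr) < 10
        }
        assert {p for p, _ in report.excluded} == expected_excluded

    def test_idempotent_on_kept_set(self, pelagos_deployments):
        report = apply_exclusions(self._segments(pelagos_deployments))
        kept_by_ptt = {}
        for s in report.kept:
            kept_by_ptt.setdefault(s.ptt, []).append(s)
        again = apply_exclusions(kept_by_ptt)
        assert again.excluded == []
        assert again.kept == report.kept
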