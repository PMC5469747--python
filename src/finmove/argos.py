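"""Argos location-table ingestion, track assembly, gap splitting and exclusion.

Argos platforms (PTTs) deliver irregular satellite fixes, each stamped with a
location class (lc) in {3, 2, 1, 0, A, B} of decreasing positional quality.
This module turns a raw delimited table of fixes into analysis-ready track
segments: one time-ordered track per platform, split wherever the temporal
gap between consecutive fixes exceeds a threshold (default: strictly more
than 4 days), with short or location-less platforms excluded from analysis.
"""

from __future__ import annotations

import io
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Argos location classes, best first. "Z" (invalid) is rejected on ingest.
LC_ORDER = ("3", "2", "1", "0", "A", "B")
LC_RANK = {lc: i for i, lc in enumerate(LC_ORDER)}

DEFAULT_COLUMNS = {"ptt": "ptt", "date": "date", "lon": "lon", "lat": "lat", "lc": "lc"}


@dataclass(frozen=True)
class ArgosFix:
    """A single Argos location fix."""

    ptt: str
    time: pd.Timestamp  # UTC, second resolution
    lon: float
    lat: float
    lc: str

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if self.lc not in LC_RANK:
            raise ValueError(f"location class {self.lc!r} not in {LC_ORDER}")
        if pd.isna(self.time):
            raise ValueError("fix time is not finite")


@dataclass
class TrackSegment:
    """A gap-free, time-ordered run of fixes from one platform."""

    ptt: str
    segment_label: str
    fixes: list[ArgosFix]

    @property
    def duration_days(self) -> float:
        if not self.fixes:
            return 0.0
        span = self.fixes[-1].time - self.fixes[0].time
        return span.total_seconds() / 86400.0

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class ExclusionReport:
    kept: list[TrackSegment]
    excluded: list[tuple[str, str]]  # (ptt, reason in {"no_locations", "too_short"})


class RowError(ValueError):
    """A data row that cannot be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"row {line}: {message}")
        self.line = line


def read_argos_table(
    source,
    columns: dict[str, str] | None = None,
    sep: str = ",",
    date_format: str | None = None,
) -> list[ArgosFix]:
    """Read an Argos location table from a path or text stream.

    ``columns`` maps the five required logical names {ptt, date, lon, lat, lc}
    to the header names used in the file. Timestamps are ISO-8601 by default;
    pass a strptime pattern via ``date_format`` otherwise. Row order is
    preserved. Malformed rows raise :class:`RowError` with the line number.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}; found {list(df.columns)}")

    fixes: list[ArgosFix] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        rec = dict(zip(df.columns, row))
        try:
            time = pd.to_datetime(rec[colmap["date"]], format=date_format, utc=True)
            if pd.isna(time):
                raise ValueError("empty timestamp")
            fix = ArgosFix(
                ptt=str(rec[colmap["ptt"]]).strip(),
                time=time.tz_localize(None).floor("s"),
                lon=float(rec[colmap["lon"]]),
                lat=float(rec[colmap["lat"]]),
                lc=str(rec[colmap["lc"]]).strip(),
            )
        except (ValueError, TypeError) as exc:
            raise RowError(line, str(exc)) from exc
        fixes.append(fix)
    return fixes


def assemble_tracks(fixes: Iterable[ArgosFix]) -> dict[str, list[ArgosFix]]:
    """Group fixes by platform and time-sort each track.

    Fixes with identical timestamps are de-duplicated keeping the one with
    the best location class (3 > 2 > 1 > 0 > A > B); earliest input order
    breaks remaining ties.
    """
    tracks: dict[str, list[ArgosFix]] = {}
    for fix in fixes:
        tracks.setdefault(fix.ptt, []).append(fix)
    out: dict[str, list[ArgosFix]] = {}
    for ptt in sorted(tracks):
        fs = sorted(tracks[ptt], key=lambda f: (f.time, LC_RANK[f.lc]))
        dedup: list[ArgosFix] = []
        for f in fs:
            if dedup and dedup[-1].time == f.time:
                continue  # an equal-time fix with better (or equal) lc already kept
            dedup.append(f)
        out[ptt] = dedup
    return out


def _segment_labels(n: int) -> list[str]:
    # a, b, ..., z, aa, ab, ... (Table-style letters)
    letters = string.ascii_lowercase
    labels = []
    for i in range(n):
        lab = ""
        j = i
        while True:
            lab = letters[j % 26] + lab
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(lab)
    return labels


def split_on_gaps(
    ptt: str, track: Sequence[ArgosFix], gap_threshold_days: float = 4.0
) -> list[TrackSegment]:
    """Split a time-ordered track wherever a gap strictly exceeds the threshold.

    A gap of exactly ``gap_threshold_days`` does NOT split (the rule is
    "longer than"). Segments are labelled a, b, ... in temporal order.
    """
    if not track:
        raise ValueError(f"platform {ptt}: empty track")
    chunks: list[list[ArgosFix]] = [[track[0]]]
    for prev, cur in zip(track, track[1:]):
        gap_days = (cur.time - prev.time).total_seconds() / 86400.0
        if gap_days < 0:
            raise ValueError(f"platform {ptt}: track not time-ordered")
        if gap_days > gap_threshold_days:
            chunks.append([])
        chunks[-1].append(cur)
    labels = _segment_labels(len(chunks))
    return [TrackSegment(ptt, lab, chunk) for lab, chunk in zip(labels, chunks)]


def apply_exclusions(
    segments_by_ptt: dict[str, list[TrackSegment]],
    min_duration_days: float = 3.0,
    min_fixes: int = 10,
) -> ExclusionReport:
    """Drop platforms with no locations or too little data to model.

    A platform is excluded with reason ``no_locations`` when it has zero
    fixes (transmissions-only tags), and ``too_short`` when its summed
    segment duration is below ``min_duration_days`` or its total fix count
    below ``min_fixes``. Idempotent on its own kept set.
    """
    kept: list[TrackSegment] = []
    excluded: list[tuple[str, str]] = []
    for ptt in sorted(segments_by_ptt):
        segs = segments_by_ptt[ptt]
        n_fixes = sum(len(s) for s in segs)
        if n_fixes == 0:
            excluded.append((ptt, "no_locations"))
            continue
        total_days = sum(s.duration_days for s in segs)
        if total_days < min_duration_days or n_fixes < min_fixes:
            excluded.append((ptt, "too_short"))
            continue
        kept.extend(segs)
    return ExclusionReport(kept=kept, excluded=excluded)


def prepare_segments(
    fixes: Iterable[ArgosFix],
    gap_threshold_days: float = 4.0,
    min_duration_days: float = 3.0,
    min_fixes: int = 10,
) -> ExclusionReport:
    """Assemble, split and filter raw fixes in one call."""
    tracks = assemble_tracks(fixes)
    segments = {ptt: split_on_gaps(ptt, tr) if tr else [] for ptt, tr in tracks.items()}
    return apply_exclusions(segments, min_duration_days, min_fixes)


# ---------------------------------------------------------------------------
# Writers


def fixes_to_frame(fixes: Sequence[ArgosFix], segment_label: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "ptt": [f.ptt for f in fixes],
            "date": [f.time.isoformat() for f in fixes],
            "lon": [f.lon for f in fixes],
            "lat": [f.lat for f in fixes],
            "lc": [f.lc for f in fixes],
        }
    )
    if segment_label is not None:
        df.insert(1, "segment_label", segment_label)
    return df


def write_argos_csv(path: str | Path | io.TextIOBase, fixes: Sequence[ArgosFix]) -> None:
    fixes_to_frame(fixes).to_csv(path, index=False)


def write_segments_csv(path: str | Path, segments: Sequence[TrackSegment]) -> None:
    frames = [fixes_to_frame(s.fixes, s.segment_label) for s in segments]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def segments_to_geojson(segments: Sequence[TrackSegment]) -> dict:
    """One GeoJSON LineString feature per segment."""
    features = []
    for s in segments:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "ptt": s.ptt,
                    "segment_label": s.segment_label,
                    "duration_days": s.duration_days,
                    "n_fixes": len(s),
                },
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[f.lon, f.lat] for f in s.fixes],
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_segments_geojson(path: str | Path, segments: Sequence[TrackSegment]) -> None:
    Path(path).write_text(json.dumps(segments_to_geojson(segments)))
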