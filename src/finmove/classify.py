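"""Behavioural classification of posterior mean states and track reports.

The posterior mean state b̂_t lies in [1, 2] (1 = transit, 2 = ARS). Under
conservative cut-offs, values below ``lo`` are called transit, above ``hi``
ARS, and everything in between — including the boundaries — uncertain.
Per-track reports give integer percentages that sum to exactly 100 via
largest-remainder rounding, matching how such tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LABELS = ("transit", "ARS", "uncertain")
DEFAULT_CUTOFFS = (1.25, 1.75)


@dataclass
class BehaviourSeries:
    ptt: str
    segment_label: str
    b_hat: np.ndarray  # (T,) in [1, 2]
    labels: list[str]


@dataclass
class TrackReport:
    ptt: str
    segment_label: str
    days_of_transmission: float
    pct_transit: int
    pct_ars: int
    pct_uncertain: int


def classify_state(b_hat: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> str:
    """Label a posterior mean state; boundary values are 'uncertain'."""
    lo, hi = cutoffs
    if not (1.0 < lo < hi < 2.0):
        raise ValueError(f"need 1 < lo < hi < 2, got {cutoffs}")
    if not 1.0 <= b_hat <= 2.0:
        raise ValueError(f"posterior mean state {b_hat} outside [1, 2]")
    if b_hat < lo:
        return "transit"
    if b_hat > hi:
        return "ARS"
    return "uncertain"


def classify_series(
    ptt: str,
    segment_label: str,
    b_hat: np.ndarray,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> BehaviourSeries:
    labels = [classify_state(float(v), cutoffs) for v in np.asarray(b_hat, float)]
    return BehaviourSeries(ptt, segment_label, np.asarray(b_hat, float), labels)


def largest_remainder_percentages(counts: Sequence[int]) -> list[int]:
    """Integer percentages of ``counts`` summing to exactly 100.

    Each share gets its floored percentage; the leftover points go to the
    largest fractional remainders, ties broken by position (earlier wins).
    """
    total = int(sum(counts))
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    exact = [100.0 * c / total for c in counts]
    floors = [int(np.floor(e)) for e in exact]
    leftover = 100 - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def summarise_track(series: BehaviourSeries, days_of_transmission: float | None = None) -> TrackReport:
    """Table-style report: integer label percentages summing to 100."""
    if len(series.labels) == 0:
        raise ValueError("empty behaviour series")
    counts = [series.labels.count(lab) for lab in LABELS]
    pct = largest_remainder_percentages(counts)
    return TrackReport(
        ptt=series.ptt,
        segment_label=series.segment_label,
        days_of_transmission=float(days_of_transmission or 0.0),
        pct_transit=pct[0],
        pct_ars=pct[1],
        pct_uncertain=pct[2],
    )


def pooled_label_fractions(series_list: Iterable[BehaviourSeries]) -> dict[str, float]:
    """Percentages of each label pooled over all locations of all segments.

    Pooling (not averaging per-segment percentages) weights every location
    equally, matching a 'percentage of locations' definition.
    """
    counts = {lab: 0 for lab in LABELS}
    total = 0
    for s in series_list:
        for lab in s.labels:
            counts[lab] += 1
            total += 1
    if total == 0:
        raise ValueError("no locations in any series")
    return {lab: 100.0 * c / total for lab, c in counts.items()}


def pooled_ars_fraction(series_list: Iterable[BehaviourSeries]) -> float:
    return pooled_label_fractions(series_list)["ARS"]


def reports_to_frame(reports: Sequence[TrackReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ptt": [r.ptt for r in reports],
            "segment": [r.segment_label for r in reports],
            "days_of_transmission": [r.days_of_transmission for r in reports],
            "pct_transit": [r.pct_transit for r in reports],
            "pct_ars": [r.pct_ars for r in reports],
            "pct_uncertain": [r.pct_uncertain for r in reports],
        }
    )
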