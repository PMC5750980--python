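"""Extended heat-wave periods (EHP) and mortality displacement.

Heat stress rarely respects the thresholded event boundaries: mortality
may already be elevated shortly before a heat wave, and a post-event
*deficit* — deaths merely advanced by days (harvesting / short-term
mortality displacement) — can offset part of the event's excess.  To bound
both effects, each heat wave is embedded in an extended heat-wave period:

* smooth the daily relative mortality deviations with a 3-day centered
  moving average;
* walk backward from the event start while the smoothed deviation stays
  positive — the EHP begins at the first day of that contiguous positive
  run;
* walk forward from the event end: the *positive phase* ends at the last
  day of the contiguous positive run; the *negative phase* then extends
  while the smoothed deviation stays negative, and the EHP ends with it;
* successive events with no drop of the smoothed deviation to or below
  zero between them merge into a single EHP.

Displaced mortality is |negative-phase sum| / positive-phase sum × 100 —
the share of the positive-phase excess apparently offset by the deficit.
A smoothed value of exactly zero terminates a phase, and scans are capped
(default 30 days from the event) to prevent runaway periods.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .heatmetrics import HeatWave

__all__ = ["EhpSummary", "moving_average_3", "delimit_ehps", "delimit_ehp", "displacement_ratio", "ehp_table"]

_DAY = pd.Timedelta(days=1)


@dataclass(frozen=True)
class EhpSummary:
    """One extended heat-wave period (possibly covering merged events)."""

    heat_wave_ids: tuple[str, ...]
    ehp_start: dt.date
    ehp_end: dt.date
    positive_phase_end: dt.date
    positive_sum: float
    negative_sum: float
    displaced_pct: Optional[float]  # None when positive_sum <= 0
    degenerate: bool = False  # no positive smoothed deviation at the event start


def moving_average_3(deviations: pd.Series) -> pd.Series:
    """3-day centered moving average; undefined (NaN) at the series ends."""
    if len(deviations) < 3:
        raise ValueError("need at least 3 days for a centered 3-day average")
    out = deviations.rolling(3, center=True).mean()
    out.name = "smoothed"
    return out


def displacement_ratio(ehp: EhpSummary) -> float:
    """Displaced mortality %: 100·|negative_sum| / positive_sum."""
    if ehp.positive_sum <= 0:
        raise ValueError("displacement undefined for non-positive positive-phase sum")
    return 100.0 * abs(ehp.negative_sum) / ehp.positive_sum


def _positive(x: float) -> bool:
    return bool(np.isfinite(x) and x > 0)


def _negative(x: float) -> bool:
    return bool(np.isfinite(x) and x < 0)


def delimit_ehps(
    heat_waves: Sequence[HeatWave],
    smoothed: pd.Series,
    scan_cap: int = 30,
) -> list[EhpSummary]:
    """Delimit the EHP of every event, merging events where the smoothed
    deviation never drops to or below zero between them.

    ``smoothed`` is the 3-day-averaged deviation series covering the events
    (NaN allowed at the ends).  Returns one summary per EHP in order; a
    merged EHP lists all ids it covers.
    """
    events = sorted(heat_waves, key=lambda h: h.start)
    out: list[EhpSummary] = []
    idx = smoothed.index
    i = 0
    while i < len(events):
        first = events[i]
        # merge forward while the inter-event gap never drops to <= 0
        j = i
        while j + 1 < len(events):
            gap = pd.date_range(
                pd.Timestamp(events[j].end) + _DAY,
                pd.Timestamp(events[j + 1].start) - _DAY,
                freq="D",
            )
            if len(gap) == 0 or (
                gap.isin(idx).all()
                and all(_positive(smoothed.loc[d]) for d in gap)
            ):
                j += 1
            else:
                break
        last = events[j]
        next_start = (
            pd.Timestamp(events[j + 1].start) if j + 1 < len(events) else None
        )

        start_ts = pd.Timestamp(first.start)
        end_ts = pd.Timestamp(last.end)

        degenerate = not (
            start_ts in idx and _positive(smoothed.loc[start_ts])
        )
        if degenerate:
            # no positive smoothed deviation at the event start: the EHP
            # degenerates to the event itself, flagged
            days = pd.date_range(start_ts, end_ts, freq="D")
            positive_sum = float(smoothed.reindex(days).fillna(0.0).sum())
            out.append(
                EhpSummary(
                    heat_wave_ids=tuple(e.id for e in events[i : j + 1]),
                    ehp_start=start_ts.date(),
                    ehp_end=end_ts.date(),
                    positive_phase_end=end_ts.date(),
                    positive_sum=positive_sum,
                    negative_sum=0.0,
                    displaced_pct=0.0 if positive_sum > 0 else None,
                    degenerate=True,
                )
            )
            i = j + 1
            continue
        else:
            d = start_ts
            while (
                (start_ts - (d - _DAY)).days <= scan_cap
                and (d - _DAY) in idx
                and _positive(smoothed.loc[d - _DAY])
            ):
                d -= _DAY
            ehp_start = d

        # positive phase: contiguous positive run after the (last) event end
        pos_end = end_ts
        d = end_ts + _DAY
        while (
            (d - end_ts).days <= scan_cap
            and d in idx
            and (next_start is None or d < next_start)
            and _positive(smoothed.loc[d])
        ):
            pos_end = d
            d += _DAY

        # negative phase: contiguous negative run after the positive phase
        neg_end = pos_end
        d = pos_end + _DAY
        while (
            (d - end_ts).days <= scan_cap
            and d in idx
            and (next_start is None or d < next_start)
            and _negative(smoothed.loc[d])
        ):
            neg_end = d
            d += _DAY

        pos_days = pd.date_range(ehp_start, pos_end, freq="D")
        positive_sum = float(smoothed.reindex(pos_days).fillna(0.0).sum())
        if neg_end > pos_end:
            neg_days = pd.date_range(pos_end + _DAY, neg_end, freq="D")
            negative_sum = float(smoothed.reindex(neg_days).fillna(0.0).sum())
        else:
            negative_sum = 0.0

        displaced = (
            100.0 * abs(negative_sum) / positive_sum if positive_sum > 0 else None
        )
        out.append(
            EhpSummary(
                heat_wave_ids=tuple(e.id for e in events[i : j + 1]),
                ehp_start=ehp_start.date(),
                ehp_end=neg_end.date(),
                positive_phase_end=pos_end.date(),
                positive_sum=positive_sum,
                negative_sum=negative_sum,
                displaced_pct=displaced,
                degenerate=degenerate,
            )
        )
        i = j + 1
    return out


def delimit_ehp(hw: HeatWave, smoothed: pd.Series, scan_cap: int = 30) -> EhpSummary:
    """EHP of a single event (no merging with neighbours considered)."""
    return delimit_ehps([hw], smoothed, scan_cap=scan_cap)[0]


def ehp_table(ehps: Sequence[EhpSummary]) -> pd.DataFrame:
    """Report table, one row per heat wave: events absorbed into a merged
    EHP carry the ``---`` sentinel and the EHP row sits on its last event."""
    rows = []
    for ehp in ehps:
        for k, hw_id in enumerate(ehp.heat_wave_ids):
            absorbed = k < len(ehp.heat_wave_ids) - 1
            rows.append(
                {
                    "id": hw_id,
                    "ehp_start": "---" if absorbed else ehp.ehp_start.isoformat(),
                    "ehp_end": "---" if absorbed else ehp.ehp_end.isoformat(),
                    "positive_phase_end": "---"
                    if absorbed
                    else ehp.positive_phase_end.isoformat(),
                    "displaced_pct": "---"
                    if absorbed
                    else (
                        ""
                        if ehp.displaced_pct is None
                        else f"{ehp.displaced_pct:.1f}"
                    ),
                    "degenerate": "" if absorbed else ("flagged" if ehp.degenerate else ""),
                }
            )
    columns = ["id", "ehp_start", "ehp_end", "positive_phase_end", "displaced_pct", "degenerate"]
    return pd.DataFrame(rows, columns=columns)
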