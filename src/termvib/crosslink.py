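"""Cross-link laser-detected vibration events to video-scored behaviors.

A vibration event can only be attributed to one animal when exactly one
scored body-shaking interval is concurrent with it.  Events concurrent
with behaviors of several workers — or with none — are retained in the
match report but discarded from structure analyses.  A symmetric time
tolerance absorbs video-versus-laser clock skew and scoring latency.
"""

from __future__ import annotations

from typing import List, Sequence

from .types import BehaviorLog, MatchResult, VibrationEvent


def match_events(
    events: Sequence[VibrationEvent],
    log: BehaviorLog,
    tolerance: float = 0.2,
) -> List[MatchResult]:
    """Match each event to the behavior intervals that overlap it.

    An event and a behavior record overlap when their half-open intervals,
    each expanded by ``tolerance`` on both sides, intersect.  The unique
    flag is set iff exactly one behavior record overlaps; the flag is also
    written back onto the event.  Non-unique events stay in the output so
    the report is complete, with a discard reason of
    ``"no-behavior-match"`` or ``"multiple-concurrent-behaviors"``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    results = []
    for eid, ev in enumerate(events):
        lo, hi = ev.onset - tolerance, ev.offset + tolerance
        matched = tuple(
            bid for bid, rec in enumerate(log)
            if lo < rec.offset + tolerance and rec.onset - tolerance < hi
        )
        if len(matched) == 1:
            unique, reason = True, None
        elif len(matched) == 0:
            unique, reason = False, "no-behavior-match"
        else:
            unique, reason = False, "multiple-concurrent-behaviors"
        ev.unique_flag = unique
        results.append(MatchResult(event_id=eid, matched_behavior_ids=matched,
                                   unique_flag=unique, discard_reason=reason))
    return results


def uniqueness_fraction(results: Sequence[MatchResult]) -> float:
    """Fraction of events attributable to exactly one scored behavior."""
    if not results:
        raise ValueError("uniqueness_fraction needs a non-empty result list")
    return sum(r.unique_flag for r in results) / len(results)
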