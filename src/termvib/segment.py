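"""Part segmentation, body-shaking typing, and structure metrics.

A vibration event is a train of pulses; its internal structure is a
sequence of "parts", each a contiguous run of pulses at a homogeneous
pulse rate.  Part boundaries are found from inter-pulse intervals (IPIs)
rather than any spectral quantity, because the frequency of interest is a
pulse *rate* (pulses divided by duration): a change of rate is directly a
change of IPI scale.

The boundary rule places a break after pulse i when its IPI exceeds
``gap_ratio`` times the median of the non-boundary IPIs; the median is
re-computed as boundaries are found (the set of boundaries grows
monotonically, so the iteration terminates).  Undersized fragments are
then merged into the neighbour across the smaller gap — this reassembles
slow parts whose own IPIs resemble the inter-part gap.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional

import numpy as np

from .types import Part, Pulse, Treatment, VibrationEvent

log = logging.getLogger(__name__)


def segment_parts(
    event_pulses: List[Pulse],
    gap_ratio: float = 3.0,
    min_part_pulses: int = 2,
    merge_ratio: float = 1.5,
) -> List[Part]:
    """Split one raw event's pulses into frequency-homogeneous parts.

    Parameters
    ----------
    event_pulses
        Time-sorted pulses of a single raw event.
    gap_ratio
        An IPI longer than ``gap_ratio`` times the running median IPI is a
        part boundary.  The default 3.0 separates the observed high
        (~26 ms IPI) and low (~70 ms IPI) pulse-rate regimes with margin.
    min_part_pulses
        Fragments with fewer pulses are merged into the nearer neighbour;
        2 is the minimum for a defined pulse rate.
    merge_ratio
        After fragment merging, adjacent parts are re-joined when the gap
        between them is at most ``merge_ratio`` times their internal IPI
        scale — a slow part shattered by the global median rule rejoins
        itself (its fragments are spaced exactly at its own IPI), while a
        genuine inter-part gap (>= gap_ratio times the slower part's IPI
        by construction of the boundary rule) survives.

    Returns
    -------
    list of Part
        At least one part, each with ``frequency = n_pulses/duration``.
        An event with fewer than 2 pulses is discarded (empty list, with a
        logged reason) since no rate is defined for it.
    """
    if gap_ratio <= 0:
        raise ValueError("gap_ratio must be strictly positive")
    if len(event_pulses) < 2:
        log.warning("discarding event with %d pulse(s): no pulse rate defined",
                    len(event_pulses))
        return []
    times = np.array([p.time for p in event_pulses])
    amps = np.array([p.amplitude for p in event_pulses])
    if np.any(np.diff(times) <= 0):
        raise ValueError("event pulses must be strictly increasing in time")

    ipis = np.diff(times)
    boundary = np.zeros(ipis.size, dtype=bool)
    for _ in range(ipis.size + 1):
        inner = ipis[~boundary]
        if inner.size == 0:
            break
        # The scale of "ordinary" IPIs is taken from the lower quartile of
        # the non-boundary IPIs: in events with several slow parts the slow
        # IPIs outnumber the fast first-part IPIs, so a median would drift
        # onto the slow block and push the boundary threshold up to the
        # inter-part gap itself; the lower quartile stays anchored on the
        # fastest pulse train.  Slow parts whose own IPIs then exceed the
        # threshold get shattered and are reassembled below.
        new = ipis > gap_ratio * np.quantile(inner, 0.25)
        if np.array_equal(new, boundary):
            break
        boundary = new  # monotone: the quantile can only shrink

    # Runs of pulse indices between boundaries.
    groups: List[List[int]] = [[0]]
    for i, is_b in enumerate(boundary):
        if is_b:
            groups.append([])
        groups[-1].append(i + 1)

    # Merge undersized fragments into a neighbour.  Fragments of a
    # shattered slow part should find each other rather than leak into an
    # adjacent full-size part, so an undersized neighbour is preferred when
    # its gap is on the same scale as the alternative (within merge_ratio);
    # otherwise the smaller gap wins, ties go left.
    while len(groups) > 1 and min(len(g) for g in groups) < min_part_pulses:
        sizes = [len(g) for g in groups]
        j = sizes.index(min(sizes))

        def _option(side: int):
            nb = j + side
            if not 0 <= nb < len(groups):
                return None
            if side < 0:
                gap = times[groups[j][0]] - times[groups[nb][-1]]
            else:
                gap = times[groups[nb][0]] - times[groups[j][-1]]
            undersized = len(groups[nb]) < min_part_pulses
            return (undersized, gap, side)

        options = [o for o in (_option(-1), _option(+1)) if o is not None]
        if len(options) == 2:
            a, b = options
            if a[0] != b[0]:
                small, other = (a, b) if a[0] else (b, a)
                pick = small if small[1] <= merge_ratio * other[1] else \
                    min(options, key=lambda o: (o[1], o[2]))
            else:
                pick = min(options, key=lambda o: (o[1], o[2]))
        else:
            pick = options[0]
        if pick[2] < 0:
            groups[j - 1].extend(groups[j])
            del groups[j]
        else:
            groups[j] = groups[j] + groups[j + 1]
            del groups[j + 1]

    # Reassembly pass: re-join adjacent parts whose joining gap matches
    # their internal IPI scale (they are fragments of one pulse train).
    changed = True
    while changed and len(groups) > 1:
        changed = False
        for j in range(len(groups) - 1):
            left, right = groups[j], groups[j + 1]
            gap = times[right[0]] - times[left[-1]]
            scales = []
            for g in (left, right):
                if len(g) >= 2:
                    scales.append(float(np.median(np.diff(times[g]))))
            if scales and gap <= merge_ratio * min(scales):
                groups[j] = left + right
                del groups[j + 1]
                changed = True
                break

    parts = []
    for k, g in enumerate(groups, start=1):
        parts.append(Part(
            index=k,
            onset=float(times[g[0]]),
            offset=float(times[g[-1]]),
            n_pulses=len(g),
            amplitude=float(amps[g].mean()),
        ))
    return parts


def classify_event(parts: List[Part]) -> int:
    """Body-shaking type = the number of parts.

    One part is BS1, two parts BS2, and so on.  Events with more than six
    parts return their literal part count; downstream code flags them as
    beyond the described BS1-BS6 range (see
    :attr:`termvib.types.VibrationEvent.beyond_range`) and excludes them
    from BS-type summaries by default.
    """
    if not parts:
        raise ValueError("cannot classify an event with no parts")
    return len(parts)


def build_event(
    parts: List[Part],
    colony_id: Optional[str] = None,
    treatment: Optional[Treatment] = None,
) -> VibrationEvent:
    """Assemble a typed :class:`VibrationEvent` from segmented parts."""
    classify_event(parts)
    return VibrationEvent(parts=list(parts), colony_id=colony_id,
                          treatment=treatment)


def event_metrics(event: VibrationEvent) -> dict:
    """Structure summary of one event in the three reporting views.

    Returns the whole-event (all parts pooled), first-part-only, and
    last-part-only views used when comparing structures across types, plus
    per-part rows.  For a one-part event the first- and last-part views
    are identical.  The pooled frequency divides the total pulse count by
    the whole-event duration (inter-part gaps included).
    """
    def view(p: Part) -> dict:
        return {"duration": p.duration, "n_pulses": p.n_pulses,
                "amplitude": p.amplitude, "frequency": p.frequency}

    pooled = {
        "duration": event.total_duration,
        "n_pulses": event.total_pulses,
        "amplitude": event.mean_amplitude,
        "frequency": event.total_pulses / event.total_duration,
    }
    return {
        "bs_type": event.bs_type,
        "beyond_range": event.beyond_range,
        "pooled": pooled,
        "first_part": view(event.parts[0]),
        "last_part": view(event.parts[-1]),
        "parts": [view(p) for p in event.parts],
    }
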