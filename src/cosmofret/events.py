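"""Assembly of per-DNA measurements into helicase-loading events.

A loading *attempt* starts when an Mcm2-7 arrival step is seen on an
empty DNA and ends when every arrival has been matched by a departure (or
the record ends).  An attempt with exactly two Mcm2-7 arrivals, both
retained longer than the 48-s (20-frame) threshold, is a successful
double-hexamer formation event; a short-lived second association is an
unsuccessful event.  ORC usage during the recruitment interval is counted
from the donor record, and the high-FRET intervals are attributed to the
arrivals they accompany to type the event's FRET profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .analysis import PresenceInterval, StepEvent, TraceAnalysis
from .params import AnalysisParams

FRET_PROFILES = ("two_peak", "first_only", "second_only", "none")


@dataclass
class McmAssociation:
    """One Mcm2-7 arrival and its retention on the DNA."""

    t_arrive: float
    t_depart: Optional[float]     # None = retained to record end
    censored: bool

    @property
    def retention(self) -> float:
        return (self.t_depart - self.t_arrive) if self.t_depart is not None \
            else np.inf


@dataclass
class EventRecord:
    """A classified loading attempt (successful or not)."""

    dna_id: int
    associations: List[McmAssociation] = field(default_factory=list)
    success: bool = False
    orc_count_class: str = ""          # "1" | "2_sequential" | "2_overlap" | "3+"
    orc_unlabeled: bool = False
    om1: Optional[PresenceInterval] = None
    om2: Optional[PresenceInterval] = None
    mo: Optional[PresenceInterval] = None
    cdt1_release_times: List[float] = field(default_factory=list)
    fret_profile: str = ""
    inferred_type: str = "NA"
    anomalous_fret: bool = False

    @property
    def t_m1(self) -> Optional[float]:
        return self.associations[0].t_arrive if self.associations else None

    @property
    def t_m2(self) -> Optional[float]:
        return self.associations[1].t_arrive if len(self.associations) > 1 \
            else None

    @property
    def retention_1(self) -> Optional[float]:
        return self.associations[0].retention if self.associations else None

    @property
    def retention_2(self) -> Optional[float]:
        return self.associations[1].retention \
            if len(self.associations) > 1 else None


def group_attempts(steps: Sequence[StepEvent],
                   record_end_s: float) -> List[List[McmAssociation]]:
    """Group arrival/departure steps into attempts.

    Arrivals push onto a stack; each departure pops the most recent open
    arrival (half-loss steps are Cdt1 releases, not occupancy changes).
    An attempt closes when its stack empties; arrivals still open at the
    record end are censored.
    """
    attempts: List[List[McmAssociation]] = []
    open_assoc: List[McmAssociation] = []
    current: List[McmAssociation] = []
    for s in sorted(steps, key=lambda s: s.time_s):
        if s.classification == "arrival":
            a = McmAssociation(s.time_s, None, censored=True)
            if not open_assoc:
                if current:
                    attempts.append(current)
                current = []
            open_assoc.append(a)
            current.append(a)
        elif s.classification == "departure":
            if open_assoc:
                a = open_assoc.pop()
                a.t_depart = s.time_s
                a.censored = False
    if current:
        attempts.append(current)
    # censor still-open associations at the record end
    for att in attempts:
        for a in att:
            if a.t_depart is None:
                a.t_depart = record_end_s
    return attempts


def find_double_hexamer_events(
    analysis: TraceAnalysis,
    record_end_s: float,
    cfg: Optional[AnalysisParams] = None,
) -> List[EventRecord]:
    """Build EventRecords from one trace's acceptor steps.

    Success requires exactly two Mcm2-7 arrivals with both retentions above
    the 48-s threshold (>= 20 acquisition frames of the Mcm channel);
    shorter second associations yield unsuccessful events.
    """
    cfg = cfg or AnalysisParams()
    thr = cfg.retention_threshold_s
    events: List[EventRecord] = []
    for att in group_attempts(analysis.acceptor_steps, record_end_s):
        ev = EventRecord(dna_id=analysis.dna_id, associations=att)
        if len(att) == 2:
            r1 = att[0].t_depart - att[0].t_arrive
            r2 = att[1].t_depart - att[1].t_arrive
            ev.success = (r1 > thr) and (r2 > thr)
        # Cdt1 releases inside the attempt window
        t0 = att[0].t_arrive
        t1 = max(a.t_depart for a in att)
        ev.cdt1_release_times = [
            s.time_s for s in analysis.acceptor_steps
            if s.classification == "half_loss" and t0 <= s.time_s <= t1]
        events.append(ev)
    return events


def per_orc_intervals(donor_intervals: Sequence[PresenceInterval],
                      donor_steps: Sequence[StepEvent],
                      unit_intensity: float) -> List[PresenceInterval]:
    """Decompose the donor record into per-ORC-molecule intervals.

    Within each detected donor presence interval, count transitions larger
    than ~0.65 of one fluorophore unit change the ORC count (smaller steps
    are PIFE); overlapping molecules are resolved LIFO (which physical ORC
    leaves first is not observable from intensity alone).
    """
    out: List[PresenceInterval] = []
    for iv in donor_intervals:
        changes: List[Tuple[float, int]] = []
        for s in donor_steps:
            if iv.t_start < s.time_s < iv.t_end:
                n = int(round(s.magnitude / unit_intensity))
                if n >= 1:
                    changes.append((s.time_s, n if s.direction == "up" else -n))
        stack = [PresenceInterval("orc", iv.t_start, iv.t_end,
                                  iv.right_censored)]
        closed: List[PresenceInterval] = []
        for t, dn in sorted(changes):
            if dn > 0:
                for _ in range(dn):
                    stack.append(PresenceInterval("orc", t, iv.t_end,
                                                  iv.right_censored))
            else:
                for _ in range(-dn):
                    if len(stack) > 1:  # the base molecule ends with the run
                        a = stack.pop()
                        closed.append(PresenceInterval("orc", a.t_start, t,
                                                       False))
        out.extend(closed)
        out.extend(stack)
    return sorted(out, key=lambda iv: iv.t_start)


def count_orc(event: EventRecord,
              orc_intervals: Sequence[PresenceInterval],
              tol_s: float = 2.4) -> str:
    """Classify ORC usage during the two-Mcm recruitment interval.

    "1": a single ORC interval spans [m1, m2]; "2_sequential": the first
    ORC ends before a second starts pre-m2; "2_overlap": a second ORC joins
    while the first persists; "3+": anything else.  With no overlapping ORC
    interval the event is flagged unlabeled-ORC (excluded from FRET
    analyses) and the class is left empty.
    """
    m1 = event.t_m1
    m2 = event.t_m2 if event.t_m2 is not None else m1
    ov = [iv for iv in orc_intervals
          if iv.t_end > m1 - tol_s and iv.t_start < m2 + tol_s]
    if not ov:
        event.orc_unlabeled = True
        event.orc_count_class = ""
        return ""
    ov = sorted(ov, key=lambda iv: iv.t_start)
    spanning = [iv for iv in ov
                if iv.t_start <= m1 + tol_s and iv.t_end >= m2 - tol_s]
    if len(ov) == 1 and spanning:
        cls = "1"
    elif len(ov) == 2:
        a, b = ov
        if b.t_start < a.t_end - tol_s:
            cls = "2_overlap"
        else:
            cls = "2_sequential"
    else:
        cls = "3+"
    event.orc_count_class = cls
    return cls


def classify_fret_profile(
    event: EventRecord,
    fret_intervals: Sequence[PresenceInterval],
    window_s: float = 4.8,
    design_kind: Optional[str] = None,
) -> Tuple[str, str]:
    """Attribute high-FRET onsets to Mcm2-7 arrivals and type the profile.

    A peak belongs to arrival i when its onset is within +-window_s of that
    arrival.  Profiles: two_peak / first_only / second_only / none.  Under
    a mixed-label design ("mixed_mcm" or "mixed_orc") the profile maps to
    the inferred molecular type: two_peak->CC, first_only->CN,
    second_only->NC, none->NN; otherwise inferred_type is "NA".  Intervals
    attributable to neither arrival flag the event anomalous.
    """
    m1, m2 = event.t_m1, event.t_m2
    has1 = has2 = False
    anomalous = False
    for iv in fret_intervals:
        hit = False
        if m1 is not None and abs(iv.t_start - m1) <= window_s:
            has1, hit = True, True
        if m2 is not None and abs(iv.t_start - m2) <= window_s:
            has2, hit = True, True
        if not hit:
            anomalous = True
    if has1 and has2:
        profile = "two_peak"
    elif has1:
        profile = "first_only"
    elif has2:
        profile = "second_only"
    else:
        profile = "none"
    inferred = "NA"
    if design_kind in ("mixed_mcm", "mixed_orc"):
        inferred = {"two_peak": "CC", "first_only": "CN",
                    "second_only": "NC", "none": "NN"}[profile]
    event.fret_profile = profile
    event.inferred_type = inferred
    event.anomalous_fret = anomalous
    return profile, inferred


def coincidence(time_a: Optional[float], time_b: Optional[float],
                window_s: float = 2.4) -> Optional[Tuple[str, float]]:
    """Temporal-coincidence call for two event times on the same DNA.

    Returns (relation, lag) with lag = time_a - time_b, signed;
    simultaneous iff |lag| <= window_s (the +-2.4-s experimental time
    resolution), otherwise the earlier event is named: positive lag means
    b preceded a ("b_first").  A missing time returns None (excluded).
    """
    if time_a is None or time_b is None:
        return None
    lag = time_a - time_b
    if abs(lag) <= window_s:
        return ("simultaneous", lag)
    return (("b_first", lag) if lag > 0 else ("a_first", lag))


def attach_fret_to_event(
    event: EventRecord,
    fret_intervals: Sequence[PresenceInterval],
    reporter: str,
    window_s: float = 4.8,
) -> None:
    """Attach detected high-FRET intervals to an event.

    For the OM reporter, the interval whose onset matches arrival 1 / 2 is
    om1 / om2.  For the MO reporter there is exactly one MO interaction
    per event, so every high-FRET fragment inside the recruitment window
    belongs to it: fragments are merged into a single interval (gated to
    start no earlier than the first Cdt1 release, when one is measured).
    """
    m1, m2 = event.t_m1, event.t_m2
    if reporter == "om":
        for iv in fret_intervals:
            if m1 is not None and abs(iv.t_start - m1) <= window_s \
                    and event.om1 is None:
                event.om1 = iv
            elif m2 is not None and abs(iv.t_start - m2) <= window_s \
                    and event.om2 is None:
                event.om2 = iv
    else:
        rel1 = event.cdt1_release_times[0] if event.cdt1_release_times \
            else None
        lo = rel1 - window_s if rel1 is not None else (
            m1 - window_s if m1 is not None else -np.inf)
        hi = m2 + window_s if m2 is not None else np.inf
        cands = [iv for iv in fret_intervals
                 if iv.t_start >= lo and iv.t_start <= hi
                 and (m1 is None or iv.t_end > m1)]
        if cands:
            event.mo = PresenceInterval(
                "fret_high", cands[0].t_start, cands[-1].t_end,
                cands[-1].right_censored)


def assemble_events(
    analysis: TraceAnalysis,
    record_end_s: float,
    reporter: str = "om",
    unit_intensity: float = 1000.0,
    cfg: Optional[AnalysisParams] = None,
    design_kind: Optional[str] = None,
) -> List[EventRecord]:
    """Full per-trace event assembly: attempts, ORC counting, FRET typing."""
    cfg = cfg or AnalysisParams()
    events = find_double_hexamer_events(analysis, record_end_s, cfg)
    orc_iv = per_orc_intervals(analysis.donor_intervals, analysis.donor_steps,
                               unit_intensity)
    for ev in events:
        count_orc(ev, orc_iv, tol_s=cfg.coincidence_window_s)
        attach_fret_to_event(ev, analysis.fret_intervals, reporter,
                             cfg.attribution_window_s)
        classify_fret_profile(ev, analysis.fret_intervals,
                              cfg.attribution_window_s, design_kind)
    return events
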