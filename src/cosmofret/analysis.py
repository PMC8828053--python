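"""Per-molecule measurement layer: background correction, presence
intervals, stepwise intensity changes, and apparent-FRET series.

Conventions (used throughout the package):

* An event time is the *start time of the first frame in the new state*;
  duration comparisons use the 2.4-s acquisition cycle as one time unit.
* Apparent FRET efficiency is E = I_Aem / (I_Aem + I_Dem) on donor-excited
  frames, computed only where both a donor and at least one acceptor are
  present; values are never clamped, and histogram-style exports exclude
  |E| > 2.
* Presence detection is hysteresis thresholding: a run turns on when the
  signal exceeds k_on * sigma and extends over contiguous frames above
  k_off * sigma.  An interval that reaches the end of the record (or ends
  with a known bleach) is right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .params import AnalysisParams, ConfigurationError
from .traces import Trace


@dataclass
class PresenceInterval:
    """A contiguous period during which a labeled species is on the DNA."""

    channel: str
    t_start: float
    t_end: float
    right_censored: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class StepEvent:
    """A stepwise intensity change in an intensity record."""

    time_s: float
    channel: str
    direction: str            # "up" | "down"
    magnitude: float          # absolute step size, raw intensity units
    classification: str = ""  # "arrival" | "departure" | "half_loss"


@dataclass
class EfretSeries:
    """Apparent-FRET values on donor-excited frames with a validity mask."""

    time_s: np.ndarray
    efret: np.ndarray
    valid: np.ndarray

    def histogram_values(self) -> np.ndarray:
        """Valid E values with the |E| > 2 exclusion rule applied."""
        e = self.efret[self.valid]
        return e[(e >= -2.0) & (e <= 2.0)]


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise scale from the median absolute successive difference.

    Insensitive to steps and plateaus; for i.i.d. Gaussian noise the MAD of
    first differences equals sigma * sqrt(2) * 0.6745^-1 ... we invert that.
    """
    d = np.diff(np.asarray(y, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (np.sqrt(2.0) * 0.674489750196082))


def correct_background(y: np.ndarray, sigma: Optional[float] = None,
                       k: float = 3.0) -> tuple:
    """Subtract the per-channel baseline (median of frames outside detected
    presence, iterated once).

    Returns (corrected, baseline, fallback_flag); the fallback flag is set
    when every frame appears occupied and a global robust baseline (overall
    median) is used instead.
    """
    y = np.asarray(y, dtype=float)
    if sigma is None:
        sigma = robust_noise_sd(y)
    sigma = max(sigma, 1e-12)
    # seed from the lowest sustained level (minimum sliding-window
    # median), so occupancy covering most of the record cannot drag the
    # baseline onto an occupied level; then refine on the low cluster
    # (initial pass + one iteration)
    w = max(3, min(15, len(y) // 4))
    if len(y) >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        baseline = float(np.median(sliding_window_view(y, w), axis=1).min())
    else:
        baseline = float(np.min(y))
    fallback = False
    for _ in range(2):
        outside = y < baseline + k * sigma
        if not outside.any():
            fallback = True
            baseline = float(np.median(y))
            break
        baseline = float(np.median(y[outside]))
    return y - baseline, baseline, fallback


def detect_presence(
    y: np.ndarray,
    t: np.ndarray,
    channel: str = "",
    on_threshold_sd: float = 4.0,
    off_threshold_sd: float = 2.0,
    sigma: Optional[float] = None,
    frame_period: Optional[float] = None,
) -> List[PresenceInterval]:
    """Hysteresis presence detection on a background-corrected record.

    A presence interval is a maximal run of frames above ``off_threshold_sd
    * sigma`` containing at least one frame above ``on_threshold_sd *
    sigma``.  The interval end is the start time of the first frame below
    the off threshold; a run ending at the last frame is right-censored at
    the record end.
    """
    if on_threshold_sd <= 0 or off_threshold_sd <= 0:
        raise ConfigurationError("presence thresholds must be positive")
    if on_threshold_sd < off_threshold_sd:
        raise ConfigurationError("on threshold must be >= off threshold")
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if sigma is None:
        sigma = robust_noise_sd(y)
    if sigma <= 0:
        sigma = 1e-12
    if frame_period is None:
        frame_period = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    above_off = y >= off_threshold_sd * sigma
    above_on = y >= on_threshold_sd * sigma
    intervals: List[PresenceInterval] = []
    n = len(y)
    i = 0
    while i < n:
        if not above_off[i]:
            i += 1
            continue
        j = i
        while j < n and above_off[j]:
            j += 1
        if above_on[i:j].any():
            censored = j >= n
            t_end = t[j] if j < n else t[-1] + frame_period
            intervals.append(PresenceInterval(channel, float(t[i]),
                                              float(t_end), censored))
        i = j
    return intervals


def _best_split(y: np.ndarray, min_seg: int, sigma: float) -> tuple:
    """Changepoint candidate maximising the between-segment mean contrast.

    Uses cumulative sums for O(n) evaluation of all splits.  Significance
    is a known-sigma z test on the mean difference, Bonferroni-corrected
    for the number of candidate splits (a per-split test at a fixed alpha
    would fire on pure noise once ~1/alpha candidates are scanned).
    Returns (index, p_value) where index is the first frame of the right
    segment.
    """
    n = len(y)
    if n < 2 * min_seg:
        return -1, 1.0
    c = np.concatenate([[0.0], np.cumsum(y)])
    ks = np.arange(min_seg, n - min_seg + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = c[ks] / n1
    m2 = (c[n] - c[ks]) / n2
    se = sigma * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = np.abs(m1 - m2) / se
    best = int(np.argmax(z))
    k = int(ks[best])
    p = 2.0 * float(sps.norm.sf(z[best]))
    return k, min(1.0, p * len(ks))


def _segment(y: np.ndarray, lo: int, hi: int, alpha: float, min_seg: int,
             sigma: float, out: List[int]) -> None:
    k, p = _best_split(y[lo:hi], min_seg, sigma)
    if k < 0 or p >= alpha:
        return
    split = lo + k
    out.append(split)
    _segment(y, lo, split, alpha, min_seg, sigma, out)
    _segment(y, split, hi, alpha, min_seg, sigma, out)


def detect_steps(
    y: np.ndarray,
    t: np.ndarray,
    channel: str = "I_Aex_Aem",
    alpha: float = 1e-3,
    min_frames: int = 2,
    sigma: Optional[float] = None,
    unit: Optional[float] = None,
    intervals: Optional[Sequence[PresenceInterval]] = None,
) -> List[StepEvent]:
    """Locate stepwise intensity changes by binary segmentation.

    When presence ``intervals`` are supplied, segmentation runs within
    each interval and the interval boundaries provide the entry/exit
    steps; this is essential because a short interior dwell has almost no
    contrast in a whole-record binary split.

    Each candidate changepoint must pass a Bonferroni-corrected
    known-sigma z test on the segment-mean difference at ``alpha`` (the
    noise scale is estimated robustly from the whole record unless given).
    Down-steps whose magnitude is 0.35--0.65 of the preceding up-step are
    classified ``half_loss`` (loss of one of two co-arrived acceptors,
    e.g. Cdt1 release); other down-steps are ``departure`` and up-steps
    ``arrival``.

    When the per-fluorophore intensity ``unit`` is known (it lives in the
    run configuration), segments are quantised to integer fluorophore
    counts and steps are emitted only at level changes.  This suppresses
    the two-half-step artifact a transition frame can induce, and a
    down-step that returns the level to zero is always a ``departure``
    (so the final exit of a molecule is never mistaken for a half-loss).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if sigma is None:
        sigma = robust_noise_sd(y)
    sigma = max(sigma, 1e-12)
    if intervals is None:
        raw = _steps_on_chunk(y, t, alpha, min_frames, sigma, unit,
                              offset_level=0.0, boundary=None)
    else:
        # segment within each presence interval; the interval boundaries
        # themselves are the arrival/departure transitions (binary
        # segmentation alone has no power against short interior dwells)
        raw = []
        frame_period = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        for iv in intervals:
            i0 = int(np.searchsorted(t, iv.t_start - 1e-9))
            i1 = int(np.searchsorted(t, iv.t_end - 1e-9))
            if i1 <= i0:
                continue
            raw.extend(_steps_on_chunk(
                y[i0:i1], t[i0:i1], alpha, min_frames, sigma, unit,
                offset_level=0.0,
                boundary=(iv.t_start, None if iv.right_censored
                          else iv.t_end)))
        raw.sort(key=lambda r: r[0])
    return _classify_steps(raw, channel, unit)


def _steps_on_chunk(y, t, alpha, min_frames, sigma, unit,
                    offset_level: float, boundary):
    """Segment one chunk; returns raw (time, delta, pre_level, post_level)
    tuples.  ``boundary`` = (t_enter, t_exit or None) adds the entry step
    from level 0 and, unless censored, the exit step back to 0."""
    splits: List[int] = []
    _segment(y, 0, len(y), alpha, min_frames, sigma, splits)
    splits = sorted(set(splits))
    # prune: a top-level binary split can land between true changepoints
    # and survive refinement; re-test every split against its immediate
    # neighbour segments and drop the weakest until all are significant
    while splits:
        bounds = [0] + splits + [len(y)]
        worst_i, worst_p = -1, -1.0
        for i in range(len(splits)):
            n1 = bounds[i + 1] - bounds[i]
            n2 = bounds[i + 2] - bounds[i + 1]
            m1 = float(np.mean(y[bounds[i]:bounds[i + 1]]))
            m2 = float(np.mean(y[bounds[i + 1]:bounds[i + 2]]))
            z = abs(m1 - m2) / (sigma * np.sqrt(1.0 / n1 + 1.0 / n2))
            p = min(1.0, 2.0 * float(sps.norm.sf(z)) * (n1 + n2 - 1))
            if p > worst_p:
                worst_i, worst_p = i, p
        if worst_p >= alpha:
            splits.pop(worst_i)
        else:
            break
    bounds = [0] + splits + [len(y)]
    means = [float(np.mean(y[bounds[i]:bounds[i + 1]]))
             for i in range(len(bounds) - 1)]
    if unit is not None:
        # quantise to fluorophore counts and keep level-changing splits only
        levels = [max(int(round(max(m, 0.0) / unit)), 0) for m in means]
        if boundary is not None and levels[0] == 0:
            levels[0] = 1  # a detected presence interval holds >= 1 dye
        keep = [(s, levels[i], levels[i + 1], means[i + 1] - means[i])
                for i, s in enumerate(splits)
                if levels[i + 1] != levels[i]]
        raw = []
        if boundary is not None:
            raw.append((boundary[0], levels[0] * unit, 0.0, float(levels[0])))
        run_level = float(levels[0])
        for s, l0, l1, dmean in keep:
            raw.append((float(t[s]), (l1 - l0) * unit, run_level, float(l1)))
            run_level = float(l1)
        if boundary is not None and boundary[1] is not None:
            raw.append((boundary[1], -run_level * unit, run_level, 0.0))
        return raw
    raw = []
    run_level = means[0]
    if boundary is not None:
        raw.append((boundary[0], means[0], 0.0, means[0]))
    for i, s in enumerate(splits):
        raw.append((float(t[s]), means[i + 1] - means[i], means[i],
                    means[i + 1]))
    if boundary is not None and boundary[1] is not None:
        raw.append((boundary[1], -means[-1], means[-1], 0.0))
    return raw


def _classify_steps(raw, channel: str, unit: Optional[float]) -> List[StepEvent]:
    """Chronological classification of raw steps.

    Up-steps are arrivals.  A down-step returning the level to zero is a
    departure; one of 0.35--0.65 the magnitude of the preceding up-step is
    a half-loss (one of two co-arrived fluorophores leaving, e.g. Cdt1
    release); anything else is a departure.
    """
    steps: List[StepEvent] = []
    last_up = None
    for time_s, delta, pre_level, post_level in raw:
        if abs(delta) <= 0:
            continue
        direction = "up" if delta > 0 else "down"
        mag = abs(delta)
        if direction == "up":
            cls = "arrival"
            last_up = mag
        elif post_level <= 0 or (unit is not None
                                 and post_level * unit < 0.5 * unit):
            cls = "departure"
        elif last_up is not None and 0.35 * last_up <= mag <= 0.65 * last_up:
            cls = "half_loss"
        else:
            cls = "departure"
        steps.append(StepEvent(float(time_s), channel, direction, mag, cls))
    return steps


def compute_efret(
    trace: Trace,
    donor_intervals: Sequence[PresenceInterval],
    acceptor_intervals: Optional[Sequence[PresenceInterval]],
) -> EfretSeries:
    """E = I_Dex_Aem / (I_Dex_Aem + I_Dex_Dem) on donor-excited frames.

    Valid only while a donor and at least one acceptor are present.  A
    non-positive denominator on a valid frame is emitted as-is (values may
    fall outside [0, 1]; no silent clamping).

    Passing ``acceptor_intervals=None`` relaxes the mask to donor presence
    only.  That is the mask used for FRET-*onset* detection: the onset is
    the earliest time the FRET signal rises above background while a donor
    is present, and the acceptor's own arrival is confirmed separately
    (within 4.8 s) rather than gating the mask — otherwise the detected
    onset inherits the acceptor channel's half-cycle grid offset.
    """
    td = trace.donor_t
    donor_ok = np.zeros(len(td), dtype=bool)
    for iv in donor_intervals:
        donor_ok |= (td >= iv.t_start) & (td < iv.t_end)
    if acceptor_intervals is None:
        acc_ok = np.ones(len(td), dtype=bool)
    else:
        acc_ok = np.zeros(len(td), dtype=bool)
        for iv in acceptor_intervals:
            acc_ok |= (td >= iv.t_start) & (td < iv.t_end)
    valid = donor_ok & acc_ok
    denom = trace.I_Dex_Aem + trace.I_Dex_Dem
    with np.errstate(divide="ignore", invalid="ignore"):
        e = trace.I_Dex_Aem / denom
    return EfretSeries(time_s=td.copy(), efret=e, valid=valid)


def detect_fret_intervals(
    efret: EfretSeries,
    high_threshold: float = 0.4,
    min_frames: int = 2,
    frame_period: float = 2.4,
    confirm_arrival_s: Optional[float] = 4.8,
    acceptor_arrivals: Optional[Sequence[float]] = None,
    max_gap_frames: int = 1,
) -> List[PresenceInterval]:
    """Contiguous runs of valid frames with E >= threshold.

    Onset/offset are the first / one-past-last qualifying frame start
    times.  Gaps of up to ``max_gap_frames`` valid-but-subthreshold frames
    inside a run are bridged (a single noisy dip should not split a
    sustained interaction).  A run truncated by loss of validity (donor
    loss or record end) rather than by E dropping is right-censored.
    When ``confirm_arrival_s`` is given together with
    ``acceptor_arrivals``, an interval whose onset has no confirmed
    acceptor arrival within the window is rejected as not genuine (the
    rule used for OM-interaction onsets; switch off for MO detection,
    whose onset deliberately trails the first Cdt1 release).
    """
    if not (0.0 < high_threshold < 1.0):
        raise ConfigurationError("high_threshold must be in (0, 1)")
    t = efret.time_s
    e = efret.efret
    v = efret.valid
    high = v & (e >= high_threshold)
    if max_gap_frames > 0:
        high = high.copy()
        n_f = len(high)
        i = 0
        while i < n_f:
            if high[i]:
                j = i + 1
                while j < n_f and high[j]:
                    j += 1
                g = j
                while g < n_f and not high[g] and v[g] and g - j < max_gap_frames:
                    g += 1
                if g < n_f and high[g] and g > j:
                    high[j:g] = True
                i = j
            else:
                i += 1
    out: List[PresenceInterval] = []
    n = len(t)
    i = 0
    while i < n:
        if not high[i]:
            i += 1
            continue
        j = i
        while j < n and high[j]:
            j += 1
        if j - i >= min_frames:
            # censored if the run ends because validity ends, not because
            # E dropped below threshold while still measurable
            censored = j >= n or not v[j]
            t_end = t[j] if j < n else t[-1] + frame_period
            out.append(PresenceInterval("fret_high", float(t[i]),
                                        float(t_end), censored))
        i = j
    if confirm_arrival_s is not None and acceptor_arrivals is not None:
        arr = np.asarray(list(acceptor_arrivals), dtype=float)
        if len(arr):
            out = [iv for iv in out
                   if np.min(np.abs(arr - iv.t_start)) <= confirm_arrival_s]
        else:
            out = []
    return out


@dataclass
class TraceAnalysis:
    """Bundle of everything the measurement layer extracts from one trace."""

    dna_id: int
    donor_intervals: List[PresenceInterval] = field(default_factory=list)
    acceptor_intervals: List[PresenceInterval] = field(default_factory=list)
    donor_steps: List[StepEvent] = field(default_factory=list)
    acceptor_steps: List[StepEvent] = field(default_factory=list)
    efret: Optional[EfretSeries] = None
    fret_intervals: List[PresenceInterval] = field(default_factory=list)
    noise_sd: float = 0.0


def analyze_trace(trace: Trace, cfg: Optional[AnalysisParams] = None,
                  sigma: Optional[float] = None,
                  confirm_arrivals: bool = True,
                  unit: Optional[float] = None) -> TraceAnalysis:
    """Run the full measurement layer on one trace.

    Donor presence is detected on donor-excited *total* emission (robust to
    the FRET-dependent redistribution between the two donor-excited
    channels, and it benefits from PIFE); acceptor presence and steps on
    the acceptor-excited record.
    """
    cfg = cfg or AnalysisParams()
    total_d = trace.I_Dex_Dem + trace.I_Dex_Aem
    sig_d = sigma * np.sqrt(2.0) if sigma is not None else None
    donor_iv = detect_presence(
        total_d, trace.donor_t, "donor", cfg.k_on, cfg.k_off, sigma=sig_d)
    acc_iv = detect_presence(
        trace.I_Aex_Aem, trace.acceptor_t, "acceptor", cfg.k_on, cfg.k_off,
        sigma=sigma)
    acc_steps = detect_steps(
        trace.I_Aex_Aem, trace.acceptor_t, "I_Aex_Aem",
        alpha=cfg.step_alpha, min_frames=cfg.step_min_frames, sigma=sigma,
        unit=unit, intervals=acc_iv)
    donor_steps = detect_steps(
        total_d, trace.donor_t, "I_Dex_total",
        alpha=cfg.step_alpha, min_frames=cfg.step_min_frames, sigma=sig_d,
        unit=unit, intervals=donor_iv)
    ef = compute_efret(trace, donor_iv, acc_iv)
    ef_detect = compute_efret(trace, donor_iv, None)
    arrivals = [s.time_s for s in acc_steps if s.classification == "arrival"]
    fret_iv = detect_fret_intervals(
        ef_detect, cfg.fret_high_threshold, cfg.fret_min_frames,
        frame_period=float(np.median(np.diff(trace.donor_t)))
        if len(trace.donor_t) > 1 else 2.4,
        confirm_arrival_s=cfg.confirm_arrival_s if confirm_arrivals else None,
        acceptor_arrivals=arrivals if confirm_arrivals else None,
        max_gap_frames=cfg.fret_max_gap_frames,
    )
    sd = sigma if sigma is not None else robust_noise_sd(trace.I_Aex_Aem)
    return TraceAnalysis(
        dna_id=trace.dna_id,
        donor_intervals=donor_iv,
        acceptor_intervals=acc_iv,
        donor_steps=donor_steps,
        acceptor_steps=acc_steps,
        efret=ef,
        fret_intervals=fret_iv,
        noise_sd=sd,
    )
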