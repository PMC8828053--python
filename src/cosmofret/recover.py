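"""Parameter-recovery experiments: simulate a cohort with the fitted
kinetic values as ground truth, run the full detection / classification /
fitting pipeline, and measure the recovered quantity.

These are the package's self-consistency benchmarks: each function
returns the recovered estimate with its uncertainty, computed only from
rendered (noisy) traces via the same code paths a user would run.

Conventions shared by all recoveries:

* Photobleaching is disabled: the measurands are pure kinetic quantities
  (the original analyses bleach-correct or control for bleaching), and
  the 5RA composite-loss process is modelled in the kinetics directly.
* A detected FRET interval counts as right-censored only when it reaches
  the record end.  An interval ending because the donor departs together
  with the complex (e.g. ORC leaving as the second OM interaction ends)
  is an observed termination, not censoring.
* Exponential MLE fits carry a left-truncation cutoff of
  (min_frames - 0.5) acquisition cycles.  The constant follows from the
  exposure geometry alone (1-s exposures on the 2.4-s cycle, a frame
  counts as in-state above ~44% occupancy): for exponential dwells of any
  mean, E[measured duration | detected] - truncation = mean at this
  cutoff, verified numerically from the abstract quantisation model.
* Attempts starting too close to the record end to be classifiable are
  excluded from event-fraction denominators (eligibility margin 250 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .events import EventRecord
from .kinstats import (
    RateFit,
    fit_exponential_mle,
    grouped_median,
    proportion_with_se,
)
from .pipeline import RunConfig, cmd_analyze, cmd_simulate

ELIGIBILITY_MARGIN_S = 250.0


def _run(preset: str, seed: int, n_dna: int, **overrides):
    cfg = RunConfig.from_preset(preset, n_dna=n_dna, seed=seed,
                                bleaching=False, **overrides)
    ts = cmd_simulate(cfg)
    analyses, events = cmd_analyze(ts, cfg)
    return cfg, ts, analyses, events


def _censor_at_record_end(iv, record_end: float, cycle: float) -> bool:
    return iv.t_end >= record_end - cycle


def _single_orc_dh(events) -> List[EventRecord]:
    """Successful events mediated by one visible ORC throughout — the
    subset the OM-duration and FRET-window statistics are defined on
    (a second co-resident donor blends the FRET signal)."""
    return [e for e in events if e.success and e.orc_count_class == "1"]


def om_dwell_recovery(seed: int, n_dna: int = 2000) -> Dict[str, RateFit]:
    """First- and second-OM dwell means recovered from the baseline
    OM-reporter simulation (detection + censored-exponential MLE), over
    single-ORC double-hexamer events."""
    cfg, _, analyses, events = _run("fig1", seed, n_dna)
    T = cfg.timing.duration_s
    cyc = cfg.timing.cycle_s
    min_dur = (cfg.analysis.fret_min_frames - 0.5) * cyc
    dh = _single_orc_dh(events)
    out: Dict[str, RateFit] = {}
    for name, pick in (("first_om", lambda e: e.om1),
                       ("second_om", lambda e: e.om2)):
        durs, cens = [], []
        for e in dh:
            iv = pick(e)
            if iv is None:
                continue
            durs.append(iv.duration)
            cens.append(_censor_at_record_end(iv, T, cyc))
        out[name] = fit_exponential_mle(durs, cens, bootstrap_B=300,
                                        rng_seed=seed, min_duration=min_dur)
    return out


def efret_window_recovery(seed: int, n_dna: int = 400,
                          window_s: float = 10.0) -> Tuple[float, float, int]:
    """Mean apparent FRET in the 10-s window after each first Mcm2-7
    arrival of a double-hexamer event.

    Window frames must lie inside the detected first OM interval and be
    interior (the camera integrates over transitions, so boundary frames
    mix states and are excluded from state-mean estimation).  Per-frame E
    values outside +-2 are excluded; each event's window E is the
    intensity-weighted (ratio-of-sums) estimate, which suppresses the
    small-denominator bias of per-frame ratios, and the grand mean is the
    average over events.  Returns (grand mean, SEM over events, n events).
    """
    cfg, ts, analyses, events = _run("fig1", seed, n_dna)
    cyc = cfg.timing.cycle_s
    by_dna: Dict[int, list] = {}
    for e in _single_orc_dh(events):
        if e.om1 is not None:
            by_dna.setdefault(e.dna_id, []).append(e)
    trace_by_id = {tr.dna_id: tr for tr in ts}
    vals: List[float] = []
    for an in analyses:
        for e in by_dna.get(an.dna_id, []):
            ef = an.efret
            tr = trace_by_id[an.dna_id]
            m1 = e.t_m1
            sel = (
                (ef.time_s > m1)
                & (ef.time_s <= m1 + window_s)
                & (ef.time_s >= e.om1.t_start)
                & (ef.time_s + cyc <= e.om1.t_end)
                & ef.valid
                & (ef.efret >= -2.0)
                & (ef.efret <= 2.0)
            )
            if sel.sum() == 0:
                continue
            aem = tr.I_Dex_Aem[sel].sum()
            total = aem + tr.I_Dex_Dem[sel].sum()
            if total > 0:
                vals.append(aem / total)
    arr = np.asarray(vals)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), sem, len(arr)


def mo_experiment_recovery(seed: int, n_dna: int = 1500) -> Dict:
    """MO-reporter cohort: MO-end lag after second Mcm2-7 arrival and the
    first-Mcm -> stable-second conversion fraction."""
    cfg, _, analyses, events = _run("fig5-MO", seed, n_dna)
    T = cfg.timing.duration_s
    cyc = cfg.timing.cycle_s
    lags = []
    for e in _single_orc_dh(events):
        if (e.mo is not None and e.t_m2 is not None
                and not _censor_at_record_end(e.mo, T, cyc)):
            lags.append(e.mo.t_end - e.t_m2)
    lags = np.asarray(lags)
    eligible = [e for e in events
                if e.t_m1 is not None and e.t_m1 <= T - ELIGIBILITY_MARGIN_S]
    k = sum(1 for e in eligible if e.success)
    p, se = proportion_with_se(k, len(eligible)) if eligible else (0.0, 0.0)
    return {
        "mo_end_lag_mean_s": float(lags.mean()) if len(lags) else np.nan,
        "mo_end_lag_se_s": float(lags.std(ddof=1) / np.sqrt(len(lags)))
        if len(lags) > 1 else 0.0,
        "n_lags": int(len(lags)),
        "conversion_fraction": p,
        "conversion_se": se,
        "k_success": int(k),
        "n_first_mcm": len(eligible),
    }


def cdt1_mo_lag_recovery(seed: int, n_dna: int = 2000) -> Tuple[float, float, int]:
    """Mean lag from first Cdt1 release (half-loss step) to MO-FRET onset,
    on the Cdt1-acceptor-labeled MO-reporter design."""
    cfg, _, analyses, events = _run("fig6-cdt1C", seed, n_dna)
    lags = []
    for e in _single_orc_dh(events):
        if e.mo is not None and e.cdt1_release_times:
            rel1 = e.cdt1_release_times[0]
            if e.t_m2 is not None and rel1 < e.t_m2:
                lags.append(e.mo.t_start - rel1)
    lags = np.asarray(lags)
    se = float(lags.std(ddof=1) / np.sqrt(len(lags))) if len(lags) > 1 else 0.0
    return float(lags.mean()), se, int(len(lags))


def five_ra_om_recovery(seed: int, n_dna: int = 450) -> RateFit:
    """Observed OM-FRET duration of the Cdt1-release-defective 5RA mutant,
    terminated only by the composite fluorophore/protein loss process."""
    cfg, _, analyses, events = _run("fig4-5RA", seed, n_dna)
    T = cfg.timing.duration_s
    cyc = cfg.timing.cycle_s
    min_dur = (cfg.analysis.fret_min_frames - 0.5) * cyc
    durs, cens = [], []
    for e in events:
        if e.om1 is not None:
            durs.append(e.om1.duration)
            cens.append(_censor_at_record_end(e.om1, T, cyc))
    return fit_exponential_mle(durs, cens, bootstrap_B=500, rng_seed=seed,
                               min_duration=min_dur)


def lone_mcm_median_recovery(seed: int, n_dna: int = 350) -> Tuple[float, float, int]:
    """Median DNA lifetime of the first Mcm2-7 after ORC departure when no
    MO interaction forms (MO branch suppressed).

    Lifetimes are measured as (acceptor presence end) - (donor presence
    end) for each attempt, both from hysteresis presence detection.
    """
    from .presets import get_preset

    kin, _ = get_preset("fig1")
    kin.p_mo_given_first_mcm = 0.0
    cfg, _, analyses, events = _run("fig1", seed, n_dna, kinetics=kin)
    T = cfg.timing.duration_s
    cyc = cfg.timing.cycle_s
    an_by_id = {a.dna_id: a for a in analyses}
    lifetimes = []
    for e in events:
        if e.t_m1 is None or len(e.associations) != 1:
            continue
        an = an_by_id[e.dna_id]
        donor_iv = next((iv for iv in an.donor_intervals
                         if iv.t_start <= e.t_m1 < iv.t_end), None)
        acc_iv = next((iv for iv in an.acceptor_intervals
                       if iv.t_start - cyc <= e.t_m1 < iv.t_end), None)
        if donor_iv is None or acc_iv is None:
            continue
        if donor_iv.right_censored or acc_iv.right_censored:
            continue
        # keep small negative lags: they are quantisation noise around a
        # true lag near zero, and dropping them would bias the median up
        lifetimes.append(acc_iv.t_end - donor_iv.t_end)
    med, se = grouped_median(lifetimes, bin_width=cyc, B=500, rng_seed=seed)
    return med, se, len(lifetimes)
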