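"""Measurement layer: background, presence, steps, E series, intervals."""

import numpy as np
import pytest

from cosmofret.analysis import (
    EfretSeries,
    analyze_trace,
    compute_efret,
    correct_background,
    detect_fret_intervals,
    detect_presence,
    detect_steps,
    robust_noise_sd,
)
from cosmofret.params import AnalysisParams, ConfigurationError
from cosmofret.traces import Trace

CYC = 2.4


def _times(n):
    return np.arange(n) * CYC


def test_background_correction_removes_offset(rng):
    y = rng.normal(100.0, 10.0, 600)
    corrected, baseline, fallback = correct_background(y)
    assert abs(corrected.mean()) < 2.0
    assert abs(baseline - 100.0) < 2.0
    assert not fallback


def test_background_correction_preserves_step_magnitudes(rng):
    y = rng.normal(0.0, 10.0, 400)
    y[100:200] += 500.0
    c0, _, _ = correct_background(y)
    c1, _, _ = correct_background(y + 250.0)
    s0 = detect_steps(c0, _times(400), sigma=10.0)
    s1 = detect_steps(c1, _times(400), sigma=10.0)
    assert len(s0) == len(s1) == 2
    for a, b in zip(s0, s1):
        assert abs(a.magnitude - b.magnitude) < 3.0
        assert a.time_s == b.time_s


def test_presence_detects_dwell_with_frame_accuracy(rng):
    n = 600
    y = rng.normal(0.0, 150.0, n)
    t = _times(n)
    on = (t >= 300.0) & (t < 400.8)
    y[on] += 1000.0
    ivs = detect_presence(y, t, sigma=150.0)
    assert len(ivs) == 1
    assert abs(ivs[0].t_start - 300.0) <= CYC
    assert abs(ivs[0].t_end - 400.8) <= CYC
    assert not ivs[0].right_censored


def test_presence_noise_only_false_positive_rate(rng):
    hits = 0
    for _ in range(50):
        y = rng.normal(0.0, 150.0, 600)
        hits += len(detect_presence(y, _times(600), sigma=150.0))
    assert hits <= 5  # well under 1 per 600-frame record


def test_presence_censored_at_record_end(rng):
    y = rng.normal(0.0, 100.0, 200)
    y[150:] += 1000.0
    ivs = detect_presence(y, _times(200), sigma=100.0)
    assert len(ivs) == 1 and ivs[0].right_censored


def test_presence_rejects_bad_thresholds():
    with pytest.raises(ConfigurationError):
        detect_presence(np.zeros(10), _times(10), on_threshold_sd=-1.0)


def test_steps_staircase_two_arrivals(rng):
    n = 300
    y = rng.normal(0.0, 100.0, n)
    t = _times(n)
    y[(t >= 120.0)] += 1000.0
    y[(t >= 360.0)] += 1000.0
    steps = detect_steps(y, t, sigma=100.0, unit=1000.0)
    ups = [s for s in steps if s.direction == "up"]
    assert len(ups) == 2
    assert abs(ups[0].time_s - 120.0) <= CYC
    assert abs(ups[1].time_s - 360.0) <= CYC
    assert all(s.classification == "arrival" for s in ups)


def test_steps_half_loss_classification(rng):
    n = 400
    y = rng.normal(0.0, 100.0, n)
    t = _times(n)
    y[(t >= 120.0) & (t < 720.0)] += 2000.0   # Mcm/Cdt1 co-arrival
    y[(t >= 360.0) & (t < 720.0)] -= 1000.0   # Cdt1 release
    steps = detect_steps(y, t, sigma=100.0, unit=1000.0)
    kinds = [s.classification for s in steps]
    assert kinds == ["arrival", "half_loss", "departure"]
    assert abs(steps[1].time_s - 360.0) <= CYC


def test_steps_flat_occupied_trace_has_single_arrival(rng):
    y = rng.normal(1000.0, 100.0, 300)
    steps = detect_steps(y, _times(300), sigma=100.0)
    downs = [s for s in steps if s.direction == "down"]
    assert not downs


def test_steps_noise_only_trace_is_empty(rng):
    for _ in range(20):
        y = rng.normal(0.0, 100.0, 600)
        assert detect_steps(y, _times(600), sigma=100.0) == []


def test_efret_formula_and_mask():
    n = 10
    tr = Trace(0, _times(n), _times(n) + 1.2,
               I_Dex_Dem=np.full(n, 30.0),
               I_Dex_Aem=np.full(n, 70.0),
               I_Aex_Aem=np.full(n, 1000.0))
    from cosmofret.analysis import PresenceInterval

    donor = [PresenceInterval("donor", 0.0, 12.0)]
    acc = [PresenceInterval("acceptor", 0.0, 24.0)]
    ef = compute_efret(tr, donor, acc)
    assert np.allclose(ef.efret, 0.7)
    # valid only while the donor is present
    assert ef.valid[:5].all() and not ef.valid[5:].any()


def test_efret_zero_acceptor_emission():
    tr = Trace(0, _times(4), _times(4) + 1.2,
               I_Dex_Dem=np.full(4, 50.0),
               I_Dex_Aem=np.zeros(4),
               I_Aex_Aem=np.zeros(4))
    from cosmofret.analysis import PresenceInterval

    ef = compute_efret(tr, [PresenceInterval("d", 0.0, 100.0)],
                       [PresenceInterval("a", 0.0, 100.0)])
    assert np.allclose(ef.efret, 0.0)


def test_efret_histogram_excludes_extreme_values():
    e = np.array([0.5, 2.5, -3.0, 1.9, -1.9])
    ef = EfretSeries(_times(5), e, np.ones(5, dtype=bool))
    vals = ef.histogram_values()
    assert sorted(vals) == [-1.9, 0.5, 1.9]


def test_fret_interval_recovery_at_noise(rng):
    """A 30-s OM window at E=0.72 with sigma_E ~ 0.1 is recovered as one
    interval with endpoints within one acquisition cycle."""
    n = 250
    t = _times(n)
    e = rng.normal(0.08, 0.12, n)
    win = (t >= 120.0) & (t < 150.0)
    e[win] = rng.normal(0.72, 0.1, win.sum())
    ef = EfretSeries(t, e, np.ones(n, dtype=bool))
    ivs = detect_fret_intervals(ef, 0.4, confirm_arrival_s=None)
    assert len(ivs) == 1
    assert abs(ivs[0].t_start - 120.0) <= CYC
    assert abs(ivs[0].t_end - 150.0) <= CYC


def test_fret_interval_none_on_baseline(rng):
    for _ in range(20):
        e = rng.normal(0.08, 0.1, 600)
        ef = EfretSeries(_times(600), e, np.ones(600, dtype=bool))
        assert detect_fret_intervals(ef, 0.4, confirm_arrival_s=None) == []


def test_fret_onset_requires_confirmed_acceptor_arrival(rng):
    n = 250
    t = _times(n)
    e = rng.normal(0.08, 0.1, n)
    e[(t >= 120.0) & (t < 150.0)] = 0.72
    ef = EfretSeries(t, e, np.ones(n, dtype=bool))
    near = detect_fret_intervals(ef, 0.4, confirm_arrival_s=4.8,
                                 acceptor_arrivals=[121.2])
    far = detect_fret_intervals(ef, 0.4, confirm_arrival_s=4.8,
                                acceptor_arrivals=[400.0])
    assert len(near) == 1 and far == []


def test_fret_threshold_validated():
    ef = EfretSeries(_times(5), np.zeros(5), np.ones(5, dtype=bool))
    with pytest.raises(ConfigurationError):
        detect_fret_intervals(ef, 1.5)


def test_detection_fidelity_on_simulated_cohort(fig1_small):
    """>= 95% of ground-truth first-OM intervals lasting >= 3 frames are
    recovered with both endpoints within one frame, over single-ORC
    events with a labeled donor and acceptor."""
    cfg, ts, analyses, events = fig1_small
    an_by = {a.dna_id: a for a in analyses}
    total = hit = 0
    for traj in ts.trajectories:
        for a in traj.attempts:
            if a.om1 is None or a.branch == "5ra_loss":
                continue
            if a.om1[1] - a.om1[0] < 3 * CYC or a.om1[1] > traj.duration_s:
                continue
            orc = traj.molecule(a.orc_ids[0])
            mcm = traj.molecule(a.mcm1_id)
            if orc.label != "donor_c" or mcm.label != "acceptor_c":
                continue
            if len([m for m in traj.molecules if m.species == "orc"
                    and m.t_on < a.om1[1] and m.t_off > a.om1[0]]) > 1:
                continue
            total += 1
            for iv in an_by[traj.dna_id].fret_intervals:
                if abs(iv.t_start - a.om1[0]) <= CYC \
                        and abs(iv.t_end - a.om1[1]) <= CYC:
                    hit += 1
                    break
    assert total > 50
    assert hit / total >= 0.95


def test_robust_noise_sd_estimates_sigma(rng):
    y = rng.normal(0.0, 150.0, 2000)
    y[500:1500] += 1000.0  # a step should not inflate the estimate
    assert abs(robust_noise_sd(y) - 150.0) < 15.0
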