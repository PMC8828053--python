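"""Trace rendering: FRET splitting, PIFE, conservation, photobleaching."""

import numpy as np
import pytest

from cosmofret.kinetics import Interaction, Molecule, StateTrajectory
from cosmofret.params import (
    ACCEPTOR_C,
    ACCEPTOR_N,
    DONOR_C,
    ExperimentDesign,
    FrameTiming,
    PhotophysicsParams,
)
from cosmofret.traces import TraceSet, apply_photobleaching, render_traces


def _dh_trajectory(T=240.0, om1=(24.0, 72.0), cdt1_label=None):
    """Hand-built trajectory: ORC from t=12, Mcm1+Cdt1 at 24, OM over om1,
    Cdt1 release at om1 end."""
    traj = StateTrajectory(dna_id=0, duration_s=T)
    traj.molecules = [
        Molecule("orc-0-0", "orc", 12.0, T + 1, label=DONOR_C),
        Molecule("mcm-0-0", "mcm", om1[0], T + 1, label=ACCEPTOR_C),
        Molecule("cdt1-0-0", "cdt1", om1[0], om1[1], label=cdt1_label),
    ]
    traj.interactions = [
        Interaction("om", 1, om1[0], om1[1], "orc-0-0", "mcm-0-0")]
    return traj


def _design(**kw):
    base = dict(n_dna=1, duration_cycles=100,
                orc_label_plan={DONOR_C: 1.0},
                mcm_label_plan={ACCEPTOR_C: 1.0})
    base.update(kw)
    return ExperimentDesign(**base)


def test_noiseless_om_frames_hit_the_setpoint_exactly():
    """Frames fully inside the first OM interaction split emission as
    I_Aem = 0.72 T, so E = 0.72 exactly."""
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams()
    ts = render_traces([_dh_trajectory()], timing, phys, _design(),
                       noiseless=True)
    tr = ts.traces[0]
    inside = (tr.donor_t >= 26.4) & (tr.donor_t + 2.4 <= 72.0)
    e = tr.I_Dex_Aem[inside] / (tr.I_Dex_Aem[inside] + tr.I_Dex_Dem[inside])
    assert np.allclose(e, 0.72)
    # PIFE boosts donor-excited total during OM
    total = tr.I_Dex_Aem[inside] + tr.I_Dex_Dem[inside]
    assert np.allclose(total, 1.3 * phys.unit_intensity)


def test_conservation_total_emission_independent_of_fret():
    """Noiseless I_Dex_Dem + I_Dex_Aem does not depend on the E set-point
    for a fixed PIFE state."""
    timing = FrameTiming(n_cycles=100)
    totals = []
    for e_om in (0.3, 0.72, 0.9):
        phys = PhotophysicsParams(efret_om_first=e_om)
        ts = render_traces([_dh_trajectory()], timing, phys, _design(),
                           noiseless=True)
        tr = ts.traces[0]
        totals.append(tr.I_Dex_Dem + tr.I_Dex_Aem)
    assert np.allclose(totals[0], totals[1])
    assert np.allclose(totals[1], totals[2])


def test_acceptor_excited_channel_invariant_to_fret_state():
    timing = FrameTiming(n_cycles=100)
    accs = []
    for e_om in (0.3, 0.9):
        phys = PhotophysicsParams(efret_om_first=e_om)
        ts = render_traces([_dh_trajectory()], timing, phys, _design(),
                           noiseless=True)
        accs.append(ts.traces[0].I_Aex_Aem)
    assert np.allclose(accs[0], accs[1])


def test_unlabeled_trajectory_renders_pure_noise(rng):
    traj = StateTrajectory(dna_id=0, duration_s=240.0)
    traj.molecules = [Molecule("orc-0-0", "orc", 10.0, 200.0, label="unlabeled")]
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams()
    ts = render_traces([traj], timing, phys, _design(), rng_seed=1)
    tr = ts.traces[0]
    for ch in (tr.I_Dex_Dem, tr.I_Dex_Aem, tr.I_Aex_Aem):
        assert abs(ch.mean()) < 4 * phys.background_sd / np.sqrt(len(ch))


def test_cdt1_release_halves_acceptor_excited_intensity():
    """Mcm2-7 and Cdt1 co-arrive with two acceptors; Cdt1 release drops
    I_Aex_Aem from ~2 to ~1 unit."""
    traj = _dh_trajectory(cdt1_label=ACCEPTOR_N)
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams()
    ts = render_traces([traj], timing, phys, _design(), noiseless=True)
    tr = ts.traces[0]
    before = (tr.acceptor_t >= 26.4) & (tr.acceptor_t + 2.4 <= 72.0)
    after = (tr.acceptor_t >= 74.4) & (tr.acceptor_t + 2.4 <= 200.0)
    assert np.allclose(tr.I_Aex_Aem[before], 2 * phys.unit_intensity)
    assert np.allclose(tr.I_Aex_Aem[after], 1 * phys.unit_intensity)
    # and the composite OM set-point applies while labeled Cdt1 is bound
    inside = (tr.donor_t >= 26.4) & (tr.donor_t + 2.4 <= 72.0)
    e = tr.I_Dex_Aem[inside] / (tr.I_Dex_Aem[inside] + tr.I_Dex_Dem[inside])
    assert np.allclose(e, phys.efret_om_with_cdt1N)


def test_zero_bleach_probability_is_identity():
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams(bleach_prob_per_exposure=0.0)
    ts = render_traces([_dh_trajectory()], timing, phys, _design(), rng_seed=4)
    out = apply_photobleaching(ts, phys, rng_seed=99)
    for a, b in zip(ts.traces, out.traces):
        assert np.array_equal(a.I_Dex_Dem, b.I_Dex_Dem)
        assert np.array_equal(a.I_Aex_Aem, b.I_Aex_Aem)


def test_bleach_hazard_scales_with_exposure_factor():
    """An immortal dye bleaches ~2.4x faster at 2.4x laser exposure."""
    timing = FrameTiming(n_cycles=600)
    p = 5e-3
    phys = PhotophysicsParams(bleach_prob_per_exposure=p, background_sd=0.0)
    rates = {}
    for factor in (1.0, 2.4):
        design = _design(n_dna=400, duration_cycles=600,
                         laser_exposure_factor=factor)
        trajs = []
        for i in range(400):
            traj = StateTrajectory(dna_id=i, duration_s=timing.duration_s)
            traj.molecules = [Molecule(f"orc-{i}-0", "orc", 0.0,
                                       timing.duration_s + 1, label=DONOR_C)]
            trajs.append(traj)
        ts = render_traces(trajs, timing, phys, design, noiseless=True)
        out = apply_photobleaching(ts, phys, rng_seed=7)
        ks = [t.trajectory.molecules[0].bleach_t for t in out.traces]
        exposures = np.array([np.inf if b is None else b / timing.cycle_s + 1
                              for b in ks])
        # geometric MLE for the per-exposure hazard with censoring at 600
        obs = np.minimum(exposures, 600)
        d = (exposures <= 600).sum()
        rates[factor] = d / obs.sum()
    ratio = rates[2.4] / rates[1.0]
    assert 2.0 < ratio < 2.9


def test_donor_bleach_leaves_acceptor_channel_alive():
    traj = _dh_trajectory()
    traj.molecules[0].bleach_t = 48.0  # donor dies mid-OM
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams()
    ts = render_traces([traj], timing, phys, _design(), noiseless=True)
    tr = ts.traces[0]
    after = (tr.donor_t >= 50.4) & (tr.donor_t + 2.4 <= 200.0)
    assert np.allclose(tr.I_Dex_Dem[after], 0.0)
    assert np.allclose(tr.I_Dex_Aem[after], 0.0)
    a_after = (tr.acceptor_t >= 50.4) & (tr.acceptor_t + 2.4 <= 200.0)
    assert np.all(tr.I_Aex_Aem[a_after] > 0)


def test_noisy_efret_converges_to_setpoint():
    timing = FrameTiming(n_cycles=100)
    phys = PhotophysicsParams(background_sd=30.0)
    trajs = [_dh_trajectory() for _ in range(40)]
    for i, t in enumerate(trajs):
        t.dna_id = i
    ts = render_traces(trajs, timing, phys, _design(n_dna=40), rng_seed=3)
    vals = []
    for tr in ts.traces:
        inside = (tr.donor_t >= 26.4) & (tr.donor_t + 2.4 <= 72.0)
        vals.extend(tr.I_Dex_Aem[inside]
                    / (tr.I_Dex_Aem[inside] + tr.I_Dex_Dem[inside]))
    vals = np.array(vals)
    assert abs(vals.mean() - 0.72) < 3 * vals.std() / np.sqrt(len(vals)) + 1e-3


def test_frame_table_and_csv_hdf5_round_trip(tmp_path):
    timing = FrameTiming(n_cycles=50)
    phys = PhotophysicsParams()
    traj = _dh_trajectory(T=120.0, om1=(24.0, 60.0))
    ts = render_traces([traj], timing, phys,
                       _design(duration_cycles=50), rng_seed=5)
    df = ts.frame_table()
    assert set(df.frame_kind) == {"donor_ex", "acceptor_ex"}
    assert (df.frame_kind.values[::2] == "donor_ex").all()
    ts.to_csv(tmp_path / "t.csv")
    back = TraceSet.from_csv(tmp_path / "t.csv")
    assert np.allclose(back.traces[0].I_Dex_Dem, ts.traces[0].I_Dex_Dem)
    ts.to_hdf5(tmp_path / "t.h5")
    back2 = TraceSet.from_hdf5(tmp_path / "t.h5")
    assert np.allclose(back2.traces[0].I_Aex_Aem, ts.traces[0].I_Aex_Aem)
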