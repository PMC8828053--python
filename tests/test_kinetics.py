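"""Kinetic simulator: branch statistics, mutants, mechanisms, labeling."""

import numpy as np
import pytest

from cosmofret.kinetics import (
    assign_labels,
    ground_truth_table,
    simulate_experiment,
    simulate_trajectory,
)
from cosmofret.params import (
    ACCEPTOR_C,
    ACCEPTOR_N,
    DONOR_C,
    UNLABELED,
    ConfigurationError,
    ExperimentDesign,
    KineticParams,
)


@pytest.mark.parametrize("bad", [
    {"p_mo_given_first_mcm": 1.5},
    {"mean_first_om_s": -3.0},
    {"mechanism": "teleport"},
    {"mutant": "unknown"},
    {"p_one_orc": 0.9, "p_two_orc_sequential": 0.2},
    {"p_second_given_mo": 0.8, "p_abortive_second": 0.5},
])
def test_invalid_params_rejected(bad):
    with pytest.raises(ConfigurationError):
        KineticParams(**bad)


def test_dn119_with_zero_override_has_no_mo_events():
    """A fully blocked MO branch yields trajectories without MO onsets."""
    params = KineticParams(mutant="orc6dN119", p_mo_dn119=0.0)
    design = ExperimentDesign(n_dna=100)
    trajs = simulate_experiment(params, design, rng_seed=3)
    events = ground_truth_table(trajs)
    assert not (events.event_kind == "mo_start").any()
    assert not (events.event_kind == "mcm2_arrive").any()


def test_mcm5ra_blocks_release_and_second_recruitment(wt_trajectories=None):
    params = KineticParams(mutant="mcm5RA")
    design = ExperimentDesign(n_dna=80)
    for traj in simulate_experiment(params, design, rng_seed=5):
        for a in traj.attempts:
            assert a.cdt1_release_1 is None
            assert a.mo_start is None
            assert a.t_m2 is None


def test_conversion_fraction_matches_branch_product():
    """With MO probability 0.23 and conditional recruitment 0.79, the
    fraction of first-Mcm2-7 events reaching a second arrival is ~0.18."""
    params = KineticParams()
    design = ExperimentDesign(n_dna=1500)
    trajs = simulate_experiment(params, design, rng_seed=11)
    attempts = [a for t in trajs for a in t.attempts
                if a.t_m1 <= t.duration_s - 300]
    n = len(attempts)
    assert n > 3000
    frac = sum(a.branch == "stable" for a in attempts) / n
    p = 0.23 * 0.79
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_exponential_dwell_sampler_is_calibrated():
    """Monte-Carlo mean of the first-OM dwell matches the configured mean
    within 3 tau / sqrt(n) (closed-form SE of an exponential mean)."""
    tau = 30.0
    params = KineticParams(mean_first_om_s=tau)
    design = ExperimentDesign(n_dna=1200)
    trajs = simulate_experiment(params, design, rng_seed=13)
    d = np.array([a.om1[1] - a.om1[0] for t in trajs for a in t.attempts
                  if a.om1 is not None and a.branch != "5ra_loss"])
    assert len(d) > 2000
    assert abs(d.mean() - tau) < 3 * tau / np.sqrt(len(d))


def test_event_times_sorted_and_om_end_equals_first_release(wt_trajectories):
    params, design, trajs = wt_trajectories
    for traj in trajs[:100]:
        times = [t for _, t, _, _ in traj.events()]
        assert all(t2 >= t1 for t1, t2 in zip(times, times[1:]))
        for a in traj.attempts:
            if a.cdt1_release_1 is not None:
                assert a.om1[1] == a.cdt1_release_1  # exact coincidence


def test_mo_strictly_brackets_second_arrival(wt_trajectories):
    params, design, trajs = wt_trajectories
    checked = 0
    for traj in trajs:
        for a in traj.attempts:
            if a.branch == "stable":
                assert a.mo_start < a.t_m2 < a.mo_end
                assert a.mo_start >= a.cdt1_release_1
                checked += 1
    assert checked > 20


def test_re_fret_attaches_both_om_to_first_mcm():
    params = KineticParams(mechanism="re_fret")
    design = ExperimentDesign(n_dna=300)
    trajs = simulate_experiment(params, design, rng_seed=21)
    n_second = 0
    for traj in trajs:
        mcm2_ids = {a.mcm2_id for a in traj.attempts if a.mcm2_id}
        for it in traj.interactions:
            if it.kind == "om":
                assert it.mcm_id not in mcm2_ids
            assert it.kind != "mo"
            n_second += it.order == 2
    assert n_second > 10


def test_orc_flip_has_one_om_per_mcm(wt_trajectories):
    params, design, trajs = wt_trajectories
    for traj in trajs:
        carriers = [it.mcm_id for it in traj.interactions if it.kind == "om"]
        assert len(carriers) == len(set(carriers))


def test_staged_prebound_orc_only_at_t0():
    params = KineticParams()
    design = ExperimentDesign(n_dna=150, staged_prebound=True)
    trajs = simulate_experiment(params, design, rng_seed=9)
    for traj in trajs:
        arrivals = [m.t_on for m in traj.molecules if m.species == "orc"]
        assert all(t == 0.0 for t in arrivals[:1])
        # no free-ORC rebinding after the prebound complex leaves
        assert len([t for t in arrivals if t > 0]) == 0


def test_labeling_probability_one_labels_everything(wt_trajectories):
    params, design, trajs = wt_trajectories
    traj = trajs[0]
    design_full = ExperimentDesign(
        n_dna=1, orc_label_plan={DONOR_C: 1.0},
        mcm_label_plan={ACCEPTOR_C: 1.0})
    assign_labels(design_full, traj, rng_seed=0)
    assert all(m.label != UNLABELED for m in traj.molecules
               if m.species in ("orc", "mcm"))


def test_two_label_fraction_of_orc_pairs():
    """With 0.88 labeling, both members of an ORC pair carry a dye in
    ~0.88^2 = 0.774 of pairs."""
    params = KineticParams(mechanism="two_orc_independent",
                           p_second_given_mo=0.95, p_abortive_second=0.0,
                           p_mo_given_first_mcm=0.9)
    design = ExperimentDesign(n_dna=1500)
    trajs = simulate_experiment(params, design, rng_seed=17)
    both = tot = 0
    for traj in trajs:
        for a in traj.attempts:
            if a.branch == "stable" and len(a.orc_ids) >= 2:
                labels = [traj.molecule(i).label for i in a.orc_ids[:2]]
                tot += 1
                both += all(l == DONOR_C for l in labels)
    assert tot > 400
    p = 0.88 ** 2
    assert abs(both / tot - p) < 3 * np.sqrt(p * (1 - p) / tot)


def test_equimolar_mcm_mixture_gives_quarter_dh_types():
    params = KineticParams()
    design = ExperimentDesign(
        n_dna=2500, mcm_label_plan={ACCEPTOR_C: 0.5, ACCEPTOR_N: 0.5})
    trajs = simulate_experiment(params, design, rng_seed=19)
    types = [a.dh_type(t) for t in trajs for a in t.attempts if a.success]
    counts = {k: types.count(k) for k in ("CC", "CN", "NC", "NN")}
    n = sum(counts.values())
    assert n > 300
    for k, c in counts.items():
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(c / n - 0.25) < 4 * se, (k, counts)


def test_ground_truth_table_schema(wt_trajectories):
    params, design, trajs = wt_trajectories
    df = ground_truth_table(trajs[:20])
    assert list(df.columns) == ["dna_id", "event_kind", "time_s",
                                "molecule_id", "label_class"]
    assert df.time_s.min() >= 0


def test_single_trajectory_seed_reproducible():
    params = KineticParams()
    design = ExperimentDesign(n_dna=1)
    t1 = simulate_trajectory(params, design, 123, dna_id=0)
    t2 = simulate_trajectory(params, design, 123, dna_id=0)
    assert [(k, t) for k, t, _, _ in t1.events()] \
        == [(k, t) for k, t, _, _ in t2.events()]
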