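"""Stochastic simulation of helicase-loading state trajectories.

Each DNA molecule is simulated independently in continuous time.  A
trajectory is a sequence of loading *attempts*: ORC arrives, recruits a
first Cdt1-bound Mcm2-7 (OM interaction), and the attempt then branches
into MO formation (followed by stable second recruitment, an abortive
short second association, or release of the first Mcm2-7) or into the
no-MO failure path in which ORC departs and the lone first Mcm2-7 is
released shortly after.  A successful attempt ends in a stable Mcm2-7
double hexamer that occupies the DNA for the rest of the record.

Ground truth (exact continuous event times, molecule identities, label
classes) is kept alongside so that detection layers can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    ACCEPTOR_C,
    ACCEPTOR_N,
    DONOR_C,
    DONOR_N,
    UNLABELED,
    ConfigurationError,
    ExperimentDesign,
    FrameTiming,
    KineticParams,
)

EVENT_KINDS = (
    "orc_arrive", "orc_depart", "mcm1_arrive", "mcm2_arrive", "mcm_depart",
    "cdt1_release", "om_start", "om_end", "mo_start", "mo_end", "dh_form",
)

# deterministic tie-break order for coincident events
_KIND_ORDER = {k: i for i, k in enumerate(EVENT_KINDS)}


@dataclass
class Molecule:
    """One protein molecule visiting a DNA. t_off may exceed the record end
    (the renderer truncates and flags censoring); bleach_t is set by the
    photobleaching stage."""

    mol_id: str
    species: str            # "orc" | "mcm" | "cdt1"
    t_on: float
    t_off: float
    label: Optional[str] = None
    bleach_t: Optional[float] = None

    def present(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


@dataclass
class Interaction:
    """An OM or MO interaction interval, with the molecules that mediate it."""

    kind: str               # "om" | "mo"
    order: int              # 1 or 2 for OM; 0 for MO
    t_start: float
    t_end: float
    orc_id: str
    mcm_id: str

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class Attempt:
    """Ground-truth record of one loading attempt."""

    t_m1: float
    mcm1_id: str
    cdt1_release_1: Optional[float] = None
    t_m2: Optional[float] = None
    mcm2_id: Optional[str] = None
    cdt1_release_2: Optional[float] = None
    mo_start: Optional[float] = None
    mo_end: Optional[float] = None
    om1: Optional[tuple] = None
    om2: Optional[tuple] = None
    success: bool = False
    branch: str = ""        # "stable" | "abortive" | "mo_release" | "no_mo" | "5ra_loss"
    orc_usage: str = "one"  # "one" | "two_sequential" | "two_overlap" | "extra"
    orc_ids: List[str] = field(default_factory=list)

    def dh_type(self, trajectory: "StateTrajectory") -> Optional[str]:
        """Ground-truth double-hexamer label type, e.g. "CN" (first Mcm2-7
        C-terminally acceptor-labeled, second N-terminally)."""
        if not self.success:
            return None
        letters = []
        for mid in (self.mcm1_id, self.mcm2_id):
            mol = trajectory.molecule(mid)
            if mol.label == ACCEPTOR_C:
                letters.append("C")
            elif mol.label == ACCEPTOR_N:
                letters.append("N")
            else:
                letters.append("U")
        return "".join(letters)


@dataclass
class StateTrajectory:
    """Timed molecular events on one DNA, plus ground-truth bookkeeping."""

    dna_id: int
    duration_s: float
    molecules: List[Molecule] = field(default_factory=list)
    interactions: List[Interaction] = field(default_factory=list)
    attempts: List[Attempt] = field(default_factory=list)

    def molecule(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.mol_id == mol_id:
                return m
        raise KeyError(mol_id)

    def events(self) -> List[tuple]:
        """Sorted (event_kind, time_s, molecule_id, label_class) tuples.
        Coincident events (e.g. om_end / cdt1_release) keep equal times and
        are ordered deterministically by kind."""
        out = []
        for m in self.molecules:
            if m.species == "orc":
                out.append(("orc_arrive", m.t_on, m.mol_id, m.label))
                if m.t_off <= self.duration_s:
                    out.append(("orc_depart", m.t_off, m.mol_id, m.label))
            elif m.species == "mcm":
                if m.t_off <= self.duration_s:
                    out.append(("mcm_depart", m.t_off, m.mol_id, m.label))
            elif m.species == "cdt1":
                if m.t_off <= self.duration_s:
                    out.append(("cdt1_release", m.t_off, m.mol_id, m.label))
        for a in self.attempts:
            m1 = self.molecule(a.mcm1_id)
            out.append(("mcm1_arrive", a.t_m1, a.mcm1_id, m1.label))
            if a.t_m2 is not None:
                m2 = self.molecule(a.mcm2_id)
                out.append(("mcm2_arrive", a.t_m2, a.mcm2_id, m2.label))
            if a.mo_start is not None:
                out.append(("mo_start", a.mo_start, a.orc_ids[-1], None))
                if a.mo_end is not None and a.mo_end <= self.duration_s:
                    out.append(("mo_end", a.mo_end, a.orc_ids[-1], None))
                    if a.success:
                        out.append(("dh_form", a.mo_end, a.mcm2_id, None))
        for it in self.interactions:
            if it.kind == "om":
                out.append(("om_start", it.t_start, it.mcm_id, None))
                if it.t_end <= self.duration_s:
                    out.append(("om_end", it.t_end, it.mcm_id, None))
        out = [e for e in out if e[1] <= self.duration_s]
        out.sort(key=lambda e: (e[1], _KIND_ORDER[e[0]]))
        return out


def _trunc_exp(rng: np.random.Generator, mean: float, upper: float) -> float:
    """Exponential(mean) conditioned below `upper` (inverse-CDF sampling)."""
    u = rng.random()
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def _choose_usage(params: KineticParams, rng: np.random.Generator) -> str:
    if params.mechanism in ("orc_exchange", "two_orc_independent"):
        return "two_sequential"
    u = rng.random()
    if u < params.p_one_orc:
        return "one"
    if u < params.p_one_orc + params.p_two_orc_sequential:
        return "two_sequential"
    if u < params.p_one_orc + params.p_two_orc_sequential + params.p_two_orc_overlap:
        return "two_overlap"
    return "extra"


def simulate_trajectory(
    params: KineticParams,
    design: ExperimentDesign,
    rng_seed,
    dna_id: int = 0,
    duration_s: Optional[float] = None,
) -> StateTrajectory:
    """Simulate one DNA's loading trajectory.

    `rng_seed` may be an int or a numpy Generator.  Returns a
    StateTrajectory whose ground truth contains every state change at
    exact continuous times.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if duration_s is None:
        duration_s = design.duration_cycles * FrameTiming().cycle_s
    T = duration_s
    traj = StateTrajectory(dna_id=dna_id, duration_s=T)
    t = 0.0
    orc_n = 0
    mcm_n = 0
    cdt_n = 0

    def new_orc(t_on: float) -> Molecule:
        nonlocal orc_n
        m = Molecule(f"orc-{dna_id}-{orc_n}", "orc", t_on, T)
        orc_n += 1
        traj.molecules.append(m)
        return m

    def new_mcm(t_on: float) -> Molecule:
        nonlocal mcm_n
        m = Molecule(f"mcm-{dna_id}-{mcm_n}", "mcm", t_on, T)
        mcm_n += 1
        traj.molecules.append(m)
        return m

    def new_cdt1(t_on: float) -> Molecule:
        nonlocal cdt_n
        m = Molecule(f"cdt1-{dna_id}-{cdt_n}", "cdt1", t_on, T)
        cdt_n += 1
        traj.molecules.append(m)
        return m

    while t < T:
        # --- ORC arrival ---
        if design.staged_prebound:
            if orc_n > 0:
                break  # free ORC withheld: no rebinding after the prebound one
            t_orc = 0.0
        else:
            t_orc = t + rng.exponential(1.0 / params.orc_arrival_rate)
        if t_orc >= T:
            break
        orc1 = new_orc(t_orc)

        # --- first Mcm2-7/Cdt1 arrival; OM interaction begins ---
        t_m1 = t_orc + rng.exponential(1.0 / params.mcm_arrival_rate)
        if t_m1 >= T:
            break  # ORC remains bound at record end (censored)
        mcm1 = new_mcm(t_m1)
        cdt1_1 = new_cdt1(t_m1)
        attempt = Attempt(t_m1=t_m1, mcm1_id=mcm1.mol_id, orc_ids=[orc1.mol_id])
        traj.attempts.append(attempt)

        if params.mutant == "mcm5RA":
            # Cdt1-release rate is zero: OM persists until the composite
            # fluorophore/protein loss process removes everything.
            loss = t_m1 + rng.exponential(params.mean_5ra_loss_s)
            traj.interactions.append(
                Interaction("om", 1, t_m1, loss, orc1.mol_id, mcm1.mol_id))
            attempt.om1 = (t_m1, loss)
            attempt.branch = "5ra_loss"
            orc1.t_off = mcm1.t_off = cdt1_1.t_off = loss
            t = loss
            continue

        # first OM interaction ends exactly at first Cdt1 release
        rel1 = t_m1 + rng.exponential(params.mean_first_om_s)
        traj.interactions.append(
            Interaction("om", 1, t_m1, rel1, orc1.mol_id, mcm1.mol_id))
        attempt.om1 = (t_m1, rel1)
        attempt.cdt1_release_1 = rel1
        cdt1_1.t_off = rel1

        if rng.random() >= params.p_mo_effective:
            # --- no MO: ORC departs, lone Mcm2-7 released soon after ---
            attempt.branch = "no_mo"
            orc_off = rel1 + rng.exponential(params.mean_orc_depart_no_mo_s)
            mcm_off = orc_off + rng.exponential(1.0 / params.m1_release_rate)
            orc1.t_off = orc_off
            mcm1.t_off = mcm_off
            t = max(orc_off, mcm_off)
            continue

        # --- MO pathway ---
        mo_start = rel1 + rng.exponential(params.mean_mo_delay_s)
        # with free ORC withheld no additional ORC can join the DNA
        usage = "one" if design.staged_prebound else _choose_usage(params, rng)
        attempt.orc_usage = usage
        mo_orc = orc1
        if params.mechanism == "orc_exchange" and not design.staged_prebound:
            # rapid coordinated hand-off: apparent single continuous ORC
            handoff = 0.5 * (rel1 + mo_start)
            orc1.t_off = handoff
            mo_orc = new_orc(handoff)
            attempt.orc_ids.append(mo_orc.mol_id)
        elif usage == "two_sequential":
            orc1.t_off = rel1 + rng.exponential(params.mean_two_orc_handoff_s)
            mo_orc = new_orc(mo_start)
            attempt.orc_ids.append(mo_orc.mol_id)

        u = rng.random()
        if u < params.p_second_given_mo:
            branch = "stable"
        elif u < params.p_second_given_mo + params.p_abortive_second:
            branch = "abortive"
        else:
            branch = "mo_release"
        attempt.branch = branch

        if branch == "mo_release":
            mo_end = mo_start + rng.exponential(params.mean_mo_abort_s)
            attempt.mo_start, attempt.mo_end = mo_start, mo_end
            if params.mechanism != "re_fret":
                traj.interactions.append(
                    Interaction("mo", 0, mo_start, mo_end,
                                mo_orc.mol_id, mcm1.mol_id))
            mcm1.t_off = mo_end
            mo_orc.t_off = mo_end + rng.exponential(params.mean_orc_depart_no_mo_s)
            t = max(mcm1.t_off, mo_orc.t_off)
            continue

        # second Mcm2-7/Cdt1 arrival (never precedes MO onset)
        t_m2 = mo_start + rng.exponential(1.0 / params.mcm_arrival_rate)
        if t_m2 >= T:
            # MO formed but record ends before second recruitment
            attempt.mo_start = mo_start
            attempt.branch = "mo_censored"
            if params.mechanism != "re_fret":
                traj.interactions.append(
                    Interaction("mo", 0, mo_start, T + 1.0,
                                mo_orc.mol_id, mcm1.mol_id))
            break
        mcm2 = new_mcm(t_m2)
        cdt1_2 = new_cdt1(t_m2)
        attempt.t_m2, attempt.mcm2_id = t_m2, mcm2.mol_id
        om2_carrier = mcm1 if params.mechanism == "re_fret" else mcm2
        mo_end = t_m2 + rng.exponential(params.mean_mo_end_after_m2_s)
        attempt.mo_start, attempt.mo_end = mo_start, mo_end
        if params.mechanism != "re_fret":
            traj.interactions.append(
                Interaction("mo", 0, mo_start, mo_end,
                            mo_orc.mol_id, mcm1.mol_id))

        if usage == "two_overlap":
            # an additional ORC joins between the two recruitments, uninvolved
            extra_on = t_m1 + rng.random() * max(t_m2 - t_m1, 1e-9)
            extra = new_orc(extra_on)
            extra.t_off = extra_on + rng.exponential(100.0)
            attempt.orc_ids.append(extra.mol_id)
        elif usage == "extra":
            # nonspecific short ORC visits (the "three ORC" class)
            for _ in range(2):
                extra_on = t_m1 + rng.random() * max(t_m2 - t_m1, 1e-9)
                extra = new_orc(extra_on)
                extra.t_off = extra_on + rng.exponential(
                    params.mean_nonspecific_orc_dwell_s)
                attempt.orc_ids.append(extra.mol_id)

        if branch == "abortive":
            dwell = _trunc_exp(rng, params.mean_abortive_dwell_s, 48.0)
            m2_off = t_m2 + dwell
            traj.interactions.append(
                Interaction("om", 2, t_m2, m2_off,
                            mo_orc.mol_id, om2_carrier.mol_id))
            attempt.om2 = (t_m2, m2_off)
            attempt.cdt1_release_2 = m2_off
            cdt1_2.t_off = m2_off
            mcm2.t_off = m2_off
            mo_orc.t_off = (max(mo_end, m2_off)
                            + rng.exponential(params.mean_orc_depart_no_mo_s))
            mcm1.t_off = mo_orc.t_off + rng.exponential(1.0 / params.m1_release_rate)
            t = max(mo_orc.t_off, mcm1.t_off)
            continue

        # --- stable second recruitment: double hexamer ---
        rel2 = t_m2 + rng.exponential(params.mean_second_om_s)
        traj.interactions.append(
            Interaction("om", 2, t_m2, rel2, mo_orc.mol_id, om2_carrier.mol_id))
        attempt.om2 = (t_m2, rel2)
        attempt.cdt1_release_2 = rel2
        cdt1_2.t_off = rel2
        # ORC departs with loss of the second OM, but never while its MO
        # interaction with the first Mcm2-7 still persists
        mo_orc.t_off = max(rel2, mo_end)
        # both helicases retained: double hexamer occupies the DNA to the end
        mcm1.t_off = T + 1.0
        mcm2.t_off = T + 1.0
        attempt.success = True
        break

    return traj


def simulate_experiment(
    params: KineticParams,
    design: ExperimentDesign,
    rng_seed: int,
    timing: Optional[FrameTiming] = None,
) -> List[StateTrajectory]:
    """Simulate and label all `design.n_dna` trajectories.

    Seeding: one SeedSequence is spawned per DNA for the kinetics and one
    for labeling, so results are reproducible and independent of n_dna
    ordering.
    """
    timing = timing or FrameTiming()
    duration = design.duration_cycles * timing.cycle_s
    ss = np.random.SeedSequence(rng_seed)
    kin_ss, lab_ss = ss.spawn(2)
    kin_children = kin_ss.spawn(design.n_dna)
    lab_children = lab_ss.spawn(design.n_dna)
    trajs = []
    for i in range(design.n_dna):
        traj = simulate_trajectory(
            params, design, np.random.default_rng(kin_children[i]),
            dna_id=i, duration_s=duration)
        assign_labels(design, traj, np.random.default_rng(lab_children[i]))
        trajs.append(traj)
    return trajs


def assign_labels(
    design: ExperimentDesign,
    trajectory: StateTrajectory,
    rng_seed,
) -> StateTrajectory:
    """Independently draw a label class for every molecule from its plan."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    plans = {"orc": design.orc_label_plan,
             "mcm": design.mcm_label_plan,
             "cdt1": design.cdt1_label_plan}
    for mol in trajectory.molecules:
        plan = plans[mol.species]
        classes = list(plan.keys())
        probs = np.array([plan[c] for c in classes], dtype=float)
        probs = probs / probs.sum()
        mol.label = classes[int(rng.choice(len(classes), p=probs))]
    return trajectory


def ground_truth_table(trajectories: Sequence[StateTrajectory]) -> pd.DataFrame:
    """Event log over all DNAs: dna_id, event_kind, time_s, molecule_id,
    label_class (CSV-exportable ground truth)."""
    rows = []
    for traj in trajectories:
        for kind, t, mol_id, label in traj.events():
            rows.append((traj.dna_id, kind, t, mol_id, label))
    return pd.DataFrame(
        rows, columns=["dna_id", "event_kind", "time_s", "molecule_id",
                       "label_class"])
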