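"""Rendering of labeled state trajectories into fluorescence traces.

Acquisition model: alternating 1-s donor- and acceptor-excited exposures
(0.2-s dead time after each) on a 2.4-s cycle.  During donor excitation a
donor-labeled ORC emits a total intensity T = unit_intensity x PIFE (PIFE
is active while an OM interaction is engaged); when a FRET-coupled
acceptor is present the emission is split I_Aem = E*T, I_Dem = (1-E)*T
with E the apparent-FRET set-point of the active state.  Acceptor-excited
frames report direct excitation: unit_intensity per present, unbleached
acceptor fluorophore.  State occupancy is integrated over each exposure,
so a transition inside a frame scales emission by time-in-state.  Additive
zero-mean Gaussian noise models background-corrected records.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import Interaction, Molecule, StateTrajectory
from .params import (
    ACCEPTOR_C,
    ACCEPTOR_N,
    DONOR_C,
    DONOR_N,
    ExperimentDesign,
    FrameTiming,
    PhotophysicsParams,
)

_ACCEPTOR_LABELS = (ACCEPTOR_C, ACCEPTOR_N)
_DONOR_LABELS = (DONOR_C, DONOR_N)


@dataclass
class Trace:
    """Per-spot intensities. Donor-excited frames carry I_Dex_Dem/I_Dex_Aem,
    acceptor-excited frames carry I_Aex_Aem."""

    dna_id: int
    donor_t: np.ndarray        # start times of donor-excited exposures
    acceptor_t: np.ndarray     # start times of acceptor-excited exposures
    I_Dex_Dem: np.ndarray
    I_Dex_Aem: np.ndarray
    I_Aex_Aem: np.ndarray
    trajectory: Optional[StateTrajectory] = None

    @property
    def n_cycles(self) -> int:
        return len(self.donor_t)


@dataclass
class TraceSet:
    """A rendered experiment: one Trace per DNA plus embedded ground truth."""

    traces: List[Trace]
    timing: FrameTiming
    phys: PhotophysicsParams
    design: ExperimentDesign
    noise_seed: int = 0
    noiseless: bool = False

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def trajectories(self) -> List[StateTrajectory]:
        return [tr.trajectory for tr in self.traces]

    def frame_table(self) -> pd.DataFrame:
        """Interleaved per-frame table (one row per dna_id x frame).
        Channels not measured on a frame kind are NaN."""
        rows = []
        for tr in self.traces:
            n = tr.n_cycles
            t = np.empty(2 * n)
            t[0::2] = tr.donor_t
            t[1::2] = tr.acceptor_t
            kind = np.empty(2 * n, dtype=object)
            kind[0::2] = "donor_ex"
            kind[1::2] = "acceptor_ex"
            dem = np.full(2 * n, np.nan)
            aem = np.full(2 * n, np.nan)
            axa = np.full(2 * n, np.nan)
            dem[0::2] = tr.I_Dex_Dem
            aem[0::2] = tr.I_Dex_Aem
            axa[1::2] = tr.I_Aex_Aem
            df = pd.DataFrame({
                "dna_id": tr.dna_id, "frame": np.arange(2 * n),
                "time_s": t, "frame_kind": kind,
                "I_Dex_Dem": dem, "I_Dex_Aem": aem, "I_Aex_Aem": axa,
            })
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    # ---- I/O: CSV and an HDF5 hierarchical container (schema v1) ----

    def to_csv(self, path) -> None:
        self.frame_table().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, timing: Optional[FrameTiming] = None,
                 phys: Optional[PhotophysicsParams] = None,
                 design: Optional[ExperimentDesign] = None) -> "TraceSet":
        df = pd.read_csv(path)
        traces = []
        for dna_id, g in df.groupby("dna_id", sort=True):
            d = g[g.frame_kind == "donor_ex"]
            a = g[g.frame_kind == "acceptor_ex"]
            traces.append(Trace(
                dna_id=int(dna_id),
                donor_t=d.time_s.to_numpy(),
                acceptor_t=a.time_s.to_numpy(),
                I_Dex_Dem=d.I_Dex_Dem.to_numpy(),
                I_Dex_Aem=d.I_Dex_Aem.to_numpy(),
                I_Aex_Aem=a.I_Aex_Aem.to_numpy(),
            ))
        return cls(traces, timing or FrameTiming(),
                   phys or PhotophysicsParams(),
                   design or ExperimentDesign(n_dna=max(1, len(traces))))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema"] = "cosmofret-traceset-v1"
            f.attrs["cycle_s"] = self.timing.cycle_s
            f.attrs["n_cycles"] = self.timing.n_cycles
            f.attrs["noise_seed"] = self.noise_seed
            for tr in self.traces:
                g = f.create_group(f"dna/{tr.dna_id}")
                for name in ("donor_t", "acceptor_t", "I_Dex_Dem",
                             "I_Dex_Aem", "I_Aex_Aem"):
                    g.create_dataset(name, data=getattr(tr, name))

    @classmethod
    def from_hdf5(cls, path, timing: Optional[FrameTiming] = None,
                  phys: Optional[PhotophysicsParams] = None,
                  design: Optional[ExperimentDesign] = None) -> "TraceSet":
        import h5py

        traces = []
        with h5py.File(path, "r") as f:
            ids = sorted(int(k) for k in f["dna"])
            for dna_id in ids:
                g = f[f"dna/{dna_id}"]
                traces.append(Trace(
                    dna_id=dna_id,
                    donor_t=g["donor_t"][...],
                    acceptor_t=g["acceptor_t"][...],
                    I_Dex_Dem=g["I_Dex_Dem"][...],
                    I_Dex_Aem=g["I_Dex_Aem"][...],
                    I_Aex_Aem=g["I_Aex_Aem"][...],
                ))
            noise_seed = int(f.attrs.get("noise_seed", 0))
        ts = cls(traces, timing or FrameTiming(), phys or PhotophysicsParams(),
                 design or ExperimentDesign(n_dna=max(1, len(traces))))
        ts.noise_seed = noise_seed
        return ts


def _dye_window(mol: Molecule, T: float) -> tuple:
    """[on, off) interval during which this molecule's dye is emissive."""
    off = min(mol.t_off, T)
    if mol.bleach_t is not None:
        off = min(off, mol.bleach_t)
    return (min(mol.t_on, T), off)


def _overlap(starts: np.ndarray, exposure: float, a: float, b: float) -> np.ndarray:
    """Seconds of each exposure window [s, s+exposure) inside [a, b)."""
    lo = np.maximum(starts, a)
    hi = np.minimum(starts + exposure, b)
    return np.clip(hi - lo, 0.0, None)


def _segment_rates(traj: StateTrajectory, phys: PhotophysicsParams,
                   design: ExperimentDesign, T: float):
    """Piecewise-constant emission rates.

    Returns (breaks, dem_rate, aem_rate, acc_rate): for each segment
    [breaks[i], breaks[i+1]), donor-excited D-emission and A-emission
    rates and the acceptor-excited rate, all in intensity units per second
    of exposure normalised so that one full exposure of one fluorophore
    integrates to unit_intensity.
    """
    pts = {0.0, T}
    for m in traj.molecules:
        a, b = _dye_window(m, T)
        pts.add(a)
        pts.add(b)
    for it in traj.interactions:
        pts.add(min(max(it.t_start, 0.0), T))
        pts.add(min(max(it.t_end, 0.0), T))
    breaks = np.array(sorted(pts))
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    unit = phys.unit_intensity

    donors = [m for m in traj.molecules
              if m.species == "orc" and m.label in _DONOR_LABELS]
    acceptors = [m for m in traj.molecules if m.label in _ACCEPTOR_LABELS
                 and m.species in ("mcm", "cdt1")]
    cdt1_by_ton = {m.t_on: m for m in traj.molecules if m.species == "cdt1"}
    mol_by_id = {m.mol_id: m for m in traj.molecules}

    dem = np.zeros(len(mids))
    aem = np.zeros(len(mids))
    acc = np.zeros(len(mids))

    for j, t in enumerate(mids):
        mcm_acc_present = any(
            m.species == "mcm" and _dye_window(m, T)[0] <= t < _dye_window(m, T)[1]
            for m in acceptors)
        cdt1_acc_present = any(
            m.species == "cdt1" and _dye_window(m, T)[0] <= t < _dye_window(m, T)[1]
            for m in acceptors)
        acc[j] = sum(
            1.0 for m in acceptors
            if _dye_window(m, T)[0] <= t < _dye_window(m, T)[1])
        for d in donors:
            a, b = _dye_window(d, T)
            if not (a <= t < b):
                continue
            om = next((it for it in traj.interactions
                       if it.kind == "om" and it.active(t)
                       and it.orc_id == d.mol_id), None)
            pife = phys.pife_factor if om is not None else 1.0
            E = 0.0
            if design.reporter == "om" and om is not None and d.label == DONOR_C:
                carrier = mol_by_id[om.mcm_id]
                ca, cb = _dye_window(carrier, T)
                if carrier.label == ACCEPTOR_C and ca <= t < cb:
                    E = (phys.efret_om_first if om.order == 1
                         else phys.efret_om_second)
                    cdt1 = cdt1_by_ton.get(carrier.t_on)
                    if cdt1 is not None and cdt1.label == ACCEPTOR_N:
                        w = _dye_window(cdt1, T)
                        if w[0] <= t < w[1]:
                            E = phys.efret_om_with_cdt1N
                elif mcm_acc_present or cdt1_acc_present:
                    E = phys.efret_baseline
            elif design.reporter == "mo" and d.label == DONOR_C:
                mo = next((it for it in traj.interactions
                           if it.kind == "mo" and it.active(t)
                           and it.orc_id == d.mol_id), None)
                hit = False
                if mo is not None:
                    mcm1 = mol_by_id[mo.mcm_id]
                    wa, wb = _dye_window(mcm1, T)
                    if mcm1.label == ACCEPTOR_N and wa <= t < wb:
                        E = phys.efret_mo
                        hit = True
                if not hit and (mcm_acc_present or cdt1_acc_present):
                    E = phys.efret_baseline
            elif mcm_acc_present or cdt1_acc_present:
                # donor present but not FRET-competent pairing (e.g. N-labeled
                # ORC, or om reporter with no engagement)
                E = phys.efret_baseline
            if E == 0.0 and not (mcm_acc_present or cdt1_acc_present):
                E = 0.0
            elif (E == phys.efret_baseline and not mcm_acc_present
                  and cdt1_acc_present and design.reporter == "om"):
                # donor + acceptor-Cdt1 only: the Cdt1 control set-point
                E = phys.efret_cdt1_control
            dem[j] += unit * pife * (1.0 - E)
            aem[j] += unit * pife * E
    return breaks, dem, aem, acc


def _render_one(traj: StateTrajectory, timing: FrameTiming,
                phys: PhotophysicsParams, design: ExperimentDesign,
                noise_rng: Optional[np.random.Generator]) -> Trace:
    T = timing.duration_s
    d_starts = timing.donor_frame_starts()
    a_starts = timing.acceptor_frame_starts()
    breaks, dem, aem, acc = _segment_rates(traj, phys, design, T)

    I_dem = np.zeros(len(d_starts))
    I_aem = np.zeros(len(d_starts))
    I_acc = np.zeros(len(a_starts))
    for i in range(len(breaks) - 1):
        a, b = breaks[i], breaks[i + 1]
        if b <= a:
            continue
        if dem[i] or aem[i]:
            ov = _overlap(d_starts, timing.donor_exposure_s, a, b)
            # normalise so a full exposure integrates to the per-frame unit
            I_dem += dem[i] * ov / timing.donor_exposure_s
            I_aem += aem[i] * ov / timing.donor_exposure_s
        if acc[i]:
            ov = _overlap(a_starts, timing.acceptor_exposure_s, a, b)
            I_acc += phys.unit_intensity * acc[i] * ov / timing.acceptor_exposure_s
    if noise_rng is not None and phys.background_sd > 0:
        sd = phys.background_sd
        I_dem = I_dem + noise_rng.normal(0.0, sd, len(I_dem))
        I_aem = I_aem + noise_rng.normal(0.0, sd, len(I_aem))
        I_acc = I_acc + noise_rng.normal(0.0, sd, len(I_acc))
    return Trace(traj.dna_id, d_starts, a_starts, I_dem, I_aem, I_acc,
                 trajectory=traj)


def render_traces(
    trajectories: Sequence[StateTrajectory],
    timing: FrameTiming,
    phys: PhotophysicsParams,
    design: ExperimentDesign,
    rng_seed: int = 0,
    noiseless: bool = False,
) -> TraceSet:
    """Render every trajectory into a three-channel trace.

    Noise is generated from per-DNA generators spawned off `rng_seed`, so
    re-rendering the same trajectories with the same seed is bit-identical
    (this is what makes `apply_photobleaching(bleach_prob=0)` a no-op).
    """
    children = np.random.SeedSequence(rng_seed).spawn(len(trajectories))
    traces = []
    for traj, child in zip(trajectories, children):
        rng = None if noiseless else np.random.default_rng(child)
        traces.append(_render_one(traj, timing, phys, design, rng))
    ts = TraceSet(traces, timing, phys, design)
    ts.noise_seed = rng_seed
    ts.noiseless = noiseless
    return ts


def apply_photobleaching(
    traceset: TraceSet,
    phys: PhotophysicsParams,
    rng_seed: int = 0,
) -> TraceSet:
    """Bleach each dye independently with a per-illuminated-frame Bernoulli
    probability (scaled by the design's laser exposure factor) and re-render.

    Bleach times are recorded on the ground-truth molecules.  The observed
    fluorophore-loss rate is then intrinsic departure + bleach hazard.
    With bleach_prob_per_exposure == 0 the returned traces are identical
    to the input (same noise seed).
    """
    timing = traceset.timing
    design = traceset.design
    p = phys.bleach_prob_per_exposure * design.laser_exposure_factor
    trajectories = copy.deepcopy(traceset.trajectories)
    rng = np.random.default_rng(rng_seed)
    T = timing.duration_s
    if p > 0:
        for traj in trajectories:
            for m in traj.molecules:
                if m.label not in _ACCEPTOR_LABELS + _DONOR_LABELS:
                    continue
                if m.label in _DONOR_LABELS:
                    starts = timing.donor_frame_starts()
                    exposure = timing.donor_exposure_s
                else:
                    starts = timing.acceptor_frame_starts()
                    exposure = timing.acceptor_exposure_s
                a, b = m.t_on, min(m.t_off, T)
                lit = starts[(starts + exposure > a) & (starts < b)]
                if len(lit) == 0:
                    continue
                k = rng.geometric(p)  # 1-based index of the fatal exposure
                if k <= len(lit):
                    m.bleach_t = float(lit[k - 1])
    out = render_traces(trajectories, timing, phys, design,
                        rng_seed=traceset.noise_seed,
                        noiseless=traceset.noiseless)
    return out
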