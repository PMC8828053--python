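"""Parameter containers for the helicase-loading simulator and analysis.

The kinetic scheme being parameterised is the single-ORC "flip" pathway of
origin licensing in budding yeast: ORC binds origin DNA, recruits a first
Cdt1-bound Mcm2-7 through a C-terminal ORC--Mcm2-7 interface (the "OM"
interaction), releases Cdt1 (which terminates the OM interaction), inverts
over the first helicase to form the "MO" intermediate, recruits a second
Mcm2-7 through a second OM interaction, and leaves once head-to-head
double-hexamer contacts form.  Alternative mechanistic hypotheses
(Re-FRET, ORC exchange, two independent ORCs) are selectable so that the
label-mixing experiments that discriminate between them can be emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict

# Fluorophore label classes.  "C"/"N" refer to the protein terminus carrying
# the dye: for the OM reporter pair the donor is on the Orc5 C-terminus and
# the acceptor on the Mcm2 C-terminus; for the MO reporter pair the donor is
# on the Orc6 C-terminus and the acceptor on the Mcm3 N-terminus.
DONOR_C = "donor_c"
DONOR_N = "donor_n"
ACCEPTOR_C = "acceptor_c"
ACCEPTOR_N = "acceptor_n"
UNLABELED = "unlabeled"

ORC_CLASSES = (DONOR_C, DONOR_N, UNLABELED)
MCM_CLASSES = (ACCEPTOR_C, ACCEPTOR_N, UNLABELED)
CDT1_CLASSES = (ACCEPTOR_N, ACCEPTOR_C, UNLABELED)

MECHANISMS = ("orc_flip", "re_fret", "orc_exchange", "two_orc_independent")
MUTANTS = ("wildtype", "mcm5RA", "orc6dN119")

LN2 = math.log(2.0)


class ConfigurationError(ValueError):
    """Raised for invalid simulator or analysis configuration."""


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {p!r}")


def _check_pos(name: str, x: float) -> None:
    if not (x > 0):
        raise ConfigurationError(f"{name} must be > 0, got {x!r}")


def _check_plan(name: str, plan: Dict[str, float], classes) -> None:
    for k in plan:
        if k not in classes:
            raise ConfigurationError(f"{name}: unknown label class {k!r}")
    total = sum(plan.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: class probabilities sum to {total}, not 1")
    for k, v in plan.items():
        _check_prob(f"{name}[{k}]", v)


@dataclass
class KineticParams:
    """Rates, dwell means and branch probabilities of the loading pathway.

    All dwell and lag distributions are exponential by default; the one
    median-parameterised quantity (`mean_m1_release_after_orc_s`) stores the
    *median* and is converted internally via rate = ln2 / median.  Defaults
    are the values measured on the wild-type reaction: first/second OM means
    30 s and 56 s, MO-onset lag 8.3 s after first Cdt1 release, MO end 9.7 s
    after second Mcm2-7 arrival, MO-formation probability 0.23, conditional
    stable-second-recruitment probability 0.79, lone-Mcm2-7 median lifetime
    11 s after ORC departure, and 5RA composite fluorophore-loss mean 156 s.
    """

    orc_arrival_rate: float = 0.005      # events/s per free DNA
    mcm_arrival_rate: float = 0.01       # events/s per ORC- or MO-bound DNA
    mean_first_om_s: float = 30.0
    mean_second_om_s: float = 56.0
    mean_mo_delay_s: float = 8.3
    mean_mo_end_after_m2_s: float = 9.7
    p_mo_given_first_mcm: float = 0.23
    p_second_given_mo: float = 0.79
    mean_m1_release_after_orc_s: float = 11.0   # MEDIAN of the lone-Mcm dwell
    p_abortive_second: float = 0.10
    mean_abortive_dwell_s: float = 20.0
    p_one_orc: float = 0.81
    p_two_orc_sequential: float = 8.0 / 166.0
    p_two_orc_overlap: float = 14.0 / 166.0
    mechanism: str = "orc_flip"
    mutant: str = "wildtype"
    # --- quantities the paper leaves free or defines only implicitly ---
    mean_5ra_loss_s: float = 156.0       # composite bleach/departure loss, 5RA
    mean_orc_depart_no_mo_s: float = 10.0
    mean_mo_abort_s: float = 40.0        # MO lifetime when no second Mcm comes
    p_mo_dn119: float = 5.0 / 418.0      # near-zero MO probability, Orc6-dN119
    mean_nonspecific_orc_dwell_s: float = 10.0
    mean_two_orc_handoff_s: float = 5.0  # 1st-ORC departure lag, sequential 2-ORC

    def __post_init__(self) -> None:
        for name in (
            "orc_arrival_rate", "mcm_arrival_rate", "mean_first_om_s",
            "mean_second_om_s", "mean_mo_delay_s", "mean_mo_end_after_m2_s",
            "mean_m1_release_after_orc_s", "mean_abortive_dwell_s",
            "mean_5ra_loss_s", "mean_orc_depart_no_mo_s", "mean_mo_abort_s",
            "mean_nonspecific_orc_dwell_s", "mean_two_orc_handoff_s",
        ):
            _check_pos(name, getattr(self, name))
        for name in (
            "p_mo_given_first_mcm", "p_second_given_mo", "p_abortive_second",
            "p_one_orc", "p_two_orc_sequential", "p_two_orc_overlap",
            "p_mo_dn119",
        ):
            _check_prob(name, getattr(self, name))
        if self.p_second_given_mo + self.p_abortive_second > 1.0 + 1e-9:
            raise ConfigurationError(
                "p_second_given_mo + p_abortive_second must not exceed 1")
        mix = self.p_one_orc + self.p_two_orc_sequential + self.p_two_orc_overlap
        if mix > 1.0 + 1e-9:
            raise ConfigurationError("ORC-usage mixture weights sum to > 1")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.mutant not in MUTANTS:
            raise ConfigurationError(f"unknown mutant {self.mutant!r}")

    @property
    def m1_release_rate(self) -> float:
        """Departure rate of a lone first Mcm2-7 after ORC leaves (ln2/median)."""
        return LN2 / self.mean_m1_release_after_orc_s

    @property
    def p_mo_effective(self) -> float:
        if self.mutant == "orc6dN119":
            return self.p_mo_dn119
        return self.p_mo_given_first_mcm

    @property
    def p_extra_orc(self) -> float:
        """Weight of the nonspecific extra-ORC (3+) class."""
        return max(
            0.0,
            1.0 - self.p_one_orc - self.p_two_orc_sequential - self.p_two_orc_overlap,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _default_orc_plan() -> Dict[str, float]:
    return {DONOR_C: 0.88, UNLABELED: 0.12}


def _default_mcm_plan() -> Dict[str, float]:
    return {ACCEPTOR_C: 1.0}


def _default_cdt1_plan() -> Dict[str, float]:
    return {UNLABELED: 1.0}


@dataclass
class ExperimentDesign:
    """Acquisition-level design: sample size, labeling plans, reporter pair.

    `reporter` selects which ORC--Mcm2-7 interface the donor/acceptor pair
    reads out: "om" (Orc5-C donor / Mcm2-C acceptor, high FRET during OM
    interactions) or "mo" (Orc6-C donor / Mcm3-N acceptor, high FRET during
    the MO interaction).  The default ORC labeling probability is 0.88, the
    measured labeled fraction of the donor-ORC preparation.
    """

    n_dna: int = 100
    duration_cycles: int = 600
    orc_label_plan: Dict[str, float] = field(default_factory=_default_orc_plan)
    mcm_label_plan: Dict[str, float] = field(default_factory=_default_mcm_plan)
    cdt1_label_plan: Dict[str, float] = field(default_factory=_default_cdt1_plan)
    staged_prebound: bool = False
    laser_exposure_factor: float = 1.0
    reporter: str = "om"

    def __post_init__(self) -> None:
        if self.n_dna < 1:
            raise ConfigurationError("n_dna must be >= 1")
        if self.duration_cycles < 1:
            raise ConfigurationError("duration_cycles must be >= 1")
        _check_plan("orc_label_plan", self.orc_label_plan, ORC_CLASSES)
        _check_plan("mcm_label_plan", self.mcm_label_plan, MCM_CLASSES)
        _check_plan("cdt1_label_plan", self.cdt1_label_plan, CDT1_CLASSES)
        if self.laser_exposure_factor <= 0:
            raise ConfigurationError("laser_exposure_factor must be > 0")
        if self.reporter not in ("om", "mo"):
            raise ConfigurationError(f"unknown reporter {self.reporter!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrameTiming:
    """Alternating-excitation cycle: 1-s donor and acceptor exposures with
    0.2-s dead times, a 2.4-s cycle repeated 600 times (~24 min)."""

    cycle_s: float = 2.4
    donor_exposure_s: float = 1.0
    acceptor_exposure_s: float = 1.0
    dead_s: float = 0.2
    n_cycles: int = 600

    def __post_init__(self) -> None:
        expected = self.donor_exposure_s + self.acceptor_exposure_s + 2 * self.dead_s
        if abs(self.cycle_s - expected) > 1e-9:
            raise ConfigurationError(
                "cycle_s must equal donor + acceptor exposure + 2 * dead time")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.cycle_s * self.n_cycles

    def donor_frame_starts(self):
        import numpy as np
        return np.arange(self.n_cycles) * self.cycle_s

    def acceptor_frame_starts(self):
        import numpy as np
        return (np.arange(self.n_cycles) * self.cycle_s
                + self.donor_exposure_s + self.dead_s)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhotophysicsParams:
    """Emission model: apparent-FRET set-points, PIFE, bleaching, noise.

    Set-points are the measured apparent FRET efficiencies: 0.72 / 0.79 for
    the first / second OM interaction, 0.73 for the MO interaction, 0.08
    no-interaction baseline with donor and acceptor co-resident, 0.83 for OM
    with an additional N-terminally acceptor-labeled Cdt1, 0.358 for the
    donor-ORC / acceptor-Cdt1-only control.
    """

    unit_intensity: float = 1000.0
    background_sd: float = 150.0
    efret_om_first: float = 0.72
    efret_om_second: float = 0.79
    efret_mo: float = 0.73
    efret_baseline: float = 0.08
    efret_om_with_cdt1N: float = 0.83
    efret_cdt1_control: float = 0.358
    pife_factor: float = 1.3
    bleach_prob_per_exposure: float = 2e-4

    def __post_init__(self) -> None:
        for name in ("efret_om_first", "efret_om_second", "efret_mo",
                     "efret_baseline", "efret_om_with_cdt1N",
                     "efret_cdt1_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.pife_factor < 1.0:
            raise ConfigurationError("pife_factor must be >= 1")
        _check_prob("bleach_prob_per_exposure", self.bleach_prob_per_exposure)
        _check_pos("unit_intensity", self.unit_intensity)
        if self.background_sd < 0:
            raise ConfigurationError("background_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisParams:
    """Detection thresholds of the analysis layer.

    The high-FRET threshold (0.4) sits midway between the 0.08 baseline and
    the ~0.72-0.79 interaction states; hysteresis factors k_on=4 / k_off=2
    and the minimum run length are stand-ins for thresholds the original
    pipeline does not print.
    """

    fret_high_threshold: float = 0.4
    fret_min_frames: int = 2
    fret_max_gap_frames: int = 1
    confirm_arrival_s: float = 4.8
    k_on: float = 4.0
    k_off: float = 2.0
    step_alpha: float = 1e-3
    step_min_frames: int = 2
    retention_threshold_s: float = 48.0
    attribution_window_s: float = 4.8
    coincidence_window_s: float = 2.4

    def __post_init__(self) -> None:
        if not (0.0 < self.fret_high_threshold < 1.0):
            raise ConfigurationError("fret_high_threshold must be in (0, 1)")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ConfigurationError("hysteresis thresholds must be positive")
        if self.k_on < self.k_off:
            raise ConfigurationError("k_on must be >= k_off")
        if not (0.0 < self.step_alpha < 1.0):
            raise ConfigurationError("step_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
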