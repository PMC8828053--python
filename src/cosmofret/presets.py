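"""Named experiment presets mirroring the figure-analog designs.

Each preset bundles the kinetic parameters, labeling plan and reporter
pair of one experimental configuration: the baseline OM-reporter reaction
(0.5 nM donor-ORC / 15 nM acceptor-Mcm2-7), the two label-mixing designs
that discriminate loading mechanisms, the Cdt1-costained designs, the two
loading-defective mutants, the staged (prebound ORC/Cdc6) reaction, and
the photobleaching-control pair.
"""

from __future__ import annotations

from typing import Dict

from .params import (
    ACCEPTOR_C,
    ACCEPTOR_N,
    DONOR_C,
    DONOR_N,
    UNLABELED,
    ExperimentDesign,
    KineticParams,
)

ORC_LABEL_P = 0.88  # measured labeled fraction of the donor-ORC preparation


def _design(**kw) -> ExperimentDesign:
    base = dict(
        n_dna=100,
        orc_label_plan={DONOR_C: ORC_LABEL_P, UNLABELED: 1 - ORC_LABEL_P},
        mcm_label_plan={ACCEPTOR_C: 1.0},
        cdt1_label_plan={UNLABELED: 1.0},
        reporter="om",
    )
    base.update(kw)
    return ExperimentDesign(**base)


def get_preset(name: str, n_dna: int = 100):
    """Return (KineticParams, ExperimentDesign) for a named preset."""
    if name not in PRESET_BUILDERS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESET_BUILDERS)}")
    params, design = PRESET_BUILDERS[name]()
    design.n_dna = n_dna
    return params, design


def _fig1():
    return KineticParams(), _design()


def _fig2_mixed_mcm():
    return KineticParams(), _design(
        mcm_label_plan={ACCEPTOR_C: 0.5, ACCEPTOR_N: 0.5})


def _fig3_mixed_orc():
    return KineticParams(), _design(
        orc_label_plan={DONOR_C: ORC_LABEL_P / 2, DONOR_N: ORC_LABEL_P / 2,
                        UNLABELED: 1 - ORC_LABEL_P})


def _fig4_cdt1():
    return KineticParams(), _design(cdt1_label_plan={ACCEPTOR_N: 1.0})


def _fig4_5ra():
    return KineticParams(mutant="mcm5RA"), _design()


def _fig5_mo():
    return KineticParams(), _design(
        reporter="mo", mcm_label_plan={ACCEPTOR_N: 1.0})


def _fig5_dn119():
    return KineticParams(mutant="orc6dN119"), _design(
        reporter="mo", mcm_label_plan={ACCEPTOR_N: 1.0})


def _fig5_prebound():
    return KineticParams(), _design(
        reporter="mo", mcm_label_plan={ACCEPTOR_N: 1.0},
        staged_prebound=True)


def _fig6_cdt1c():
    return KineticParams(), _design(
        reporter="mo", mcm_label_plan={ACCEPTOR_N: 1.0},
        cdt1_label_plan={ACCEPTOR_C: 1.0})


def _bleach_control_low():
    # 5RA with unlabeled Mcm2-7: the donor-ORC dwell is limited only by
    # departure and bleaching; relative laser exposure 1.0
    return (KineticParams(mutant="mcm5RA"),
            _design(mcm_label_plan={UNLABELED: 1.0},
                    laser_exposure_factor=1.0))


def _bleach_control_high():
    return (KineticParams(mutant="mcm5RA"),
            _design(mcm_label_plan={UNLABELED: 1.0},
                    laser_exposure_factor=2.4))


PRESET_BUILDERS: Dict[str, callable] = {
    "fig1": _fig1,
    "fig2-mixedMcm": _fig2_mixed_mcm,
    "fig3-mixedORC": _fig3_mixed_orc,
    "fig4-cdt1": _fig4_cdt1,
    "fig4-5RA": _fig4_5ra,
    "fig5-MO": _fig5_mo,
    "fig5-dN119": _fig5_dn119,
    "fig5-prebound": _fig5_prebound,
    "fig6-cdt1C": _fig6_cdt1c,
    "bleach-control": _bleach_control_low,
    "bleach-control-2.4": _bleach_control_high,
}

PRESETS = tuple(PRESET_BUILDERS)
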