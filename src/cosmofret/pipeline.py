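"""End-to-end orchestration: configuration, seeding, simulate / analyze /
report.

Reproducibility contract: a run is a pure function of (config, master
seed).  The master seed is split with numpy's SeedSequence into one child
per stage (kinetics+labels, rendering noise, photobleaching), and each
stage spawns one grandchild per DNA, so outputs are bit-identical across
runs and independent of evaluation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .analysis import TraceAnalysis, analyze_trace, correct_background
from .events import EventRecord, assemble_events, coincidence
from .kinetics import StateTrajectory, ground_truth_table, simulate_experiment
from .kinstats import (
    fit_exponential_mle,
    offset_histogram,
    proportion_with_se,
    survival_curve,
)
from .params import (
    AnalysisParams,
    ConfigurationError,
    ExperimentDesign,
    FrameTiming,
    KineticParams,
    PhotophysicsParams,
)
from .presets import get_preset
from .traces import Trace, TraceSet, apply_photobleaching, render_traces


@dataclass
class RunConfig:
    """Fully serialisable run description (preset + overrides + seed)."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    timing: FrameTiming = field(default_factory=FrameTiming)
    phys: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    preset: str = ""
    bleaching: bool = True

    @classmethod
    def from_preset(cls, name: str, n_dna: int = 100, seed: int = 0,
                    **overrides) -> "RunConfig":
        params, design = get_preset(name, n_dna=n_dna)
        cfg = cls(kinetics=params, design=design, seed=seed, preset=name)
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise ConfigurationError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        cfg.timing = FrameTiming(n_cycles=design.duration_cycles)
        return cfg

    def to_dict(self) -> dict:
        return {
            "kinetics": self.kinetics.to_dict(),
            "design": self.design.to_dict(),
            "timing": self.timing.to_dict(),
            "phys": self.phys.to_dict(),
            "analysis": self.analysis.to_dict(),
            "seed": self.seed,
            "preset": self.preset,
            "bleaching": self.bleaching,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            kinetics=KineticParams(**raw.get("kinetics", {})),
            design=ExperimentDesign(**raw.get("design", {})),
            timing=FrameTiming(**raw.get("timing", {})),
            phys=PhotophysicsParams(**raw.get("phys", {})),
            analysis=AnalysisParams(**raw.get("analysis", {})),
            seed=int(raw.get("seed", 0)),
            preset=str(raw.get("preset", "")),
            bleaching=bool(raw.get("bleaching", True)),
        )

    def stage_seeds(self) -> Tuple[int, int, int]:
        """(kinetics, noise, bleach) sub-seeds derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(int(c.generate_state(1)[0] % (2 ** 31)) for c in children)


def cmd_simulate(config: RunConfig, out_dir: Optional[Path] = None) -> TraceSet:
    """Simulate trajectories, render traces, optionally bleach, and write
    trace + ground-truth + config-snapshot files."""
    kin_seed, noise_seed, bleach_seed = config.stage_seeds()
    trajs = simulate_experiment(config.kinetics, config.design, kin_seed,
                                timing=config.timing)
    ts = render_traces(trajs, config.timing, config.phys, config.design,
                       rng_seed=noise_seed)
    if config.bleaching and config.phys.bleach_prob_per_exposure > 0:
        ts = apply_photobleaching(ts, config.phys, rng_seed=bleach_seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ts.to_csv(out / "traces.csv")
        ts.to_hdf5(out / "traces.h5")
        ground_truth_table(ts.trajectories).to_csv(
            out / "ground_truth.csv", index=False)
        config.to_yaml(out / "config.yaml")
    return ts


def _design_kind(config: RunConfig) -> Optional[str]:
    plan = config.design.mcm_label_plan
    if len([k for k, v in plan.items() if v > 0 and k != "unlabeled"]) > 1:
        return "mixed_mcm"
    oplan = config.design.orc_label_plan
    if len([k for k, v in oplan.items() if v > 0 and k != "unlabeled"]) > 1:
        return "mixed_orc"
    return None


def cmd_analyze(
    traceset: TraceSet,
    config: RunConfig,
) -> Tuple[List[TraceAnalysis], List[EventRecord]]:
    """Run the measurement layer and event assembly on every trace."""
    cfg = config.analysis
    record_end = config.timing.duration_s
    # MO-FRET onset is deliberately not coincident with an acceptor
    # arrival, so the onset-confirmation rule applies only to the OM pair.
    confirm = config.design.reporter == "om"
    kind = _design_kind(config)
    analyses: List[TraceAnalysis] = []
    events: List[EventRecord] = []
    for trace in traceset:
        # simulator output is already background-corrected, so this is a
        # no-op within noise; it matters for externally produced records
        corrected = Trace(
            dna_id=trace.dna_id, donor_t=trace.donor_t,
            acceptor_t=trace.acceptor_t,
            I_Dex_Dem=correct_background(trace.I_Dex_Dem)[0],
            I_Dex_Aem=correct_background(trace.I_Dex_Aem)[0],
            I_Aex_Aem=correct_background(trace.I_Aex_Aem)[0],
            trajectory=trace.trajectory)
        an = analyze_trace(corrected, cfg, confirm_arrivals=confirm,
                           unit=config.phys.unit_intensity)
        evs = assemble_events(
            an, record_end, reporter=config.design.reporter,
            unit_intensity=config.phys.unit_intensity, cfg=cfg,
            design_kind=kind)
        analyses.append(an)
        events.extend(evs)
    return analyses, events


def compute_statistics(
    events: Sequence[EventRecord],
    analyses: Sequence[TraceAnalysis],
    config: RunConfig,
) -> Dict:
    """Population statistics keyed by figure-analog."""
    cfg = config.analysis
    T = config.timing.duration_s
    cyc = config.timing.cycle_s
    out: Dict = {"n_events": len(events)}
    dh = [e for e in events if e.success]
    # dwell/FRET statistics follow the single-ORC double-hexamer subset
    dh_one = [e for e in dh if e.orc_count_class == "1"]
    # attempts too close to the record end cannot be classified
    eligible = [e for e in events
                if e.t_m1 is not None and e.t_m1 <= T - 250.0]
    out["fig5e"] = {}
    if eligible:
        k = sum(1 for e in eligible if e.success)
        p, se = proportion_with_se(k, len(eligible))
        out["fig5e"] = {"conversion_fraction": p, "se": se,
                        "k": k, "n": len(eligible)}
    if config.design.reporter == "mo":
        if eligible:
            k = sum(1 for e in eligible if e.mo is not None)
            p, se = proportion_with_se(k, len(eligible))
            out["fig5f"] = {"mo_fraction": p, "se": se,
                            "k": k, "n": len(eligible)}
        lags = [e.mo.t_end - e.t_m2 for e in dh_one
                if e.mo is not None and e.t_m2 is not None
                and e.mo.t_end < T - cyc]
        if lags:
            edges, counts, frac, fse = offset_histogram(lags)
            out["fig6d"] = {"mean_mo_end_lag_s": float(np.mean(lags)),
                            "se": float(np.std(lags, ddof=1)
                                        / np.sqrt(len(lags))),
                            "n": len(lags)}
        onset_lags = [e.mo.t_start - e.cdt1_release_times[0]
                      for e in dh_one
                      if e.mo is not None and e.cdt1_release_times]
        if onset_lags:
            out["fig6c"] = {"mean_cdt1_to_mo_s": float(np.mean(onset_lags)),
                            "se": float(np.std(onset_lags, ddof=1)
                                        / np.sqrt(len(onset_lags))),
                            "n": len(onset_lags)}
    else:
        # an OM interval ending with complex dissolution (ORC departing
        # as the interaction ends) is an observed termination; censoring
        # applies only at the record end
        om1 = [(e.om1.duration, e.om1.t_end >= T - cyc)
               for e in dh_one if e.om1 is not None]
        om2 = [(e.om2.duration, e.om2.t_end >= T - cyc)
               for e in dh_one if e.om2 is not None]
        # effective left truncation of the interval detector: a run of
        # min_frames frames corresponds to true dwells down to about
        # (min_frames - 0.5) cycles under the exposure geometry
        min_dur = (cfg.fret_min_frames - 0.5) * config.timing.cycle_s
        fits = {}
        for name, data in (("first_om", om1), ("second_om", om2)):
            if len(data) >= 3 and any(not c for _, c in data):
                fit = fit_exponential_mle(
                    [d for d, _ in data], [c for _, c in data],
                    bootstrap_B=200, rng_seed=config.seed,
                    min_duration=min_dur)
                fits[name] = {"mean_s": fit.mean_s, "se_s": fit.se_s,
                              "n": fit.n, "n_censored": fit.n_censored}
        out["fig4a"] = fits
        # Cdt1-release / OM-end coincidence (Cdt1-labeled designs)
        lags = []
        for e in events:
            for om, rel in ((e.om1, 0), (e.om2, 1)):
                if om is not None and len(e.cdt1_release_times) > rel:
                    lags.append(om.t_end - e.cdt1_release_times[rel])
        if lags:
            edges, counts, frac, fse = offset_histogram(lags)
            centre = int(np.argmin(np.abs(0.5 * (edges[:-1] + edges[1:]))))
            out["fig4d"] = {"n": len(lags),
                            "central_bin_fraction": float(frac[centre]),
                            "central_bin_se": float(fse[centre])}
        # FRET-profile frequencies (mixed-label designs)
        typed = [e for e in dh if e.fret_profile]
        if typed and _design_kind(config):
            countd = {}
            for profile in ("two_peak", "none", "first_only", "second_only"):
                k = sum(1 for e in typed if e.fret_profile == profile)
                p, se = proportion_with_se(k, len(typed))
                countd[profile] = {"k": k, "fraction": p, "se": se}
            key = "fig2d" if _design_kind(config) == "mixed_mcm" else "fig3d"
            out[key] = {"n": len(typed), "profiles": countd}
    # ORC counting over successful events
    counted = [e for e in dh if e.orc_count_class]
    if counted:
        classes = {}
        for cls in ("1", "2_sequential", "2_overlap", "3+"):
            k = sum(1 for e in counted if e.orc_count_class == cls)
            p, se = proportion_with_se(k, len(counted))
            classes[cls] = {"k": k, "fraction": p, "se": se}
        out["orc_usage"] = {"n": len(counted), "classes": classes}
    return out


def cmd_report(stats: Dict, events: Sequence[EventRecord]) -> str:
    """Human-readable run summary."""
    lines = ["cosmofret run report", "===================="]
    lines.append(f"events: {stats.get('n_events', 0)} "
                 f"({sum(1 for e in events if e.success)} successful)")
    if "fig5e" in stats and stats["fig5e"]:
        s = stats["fig5e"]
        lines.append(
            f"conversion fraction: {s['conversion_fraction']:.3f} "
            f"+- {s['se']:.3f} ({s['k']}/{s['n']})")
    if "fig5f" in stats:
        s = stats["fig5f"]
        lines.append(f"MO-FRET fraction: {s['mo_fraction']:.3f} "
                     f"+- {s['se']:.3f} ({s['k']}/{s['n']})")
    if "fig4a" in stats:
        for name, f in stats["fig4a"].items():
            lines.append(
                f"{name} dwell: {f['mean_s']:.1f} +- {f['se_s']:.1f} s "
                f"(n={f['n']}, censored={f['n_censored']})")
    for key in ("fig6c", "fig6d"):
        if key in stats:
            s = stats[key]
            label = ("Cdt1-release -> MO-onset lag" if key == "fig6c"
                     else "MO end after 2nd Mcm2-7")
            val = s.get("mean_cdt1_to_mo_s", s.get("mean_mo_end_lag_s"))
            lines.append(f"{label}: {val:.1f} +- {s['se']:.1f} s (n={s['n']})")
    for key in ("fig2d", "fig3d"):
        if key in stats:
            s = stats[key]
            parts = [f"{p}: {d['k']}" for p, d in s["profiles"].items()]
            lines.append(f"FRET profiles (n={s['n']}): " + ", ".join(parts))
    if "orc_usage" in stats:
        s = stats["orc_usage"]
        parts = [f"{c}: {d['k']}" for c, d in s["classes"].items()]
        lines.append(f"ORC usage (n={s['n']}): " + ", ".join(parts))
    return "\n".join(lines)


def run_experiment(config: RunConfig, out_dir: Optional[Path] = None):
    """simulate -> analyze -> statistics in one call.

    Returns (traceset, analyses, events, stats).
    """
    ts = cmd_simulate(config, out_dir=out_dir)
    analyses, events = cmd_analyze(ts, config)
    stats = compute_statistics(events, analyses, config)
    if out_dir is not None:
        out = Path(out_dir)
        events_table(events).to_csv(out / "events.csv", index=False)
        intervals_table(analyses).to_csv(out / "intervals.csv", index=False)
        (out / "stats.json").write_text(json.dumps(stats, indent=2))
        (out / "report.txt").write_text(cmd_report(stats, events))
    return ts, analyses, events, stats


def intervals_table(analyses: Sequence[TraceAnalysis]):
    """The "intervals table": every detected presence / high-FRET interval
    and step, one row each (dna_id, kind, t_start_s, t_end_s, censored,
    magnitude)."""
    import pandas as pd

    rows = []
    for an in analyses:
        for group, kind in ((an.donor_intervals, "donor_presence"),
                            (an.acceptor_intervals, "acceptor_presence"),
                            (an.fret_intervals, "fret_high")):
            for iv in group:
                rows.append((an.dna_id, kind, iv.t_start, iv.t_end,
                             iv.right_censored, ""))
        for s in an.acceptor_steps + an.donor_steps:
            rows.append((an.dna_id, f"step_{s.classification}",
                         s.time_s, "", "", s.magnitude))
    return pd.DataFrame(rows, columns=[
        "dna_id", "kind", "t_start_s", "t_end_s", "censored", "magnitude"])


def events_table(events: Sequence[EventRecord]):
    """Events as a flat table (CSV-exportable)."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append({
            "dna_id": e.dna_id,
            "t_m1": e.t_m1,
            "t_m2": e.t_m2,
            "retention_1": e.retention_1 if e.retention_1 is not None else "",
            "retention_2": e.retention_2 if e.retention_2 is not None else "",
            "success": e.success,
            "orc_count_class": e.orc_count_class,
            "om1_start": e.om1.t_start if e.om1 else "",
            "om1_end": e.om1.t_end if e.om1 else "",
            "om2_start": e.om2.t_start if e.om2 else "",
            "om2_end": e.om2.t_end if e.om2 else "",
            "mo_start": e.mo.t_start if e.mo else "",
            "mo_end": e.mo.t_end if e.mo else "",
            "n_cdt1_releases": len(e.cdt1_release_times),
            "fret_profile": e.fret_profile,
            "inferred_type": e.inferred_type,
        })
    return pd.DataFrame(rows)
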