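"""Seeded synthetic datasets with known ground truth for every analysis
stage: ODE-backed transfer-assay fluorescence traces (with injection
segments and equilibrium-reference companions), competition curves, melt
curves, and saturation-binding curves.

Every generator is deterministic under its seed and returns the planted
parameters in a ``truth`` dict; file-writing entry points store that dict
as a ``truth.json`` sidecar next to the data.

The noise model is additive Gaussian on the measured signal with a
standard deviation expressed as a fraction of the curve's dynamic range
(default 1%).  Liposome-injection events carry two-sample spike
transients, emulating the mixing artefacts that the reference-averaging
windows are designed to trim; no drift or photobleaching is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .binding import TitrationCurve, boltzmann, hyperbolic_displacement, saturation_fold
from .kinetics import SimulationConfig, simulate
from .traces import FluorescenceTrace, max_transfer_uM

__all__ = [
    "GeneratorSpec",
    "gen_transfer_assay",
    "gen_competition",
    "gen_melt",
    "gen_saturation",
    "write_dataset",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed, noise level (fraction of dynamic range) and trace sampling
    interval shared by all generators."""

    seed: int = 0
    noise_sd_fraction: float = 0.01
    sampling_s: float = 0.5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _add_event_transients(f: np.ndarray, time_s: np.ndarray, event_times,
                          amplitude: float) -> None:
    """Two-sample spike right after each event time (in place)."""
    for te in event_times:
        idx = np.where(time_s > te)[0][:2]
        f[idx] += amplitude


def gen_transfer_assay(
    spec: GeneratorSpec,
    sim_config: SimulationConfig | None = None,
    assay_kind: str = "ps2pop",
    target_initial_rate: float | None = None,
    f0: float = 100.0,
    f_eq: float = 400.0,
    f0_eq: float = 95.0,
):
    """Generate an assay trace and its equilibrium-reference companion.

    The transferred-lipid course comes from the kinetic model
    (``sim_config``, defaulting to the standard non-exchange condition)
    unless ``target_initial_rate`` is given, in which case a saturating
    exponential course is scaled so that the eight-point initial-velocity
    estimator applied to the noiseless curve returns exactly that rate
    (lipids min^-1 per protein).  The course is mapped to fluorescence by
    inverting the assay normalization with the chosen reference levels,
    baseline segments and injection events are prepended, and seeded
    Gaussian noise is added.

    Returns ``(trace, eq_trace, truth)``.
    """
    if assay_kind not in ("ps2pop", "pi4p2pop", "ps3pop"):
        raise ValueError(f"unknown assay kind {assay_kind!r}")
    rng = spec.rng()
    dt = spec.sampling_s
    max_transfer = max_transfer_uM()
    quench = assay_kind == "ps3pop"
    if quench and f_eq > f0:
        f0, f_eq = 400.0, 100.0

    if sim_config is None:
        sim_config = SimulationConfig()
    protein = sim_config.initial_state.total_protein

    # transferred-lipid time course x(t) on the sampling grid
    t_course = np.arange(0.0, 600.0 + dt / 2, dt)
    if target_initial_rate is None:
        cfg = replace(sim_config, t_end=float(t_course[-1]), t_step=dt)
        traj = simulate(cfg)
        x = traj.species("ps_b" if assay_kind != "pi4p2pop" else "pi4p_a").copy()
        planted_rate = _eight_point_rate(t_course, x, protein)
    else:
        slope = target_initial_rate * protein / 60.0  # uM/s
        tau = max(10.0, min(300.0, 0.9 * max_transfer / max(slope, 1e-12)))
        shape = 1.0 - np.exp(-t_course / tau)
        trial = _eight_point_rate(t_course, shape, protein)
        x = shape * (target_initial_rate / trial)
        planted_rate = target_initial_rate

    # assay trace: baseline, liposome injection(s), protein, transfer course
    if assay_kind == "ps3pop":
        events = [("liposome_b", 60.0), ("liposome_c", 180.0), ("protein", 300.0)]
    else:
        events = [("liposome_b", 60.0), ("protein", 240.0)]
    t_prot = events[-1][1]
    t_pre = np.arange(0.0, t_prot, dt)
    denom = f_eq - (f0 if assay_kind != "ps2pop" else f0_eq)
    f_pre = np.full(t_pre.size, f0, dtype=float)
    f_pre[t_pre < events[0][1]] = f0 * 0.98
    f_course = f0 + denom * x / max_transfer
    time_s = np.concatenate([t_pre, t_prot + t_course])
    f = np.concatenate([f_pre, f_course])
    dyn = abs(f_eq - f0)
    _add_event_transients(f, time_s, [t for lab, t in events[:-1]], 0.05 * dyn)
    f += rng.normal(0.0, spec.noise_sd_fraction * dyn, size=f.size)
    trace = FluorescenceTrace(
        time_s=time_s, f=f, events=events,
        channel="NBD-C2Lact" if assay_kind != "pi4p2pop" else "NBD-PHFAPP",
        direction="quench" if quench else "dequench",
    )

    # equilibrium-reference companion
    if assay_kind == "ps3pop":
        eq_events = [("liposome_b", 60.0), ("liposome_c", 120.0)]
        t_eq = np.arange(0.0, 120.0 + 1300.0, dt)
        f_eq_trace = np.where(t_eq < 120.0, f0, f_eq).astype(float)
    else:
        eq_events = [("liposome_b", 60.0)]
        t_eq = np.arange(0.0, 300.0, dt)
        f_eq_trace = np.where(t_eq < 60.0, f0_eq, f_eq).astype(float)
    _add_event_transients(f_eq_trace, t_eq, [t for _, t in eq_events], 0.05 * dyn)
    f_eq_trace += rng.normal(0.0, spec.noise_sd_fraction * dyn,
                             size=f_eq_trace.size)
    eq_trace = FluorescenceTrace(time_s=t_eq, f=f_eq_trace, events=eq_events,
                                 direction=trace.direction)

    truth = {
        "initial_rate": float(planted_rate),
        "protein_uM": float(protein),
        "f0": float(f0),
        "f_eq": float(f_eq),
        "f0_eq": float(f0_eq if assay_kind == "ps2pop" else f0),
        "max_transfer_uM": float(max_transfer),
        "assay_kind": assay_kind,
        "seed": spec.seed,
        "noise_sd_fraction": spec.noise_sd_fraction,
    }
    return trace, eq_trace, truth


def _eight_point_rate(t: np.ndarray, x: np.ndarray, protein: float) -> float:
    """The experimental estimator (linear fit of the first eight samples)
    applied to a noiseless course."""
    slope = np.polyfit(t[:8], x[:8], 1)[0]
    return float(slope * 60.0 / protein)


def gen_competition(
    spec: GeneratorSpec,
    l50: float = 0.2,
    f_min: float = 0.75,
    f_max: float = 0.97,
    x_max: float = 1.25,
    n_points: int = 11,
    displacement: bool = True,
):
    """Hyperbolic competition-displacement curve on the 0-1.25 uM
    accessible-competitor grid of the titration protocol.  With
    ``displacement=False`` the curve stays flat at ``f_min`` (a
    non-binding competitor).  Returns ``(curve, truth)``."""

    rng = spec.rng()
    x = np.linspace(0.0, x_max, n_points)
    y = (hyperbolic_displacement(x, f_min, f_max, l50) if displacement
         else np.full_like(x, f_min))
    y = y + rng.normal(0.0, spec.noise_sd_fraction * abs(f_max - f_min), x.size)
    curve = TitrationCurve(x=x, y=y, kind="competition")
    truth = {"l50": float(l50) if displacement else None,
             "f_min": f_min, "f_max": f_max, "seed": spec.seed,
             "noise_sd_fraction": spec.noise_sd_fraction}
    return curve, truth


def gen_melt(
    spec: GeneratorSpec,
    t_m: float = 52.0,
    slope: float = 2.0,
    f_native: float = 1000.0,
    f_denatured: float = 5000.0,
    t_min: float = 25.0,
    t_max: float = 95.0,
    step: float = 1.0,
    replicates: int = 1,
):
    """Boltzmann melt curve(s) on the 25-95 degC, 1 degC scan grid.
    Returns ``(curve, truth)``; with ``replicates > 1`` the curve carries
    a ``replicate_id`` column and per-replicate gain jitter."""

    rng = spec.rng()
    t = np.arange(t_min, t_max + step / 2, step)
    xs, ys, ids = [], [], []
    for r in range(replicates):
        gain = 1.0 if replicates == 1 else float(rng.normal(1.0, 0.05))
        y = gain * boltzmann(t, f_native, f_denatured, t_m, slope)
        y += rng.normal(0.0, spec.noise_sd_fraction * gain
                        * abs(f_denatured - f_native), t.size)
        xs.append(t)
        ys.append(y)
        ids.append(np.full(t.size, r))
    curve = TitrationCurve(
        x=np.concatenate(xs), y=np.concatenate(ys), kind="melt",
        replicate_id=(np.concatenate(ids) if replicates > 1 else None),
    )
    truth = {"t_m": float(t_m), "slope": float(slope), "f_native": f_native,
             "f_denatured": f_denatured, "replicates": replicates,
             "seed": spec.seed, "noise_sd_fraction": spec.noise_sd_fraction}
    return curve, truth


def gen_saturation(
    spec: GeneratorSpec,
    k: float = 40.0,
    fold_change: float = 2.2,
    y0: float = 1.0,
    x_max: float = 300.0,
    n_points: int = 13,
):
    """Saturation membrane-binding curve on a 0-300 uM total-lipid grid.
    ``fold_change = 1`` plants a non-binding (flat) curve.  Returns
    ``(curve, truth)``."""

    rng = spec.rng()
    x = np.linspace(0.0, x_max, n_points)
    y = saturation_fold(x, y0, fold_change, k)
    dyn = max(abs(y0 * (fold_change - 1.0)), 0.1 * y0)
    y = y + rng.normal(0.0, spec.noise_sd_fraction * dyn, x.size)
    curve = TitrationCurve(x=x, y=y, kind="saturation")
    truth = {"k": float(k), "fold_change": float(fold_change), "y0": y0,
             "seed": spec.seed, "noise_sd_fraction": spec.noise_sd_fraction}
    return curve, truth


def write_dataset(out_dir, kind: str, spec: GeneratorSpec, **kwargs) -> dict:
    """Generate one dataset and write it (CSV dialects matching the
    analysis readers) plus its ``truth.json`` sidecar under ``out_dir``."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "transfer":
        trace, eq_trace, truth = gen_transfer_assay(spec, **kwargs)
        _io.write_trace_csv(trace, out / "trace.csv", out / "events.csv")
        _io.write_trace_csv(eq_trace, out / "eq_trace.csv", out / "eq_events.csv")
    elif kind in ("competition", "melt", "saturation"):
        gen = {"competition": gen_competition, "melt": gen_melt,
               "saturation": gen_saturation}[kind]
        curve, truth = gen(spec, **kwargs)
        _io.write_titration_csv(curve, out / "curve.csv")
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
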