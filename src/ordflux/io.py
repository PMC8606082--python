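"""Readers and writers for the package's CSV/YAML/JSON interfaces.

All writers are deterministic: fixed column order, fixed float format,
no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import TitrationCurve
from .kinetics import (
    ExchangeState,
    RateConstants,
    SimulationConfig,
    SweepResult,
    Trajectory,
)
from .traces import FluorescenceTrace

__all__ = [
    "load_sim_config",
    "write_trajectory_csv",
    "write_sweep_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_titration_csv",
    "write_titration_csv",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def load_sim_config(path) -> SimulationConfig:
    """Load a model/run configuration from YAML or JSON.

    Recognised keys: ``rates{...}``, ``initial{...}``,
    ``membranes{m_a_uM, m_b_uM}``, and
    ``sim{t_end_s, t_step_s, rate_window_s, rel_tol, abs_tol}``; absent
    keys fall back to the package defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    rates = RateConstants(**data.get("rates", {}))
    membranes = data.get("membranes", {})
    initial = dict(data.get("initial", {}))
    initial.setdefault("m_a", membranes.get("m_a_uM", 100.0))
    initial.setdefault("m_b", membranes.get("m_b_uM", 100.0))
    state = ExchangeState(**initial)
    sim = data.get("sim", {})
    kwargs = {}
    for src, dst in (("t_end_s", "t_end"), ("t_step_s", "t_step"),
                     ("rate_window_s", "rate_window"),
                     ("rel_tol", "solver_rel_tol"), ("abs_tol", "solver_abs_tol")):
        if src in sim:
            kwargs[dst] = sim[src]
    return SimulationConfig(rates=rates, initial_state=state, **kwargs)


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    trajectory.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_sweep_csv(sweep_result: SweepResult, path) -> None:
    sweep_result.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trace_csv(trace: FluorescenceTrace, path, events_path=None) -> None:
    pd.DataFrame({"time_s": trace.time_s, "fluorescence": trace.f}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    if events_path is not None:
        pd.DataFrame(trace.events, columns=["label", "time_s"]).to_csv(
            events_path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(path, events_path=None, channel: str = "NBD-C2Lact",
                   direction: str = "dequench") -> FluorescenceTrace:
    """Read a trace CSV (columns ``time_s, fluorescence``) plus an
    optional sidecar events CSV (columns ``label, time_s``)."""
    df = pd.read_csv(path)
    events = []
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = [(str(r.label), float(r.time_s)) for r in ev.itertuples()]
    return FluorescenceTrace(
        time_s=df["time_s"].to_numpy(dtype=float),
        f=df["fluorescence"].to_numpy(dtype=float),
        events=events, channel=channel, direction=direction,
    )


def write_titration_csv(curve: TitrationCurve, path) -> None:
    cols = {"x": curve.x, "y": curve.y}
    if curve.replicate_id is not None:
        cols["replicate_id"] = curve.replicate_id
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_titration_csv(path, kind: str) -> TitrationCurve:
    df = pd.read_csv(path)
    rep = (df["replicate_id"].to_numpy()
           if "replicate_id" in df.columns else None)
    return TitrationCurve(x=df["x"].to_numpy(dtype=float),
                          y=df["y"].to_numpy(dtype=float),
                          kind=kind, replicate_id=rep)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
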