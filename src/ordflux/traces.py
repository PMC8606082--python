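"""Normalization of FRET-assay fluorescence traces into transferred-lipid
time courses and initial velocities.

A transfer assay records the NBD signal of a lipid sensor while liposome
populations and then the transfer protein are injected into the cuvette.
The raw signal F is mapped to an absolute amount of transferred lipid by

    transferred = max_transfer * (F - F0) / (F_Eq - F0_Eq)

where F0 is the baseline between the last liposome injection and the
protein injection, and F_Eq/F0_Eq come from a separately recorded
equilibrium-calibration sample in which the ligand is pre-distributed
between both liposome populations.  ``max_transfer`` is the amount of
accessible ligand that moves at full equilibration (2.5 uM for the
standard geometry: 5% ligand, outer leaflet = half, 200 uM lipid per
population).

The initial velocity is the linear slope over the first eight samples
(4 s at 0.5 s sampling) after protein injection, per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "NormalizationRefs",
    "TransferKinetics",
    "MissingEventError",
    "DegenerateCalibrationError",
    "EVENT_TRIM",
    "compute_refs",
    "normalize",
    "initial_velocity",
    "three_liposome_normalize",
    "max_transfer_uM",
]

#: samples discarded on each side of an injection event when averaging,
#: to avoid mixing/injection transients
EVENT_TRIM = 2


class MissingEventError(ValueError):
    """A required injection event is absent from the trace."""


class DegenerateCalibrationError(ValueError):
    """F_Eq - F0_Eq is too small to normalize against."""


@dataclass
class FluorescenceTrace:
    """Raw assay recording with injection-event markers.

    ``events`` is an ordered list of ``(label, time_s)`` pairs; labels
    used by the assays are ``"liposome_b"``, ``"liposome_c"`` and
    ``"protein"``.  ``direction`` states whether transfer raises
    ("dequench") or lowers ("quench") the signal.
    """

    time_s: np.ndarray
    f: np.ndarray
    events: list = field(default_factory=list)
    channel: str = "NBD-C2Lact"
    direction: str = "dequench"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.f.shape:
            raise ValueError("time_s and f must be 1-D arrays of equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if self.direction not in ("dequench", "quench"):
            raise ValueError("direction must be 'dequench' or 'quench'")
        for label, t in self.events:
            if not (self.time_s[0] <= t <= self.time_s[-1]):
                raise ValueError(f"event {label!r} at {t} s outside trace span")

    def event_time(self, label: str) -> float:
        for lab, t in self.events:
            if lab == label:
                return float(t)
        raise MissingEventError(f"required event {label!r} not found in trace")

    def has_event(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.events)

    def segment_mean(self, t_start: float, t_stop: float,
                     trim: int = EVENT_TRIM) -> float:
        """Mean fluorescence strictly between two times, with ``trim``
        samples discarded next to each bound."""
        idx = np.where((self.time_s > t_start) & (self.time_s < t_stop))[0]
        if trim:
            idx = idx[trim:len(idx) - trim] if len(idx) > 2 * trim else idx[:0]
        if idx.size == 0:
            raise ValueError(
                f"no usable samples between {t_start} s and {t_stop} s after trimming"
            )
        return float(self.f[idx].mean())


@dataclass
class NormalizationRefs:
    """Reference levels mapping fluorescence to transferred lipid."""

    f0: float
    f_eq: float
    f0_eq: float
    max_transfer_uM: float

    def __post_init__(self):
        if self.max_transfer_uM <= 0:
            raise ValueError("max_transfer_uM must be > 0")
        if self.f_eq == self.f0_eq:
            raise DegenerateCalibrationError("f_eq equals f0_eq")


@dataclass
class TransferKinetics:
    """Normalized transferred-lipid time course, time-zeroed at the
    protein injection."""

    time_s: np.ndarray
    transferred_uM: np.ndarray
    lipid: str = "PS"
    initial_rate: float | None = None


def max_transfer_uM(total_uM: float = 200.0, fraction: float = 0.05,
                    leaflet_share: float = 0.5) -> float:
    """Maximum transferable ligand (uM): at equilibrium half of the
    accessible (outer-leaflet) ligand of the donor population has moved
    to the acceptor."""
    from .binding import accessible_lipid

    return accessible_lipid(total_uM, fraction, leaflet_share) / 2.0


def compute_refs(
    trace: FluorescenceTrace,
    eq_trace: FluorescenceTrace,
    assay_kind: str = "ps2pop",
    max_transfer: float | None = None,
) -> NormalizationRefs:
    """Extract F0, F_Eq and F0_Eq from an assay trace and its
    equilibrium-calibration companion.

    ``assay_kind``:

    * ``"ps2pop"`` -- two-population PS assay.  F0 averages the assay
      trace between the liposome-B and protein injections; F0_Eq is the
      equilibrium sample's own baseline before its liposome-B addition.
    * ``"pi4p2pop"`` -- two-population PI(4)P (or PI(4,5)P2) assay; the
      normalization denominator uses F_Eq - F0, so F0_Eq is set to F0.
    * ``"ps3pop"`` -- three-population routing assay; F0 averages after
      the liposome-C injection, F0_Eq = F0, and F_Eq is averaged over a
      5-min window starting 15 min after the equilibrium sample's last
      liposome addition.
    """
    if assay_kind not in ("ps2pop", "pi4p2pop", "ps3pop"):
        raise ValueError(f"unknown assay kind {assay_kind!r}")
    if max_transfer is None:
        max_transfer = max_transfer_uM()

    t_prot = trace.event_time("protein")
    last_lipo = "liposome_c" if assay_kind == "ps3pop" else "liposome_b"
    t_lipo = trace.event_time(last_lipo)
    f0 = trace.segment_mean(t_lipo, t_prot)

    if assay_kind == "ps3pop":
        t_c = eq_trace.event_time("liposome_c")
        t_hi = min(t_c + 1200.0, float(eq_trace.time_s[-1]))
        f_eq = eq_trace.segment_mean(t_c + 900.0, t_hi, trim=0)
        f0_eq = f0
    else:
        t_b = eq_trace.event_time("liposome_b")
        f_eq = eq_trace.segment_mean(t_b, float(eq_trace.time_s[-1]) + 1e-9)
        if assay_kind == "ps2pop":
            f0_eq = eq_trace.segment_mean(float(eq_trace.time_s[0]) - 1e-9, t_b)
        else:
            f0_eq = f0

    return NormalizationRefs(f0=f0, f_eq=f_eq, f0_eq=f0_eq,
                             max_transfer_uM=max_transfer)


def normalize(trace: FluorescenceTrace, refs: NormalizationRefs,
              lipid: str = "PS") -> TransferKinetics:
    """Map a trace to a transferred-lipid time course.

    The trace is truncated to start at the protein injection (inclusive,
    which sets time zero).  The same formula serves quench-direction
    traces, where f_eq < f0 makes the numerator and denominator change
    sign together.  Negative values from noise are retained.
    """
    denom = refs.f_eq - refs.f0_eq
    if abs(denom) < 1e-6 * abs(refs.f0):
        raise DegenerateCalibrationError(
            f"|f_eq - f0_eq| = {abs(denom):g} is below the relative floor"
        )
    t_prot = trace.event_time("protein")
    mask = trace.time_s >= t_prot - 1e-9
    t = trace.time_s[mask] - t_prot
    transferred = refs.max_transfer_uM * (trace.f[mask] - refs.f0) / denom
    return TransferKinetics(time_s=t, transferred_uM=transferred, lipid=lipid)


def initial_velocity(kinetics: TransferKinetics, protein_uM: float,
                     n_points: int = 8) -> float:
    """Initial transfer velocity (lipids min^-1 per protein): linear
    least-squares slope over the first ``n_points`` samples (the first
    4 s at the nominal 0.5 s sampling)."""
    if protein_uM <= 0:
        raise ValueError("protein_uM must be > 0")
    if kinetics.time_s.size < n_points:
        raise ValueError(
            f"kinetics has {kinetics.time_s.size} samples, needs >= {n_points}"
        )
    t = kinetics.time_s[:n_points]
    x = kinetics.transferred_uM[:n_points]
    slope = np.polyfit(t, x, 1)[0]
    rate = slope * 60.0 / protein_uM
    kinetics.initial_rate = float(rate)
    return float(rate)


def three_liposome_normalize(trace: FluorescenceTrace,
                             refs: NormalizationRefs) -> TransferKinetics:
    """Normalize a three-population routing trace (quench direction).

    Requires ``liposome_b``, ``liposome_c`` and ``protein`` events; the
    normalization denominator is F_Eq - F0 (three-population convention,
    already reflected in ``refs`` built with ``assay_kind="ps3pop"``).
    """
    for label in ("liposome_b", "liposome_c", "protein"):
        if not trace.has_event(label):
            raise MissingEventError(f"required event {label!r} not found in trace")
    return normalize(trace, refs, lipid="PS")
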