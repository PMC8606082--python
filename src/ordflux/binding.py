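"""Titration-curve fits: competition binding ([L]50), thermal-shift
melting temperature (Boltzmann T_m), and saturation membrane binding.

The competition readout is the tryptophan fluorescence of the protein,
quenched while its pocket holds NBD-PS and restored as unlabelled
competitor lipid displaces the probe.  The displacement is modelled as a
single-site hyperbola in accessible competitor concentration,

    y(x) = f_min + (f_max - f_min) * x / (l50 + x),

so [L]50 is an operational half-displacement concentration (probe and
competitor are at comparable concentrations, so no Cheng-Prusoff
conversion to a Ki is attempted); 1/[L]50 serves as the relative
affinity proxy.

Melt curves follow the Boltzmann sigmoid

    y(T) = f_native + (f_denatured - f_native) / (1 + exp((t_m - T)/slope)),

and saturation binding the fold-change hyperbola

    y(x) = y0 * (1 + (a - 1) * x / (k + x)).

All fits are plain least squares (via lmfit) and therefore equivariant
under positive rescaling of y: plateau parameters scale, the location
parameters (l50, t_m, k) do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model, Parameters, minimize

__all__ = [
    "TitrationCurve",
    "CompetitionFit",
    "MeltFit",
    "SaturationFit",
    "accessible_lipid",
    "fit_competition",
    "fit_melt",
    "fit_saturation",
    "rate_affinity_table",
    "hyperbolic_displacement",
    "boltzmann",
    "saturation_fold",
]


def accessible_lipid(total_uM: float, fraction: float,
                     leaflet_share: float = 0.5) -> float:
    """Accessible (outer-leaflet) concentration of a lipid species:
    total lipid x molar fraction x leaflet share.

    E.g. 100 uM total lipid at 2% labelled lipid gives 1 uM accessible
    labelled lipid.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be within [0, 1], got {fraction}")
    if not 0.0 <= leaflet_share <= 1.0:
        raise ValueError(f"leaflet_share must be within [0, 1], got {leaflet_share}")
    if total_uM < 0:
        raise ValueError("total_uM must be >= 0")
    return total_uM * fraction * leaflet_share


def hyperbolic_displacement(x, f_min, f_max, l50):
    return f_min + (f_max - f_min) * x / (l50 + x)


def boltzmann(x, f_native, f_denatured, t_m, slope):
    return f_native + (f_denatured - f_native) / (1.0 + np.exp((t_m - x) / slope))


def saturation_fold(x, y0, a, k):
    return y0 * (1.0 + (a - 1.0) * x / (k + x))


@dataclass
class TitrationCurve:
    """Concentration-response (or temperature-response) table.

    ``x`` is accessible lipid (uM) for competition/saturation curves and
    temperature (degC) for melts; ``y`` is the normalized or raw
    fluorescence.  ``replicate_id`` marks replicate membership for joint
    fitting.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "competition"
    replicate_id: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.kind not in ("competition", "melt", "saturation"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.x.shape:
                raise ValueError("replicate_id must match x in length")
        ids = ([None] if self.replicate_id is None
               else np.unique(self.replicate_id))
        for rid in ids:
            xs = self.x if rid is None else self.x[self.replicate_id == rid]
            if xs.size >= 2 and not np.all(np.diff(xs) > 0):
                raise ValueError("x must be strictly increasing within a replicate")
        if self.kind == "competition" and self.x.min() != 0.0:
            raise ValueError("competition curves must start at x = 0")
        if self.kind == "melt" and np.ptp(self.x) < 20.0:
            raise ValueError("melt curves must span at least 20 degC")

    def replicates(self):
        """Yield (id, x, y) per replicate (a single anonymous replicate
        when no ids are present)."""
        if self.replicate_id is None:
            yield None, self.x, self.y
        else:
            for rid in np.unique(self.replicate_id):
                m = self.replicate_id == rid
                yield rid, self.x[m], self.y[m]


@dataclass
class CompetitionFit:
    l50: float
    f_min: float
    f_max: float
    l50_stderr: float | None = None
    flag: str | None = None
    residual_sd: float = 0.0

    @property
    def inv_l50(self) -> float:
        return 1.0 / self.l50 if np.isfinite(self.l50) and self.l50 > 0 else np.nan

    @property
    def determinable(self) -> bool:
        return self.flag is None


@dataclass
class MeltFit:
    t_m: float
    slope: float
    f_native: float
    f_denatured: float
    t_m_stderr: float | None = None
    flag: str | None = None

    @property
    def determinable(self) -> bool:
        return self.flag is None


@dataclass
class SaturationFit:
    k: float
    fold_change: float
    y0: float
    flag: str | None = None

    @property
    def determinable(self) -> bool:
        return self.flag is None


def _joint_fit(curve: TitrationCurve, model_fn, shared: dict, per_rep: dict):
    """Least-squares fit with shape parameters shared across replicates
    and plateau/gain parameters free per replicate."""
    reps = list(curve.replicates())
    params = Parameters()
    for name, (value, minval) in shared.items():
        params.add(name, value=value, min=minval)
    for i, _ in enumerate(reps):
        for name, value in per_rep.items():
            params.add(f"{name}_{i}", value=value[i])

    def residual(p):
        out = []
        for i, (_, x, y) in enumerate(reps):
            kw = {name: p[name].value for name in shared}
            kw.update({name: p[f"{name}_{i}"].value for name in per_rep})
            out.append(model_fn(x, **kw) - y)
        return np.concatenate(out)

    return minimize(residual, params), reps


def fit_competition(curve: TitrationCurve) -> CompetitionFit:
    """Fit the hyperbolic displacement model and return [L]50.

    When the fitted dynamic range does not exceed three times the
    residual noise the curve is flagged ``no-displacement`` and l50 is
    reported as NaN (not determinable), the behaviour expected for
    ligands that barely bind.
    """
    if curve.kind != "competition":
        raise ValueError("curve.kind must be 'competition'")
    if curve.x.size < 5:
        raise ValueError("need at least 5 points to fit a competition curve")

    n_edge = max(2, curve.x.size // 10)
    f_min0 = float(np.mean(curve.y[:n_edge]))
    f_max0 = float(np.mean(curve.y[-n_edge:]))
    half = (f_min0 + f_max0) / 2.0
    l50_0 = float(curve.x[np.argmin(np.abs(curve.y - half))])
    l50_0 = max(l50_0, curve.x[curve.x > 0].min() / 2.0)

    try:
        res, reps = _joint_fit(
            curve, hyperbolic_displacement,
            shared={"l50": (l50_0, 1e-9)},
            per_rep={"f_min": [f_min0] * _n_reps(curve),
                     "f_max": [f_max0] * _n_reps(curve)},
        )
    except Exception:
        return CompetitionFit(np.nan, f_min0, f_max0, flag="fit-failed")

    p = res.params
    resid_sd = float(np.std(res.residual, ddof=min(res.nvarys, res.residual.size - 1)))
    f_min = float(np.mean([p[f"f_min_{i}"].value for i in range(len(reps))]))
    f_max = float(np.mean([p[f"f_max_{i}"].value for i in range(len(reps))]))
    fit = CompetitionFit(
        l50=float(p["l50"].value), f_min=f_min, f_max=f_max,
        l50_stderr=(float(p["l50"].stderr) if p["l50"].stderr else None),
        residual_sd=resid_sd,
    )
    # displacement actually resolved over the measured range, not the
    # extrapolated plateau difference
    span = abs(hyperbolic_displacement(curve.x.max(), f_min, f_max, fit.l50)
               - f_min)
    if not res.success or span < 3.0 * max(resid_sd, 1e-12):
        fit.flag = "no-displacement"
        fit.l50 = np.nan
    return fit


def fit_melt(curve: TitrationCurve) -> MeltFit:
    """Fit the Boltzmann unfolding sigmoid and return T_m.

    Non-sigmoidal data (fit failure, T_m at the scan edge, or a
    transition wider than a quarter of the scanned range) is flagged
    ``melt-fit-failure``.
    """
    if curve.kind != "melt":
        raise ValueError("curve.kind must be 'melt'")
    if curve.x.size < 15:
        raise ValueError("need at least 15 points to fit a melt curve")

    n_reps = _n_reps(curve)
    _, x0, y0 = next(curve.replicates())
    n_edge = max(2, x0.size // 10)
    f_nat0, f_den0 = float(np.mean(y0[:n_edge])), float(np.mean(y0[-n_edge:]))
    # steepest local slope locates the transition midpoint
    t_m0 = float(x0[:-1][np.argmax(np.abs(np.diff(y0)))])
    span = float(np.ptp(curve.x))

    try:
        res, reps = _joint_fit(
            curve, boltzmann,
            shared={"t_m": (t_m0, curve.x.min()), "slope": (2.0, 1e-6)},
            per_rep={"f_native": [f_nat0] * n_reps,
                     "f_denatured": [f_den0] * n_reps},
        )
    except Exception:
        return MeltFit(np.nan, np.nan, f_nat0, f_den0, flag="melt-fit-failure")

    p = res.params
    fit = MeltFit(
        t_m=float(p["t_m"].value), slope=float(p["slope"].value),
        f_native=float(np.mean([p[f"f_native_{i}"].value for i in range(len(reps))])),
        f_denatured=float(np.mean([p[f"f_denatured_{i}"].value
                                   for i in range(len(reps))])),
        t_m_stderr=(float(p["t_m"].stderr) if p["t_m"].stderr else None),
    )
    edge = 1.0  # one scan step from either end counts as "at the edge"
    if (not res.success
            or fit.t_m <= curve.x.min() + edge
            or fit.t_m >= curve.x.max() - edge
            or fit.slope > span / 4.0):
        fit.flag = "melt-fit-failure"
    return fit


def fit_saturation(curve: TitrationCurve) -> SaturationFit:
    """Fit the fold-change saturation hyperbola; returns the
    half-saturation concentration k and the amplitude fold-change a.

    An amplitude indistinguishable from noise (a ~ 1) is flagged
    ``no-binding``, as observed with liposomes the sensor cannot engage.
    """
    if curve.kind != "saturation":
        raise ValueError("curve.kind must be 'saturation'")
    if curve.x.size < 5:
        raise ValueError("need at least 5 points to fit a saturation curve")
    if curve.x.min() != 0.0:
        raise ValueError("saturation curves must include x = 0")

    y0_0 = float(curve.y[np.argmin(curve.x)])
    a0 = float(curve.y.max() / y0_0) if y0_0 != 0 else 2.0
    k0 = float(np.median(curve.x[curve.x > 0]))

    model = Model(saturation_fold)
    params = model.make_params(y0=y0_0, a=max(a0, 1.01), k=k0)
    params["k"].set(min=1e-9)
    params["y0"].set(min=1e-12)
    try:
        res = model.fit(curve.y, params, x=curve.x)
    except Exception:
        return SaturationFit(np.nan, np.nan, y0_0, flag="fit-failed")

    y0_f = float(res.params["y0"].value)
    a_f = float(res.params["a"].value)
    k_f = float(res.params["k"].value)
    resid_sd = float(np.std(res.residual))
    fit = SaturationFit(k=k_f, fold_change=a_f, y0=y0_f)
    if not res.success or abs(a_f - 1.0) * y0_f < 3.0 * max(resid_sd, 1e-12):
        fit.flag = "no-binding"
    return fit


def rate_affinity_table(rates: dict, fits: dict) -> tuple[pd.DataFrame, float]:
    """Pair per-species transfer rates with competition-fit affinities.

    Inner join on species keys, sorted by 1/[L]50 ascending; returns the
    table and the Spearman rank correlation of rate versus 1/[L]50 (NaN
    with a warning when fewer than two species overlap).
    """
    common = sorted(set(rates) & set(fits))
    if not common:
        raise ValueError("rates and fits share no species keys")
    table = pd.DataFrame(
        {
            "species": common,
            "rate": [rates[s] for s in common],
            "inv_l50": [fits[s].inv_l50 for s in common],
        }
    ).sort_values("inv_l50", ignore_index=True)
    if len(common) < 2:
        warnings.warn("correlation undefined with a single shared species")
        return table, float("nan")
    from scipy.stats import spearmanr

    rho = spearmanr(table["rate"], table["inv_l50"]).statistic
    return table, float(rho)


def _n_reps(curve: TitrationCurve) -> int:
    return 1 if curve.replicate_id is None else len(np.unique(curve.replicate_id))
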