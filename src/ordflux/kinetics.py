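"""Mass-action kinetics of ORD-mediated lipid transfer and exchange.

The model describes a lipid transfer domain (ORD) shuttling PS and PI(4)P
between two membranes, A and B, through six reversible reactions:

    (1) O + M_A          <->  O-M_A            k_on_mb / k_off_mb
    (2) O + M_B          <->  O-M_B            k_on_mb / k_off_mb
    (3) O-M_A + PS_A     <->  O(PS)            k_on_ps / k_off_ps
    (4) O-M_B + PS_B     <->  O(PS)            k_on_ps / k_off_ps
    (5) O-M_A + PI4P_A   <->  O(PI4P)          k_on_pi4p / k_off_pi4p
    (6) O-M_B + PI4P_B   <->  O(PI4P)          k_on_pi4p / k_off_pi4p

``O`` is the empty soluble domain, ``O-M_A``/``O-M_B`` the empty domain
docked on either membrane, and ``O(PS)``/``O(PI4P)`` the soluble 1:1
lipid complexes.  The membranes ``M_A``/``M_B`` are boundary species: the
docking reactions (1)-(2) consume/release them, and the extraction
reactions (3)-(6) interconvert docked and soluble protein forms without a
membrane term, so [M_A] and [M_B] are held constant during integration
(the "fixed species" convention of biochemical simulators).

Concentrations are in uM, time in s, bimolecular rate constants in
uM^-1 s^-1, unimolecular ones in s^-1.  Transfer rates are reported as
lipids min^-1 per protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "ExchangeState",
    "SimulationConfig",
    "Trajectory",
    "SweepResult",
    "IntegrationError",
    "BoundaryMaximumWarning",
    "SPECIES",
    "build_rhs",
    "simulate",
    "initial_transfer_rate",
    "acceleration_factor",
    "sweep",
    "find_rate_maximum",
    "parametric_acceleration_curve",
    "nonexchange_state",
    "exchange_state",
]

#: order of the nine dynamic species in all state vectors
SPECIES = (
    "o_free", "o_ma", "o_mb", "o_ps", "o_pi4p",
    "ps_a", "ps_b", "pi4p_a", "pi4p_b",
)


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the offending parameter set."""

    def __init__(self, message: str, rates: "RateConstants | None" = None):
        super().__init__(message)
        self.rates = rates


class BoundaryMaximumWarning(UserWarning):
    """The sweep maximum sits on a grid boundary; no refinement possible."""


@dataclass(frozen=True)
class RateConstants:
    """The six kinetic parameters of the exchange scheme.

    Bimolecular constants (``k_on_*``, uM^-1 s^-1) and unimolecular ones
    (``k_off_*``, s^-1) are distinct quantities and must not be swapped.
    Defaults: membrane docking k_on_mb = 10 uM^-1 s^-1 with
    k_off_mb = 0.1 s^-1; lipid capture/release 10 uM^-1 s^-1 and 1 s^-1
    for both ligands.
    """

    k_on_mb: float = 10.0
    k_off_mb: float = 0.1
    k_on_ps: float = 10.0
    k_off_ps: float = 1.0
    k_on_pi4p: float = 10.0
    k_off_pi4p: float = 1.0

    def __post_init__(self):
        for name in (
            "k_on_mb", "k_off_mb", "k_on_ps", "k_off_ps",
            "k_on_pi4p", "k_off_pi4p",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    def swapped_ligands(self) -> "RateConstants":
        """Return the constants with PS and PI(4)P labels exchanged."""
        return RateConstants(
            k_on_mb=self.k_on_mb, k_off_mb=self.k_off_mb,
            k_on_ps=self.k_on_pi4p, k_off_ps=self.k_off_pi4p,
            k_on_pi4p=self.k_on_ps, k_off_pi4p=self.k_off_ps,
        )


@dataclass
class ExchangeState:
    """Concentrations (uM) of the nine dynamic species plus the two
    constant membrane boundary species ``m_a``/``m_b``."""

    o_free: float = 0.0
    o_ma: float = 0.0
    o_mb: float = 0.0
    o_ps: float = 0.0
    o_pi4p: float = 0.0
    ps_a: float = 0.0
    ps_b: float = 0.0
    pi4p_a: float = 0.0
    pi4p_b: float = 0.0
    m_a: float = 100.0
    m_b: float = 100.0

    def __post_init__(self):
        for name in SPECIES + ("m_a", "m_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, m_a: float, m_b: float) -> "ExchangeState":
        return cls(**dict(zip(SPECIES, np.maximum(y, 0.0))), m_a=m_a, m_b=m_b)

    @property
    def total_protein(self) -> float:
        return self.o_free + self.o_ma + self.o_mb + self.o_ps + self.o_pi4p

    @property
    def total_ps(self) -> float:
        return self.ps_a + self.ps_b + self.o_ps

    @property
    def total_pi4p(self) -> float:
        return self.pi4p_a + self.pi4p_b + self.o_pi4p

    def swapped_ligands(self) -> "ExchangeState":
        """Return the state with PS and PI(4)P pools exchanged."""
        return ExchangeState(
            o_free=self.o_free, o_ma=self.o_ma, o_mb=self.o_mb,
            o_ps=self.o_pi4p, o_pi4p=self.o_ps,
            ps_a=self.pi4p_a, ps_b=self.pi4p_b,
            pi4p_a=self.ps_a, pi4p_b=self.ps_b,
            m_a=self.m_a, m_b=self.m_b,
        )


def nonexchange_state(
    protein_uM: float = 0.2,
    ps_a_uM: float = 5.0,
    membrane_uM: float = 100.0,
) -> ExchangeState:
    """Initial state of the non-exchange transfer condition: soluble empty
    protein, PS only in membrane A, no counterligand."""
    return ExchangeState(o_free=protein_uM, ps_a=ps_a_uM,
                         m_a=membrane_uM, m_b=membrane_uM)


def exchange_state(
    protein_uM: float = 0.2,
    ps_a_uM: float = 5.0,
    pi4p_b_uM: float = 5.0,
    membrane_uM: float = 100.0,
) -> ExchangeState:
    """Initial state of the exchange condition: PS in membrane A and the
    PI(4)P counterligand in membrane B."""
    return ExchangeState(o_free=protein_uM, ps_a=ps_a_uM, pi4p_b=pi4p_b_uM,
                         m_a=membrane_uM, m_b=membrane_uM)


@dataclass
class SimulationConfig:
    """Run configuration: rate constants, initial state, output grid and
    the window over which the initial transfer rate is measured.

    The defaults (``t_step = rate_window = 0.6 s``) make the initial rate
    the average flux over the first output interval; see the methods note
    for how this estimator and the membrane-docking off-rate were fixed.
    """

    rates: RateConstants = field(default_factory=RateConstants)
    initial_state: ExchangeState = field(default_factory=nonexchange_state)
    t_end: float = 60.0
    t_step: float = 0.6
    rate_window: float = 0.6
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10

    def __post_init__(self):
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        if self.rate_window < self.t_step:
            raise ValueError("rate_window must be >= t_step")
        if self.solver_rel_tol <= 0 or self.solver_abs_tol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")


@dataclass
class Trajectory:
    """Integrated time course: ``time_s`` and one row per output time in
    ``y`` (columns ordered as :data:`SPECIES`)."""

    time_s: np.ndarray
    y: np.ndarray
    m_a: float
    m_b: float
    config: SimulationConfig

    def species(self, name: str) -> np.ndarray:
        return self.y[:, SPECIES.index(name)]

    def state_at(self, i: int) -> ExchangeState:
        return ExchangeState.from_array(self.y[i], self.m_a, self.m_b)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.time_s, **{s: self.y[:, j] for j, s in enumerate(SPECIES)}}
        )


def build_rhs(rates: RateConstants, m_a: float, m_b: float):
    """Return the mass-action right-hand side ``f(t, y) -> dy/dt`` for the
    nine dynamic species, with membranes clamped at ``m_a``/``m_b``.

    The reverse of the extraction reactions regenerates membrane-docked
    protein without a membrane term, so membrane pools never change.
    """
    k1, km1 = rates.k_on_mb, rates.k_off_mb
    k3, km3 = rates.k_on_ps, rates.k_off_ps
    k5, km5 = rates.k_on_pi4p, rates.k_off_pi4p

    def rhs(t, y):
        o, oma, omb, ops, opi, psa, psb, pia, pib = y
        r1 = k1 * o * m_a - km1 * oma
        r2 = k1 * o * m_b - km1 * omb
        r3 = k3 * oma * psa - km3 * ops
        r4 = k3 * omb * psb - km3 * ops
        r5 = k5 * oma * pia - km5 * opi
        r6 = k5 * omb * pib - km5 * opi
        return (
            -r1 - r2,                 # o_free
            r1 - r3 - r5,             # o_ma
            r2 - r4 - r6,             # o_mb
            r3 + r4,                  # o_ps
            r5 + r6,                  # o_pi4p
            -r3,                      # ps_a
            -r4,                      # ps_b
            -r5,                      # pi4p_a
            -r6,                      # pi4p_b
        )

    return rhs


def simulate(config: SimulationConfig) -> Trajectory:
    """Integrate the model on the config's output grid.

    Uses a stiff-capable implicit solver (LSODA); total protein and each
    total lipid are conserved to within solver tolerance.  Output
    concentrations are clipped at zero (negatives can only arise at the
    absolute-tolerance scale).
    """
    state = config.initial_state
    y0 = state.to_array()
    n = int(np.floor(config.t_end / config.t_step + 1e-9))
    t_eval = np.linspace(0.0, n * config.t_step, n + 1)
    if config.t_end == 0:
        return Trajectory(np.array([0.0]), y0[None, :].copy(),
                          state.m_a, state.m_b, config)
    rhs = build_rhs(config.rates, state.m_a, state.m_b)
    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), y0, method="LSODA", t_eval=t_eval,
        rtol=config.solver_rel_tol, atol=config.solver_abs_tol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed ({sol.message}) with rates {config.rates}",
            rates=config.rates,
        )
    y = sol.y.T
    y[y < 0] = 0.0
    return Trajectory(sol.t, y, state.m_a, state.m_b, config)


def initial_transfer_rate(
    trajectory: Trajectory,
    species: str = "ps_b",
    protein_total: float | None = None,
    window: float | None = None,
) -> float:
    """Initial transfer rate (lipids min^-1 per protein) of the tracked
    destination pool.

    Least-squares slope (uM/s) of ``species`` over [0, window], divided by
    the total protein concentration and converted to per-minute units.
    ``species`` is ``"ps_b"`` for A-to-B PS transfer and ``"pi4p_a"`` for
    B-to-A PI(4)P transfer.
    """
    if species not in ("ps_b", "pi4p_a"):
        raise ValueError("species must be 'ps_b' or 'pi4p_a'")
    if window is None:
        window = trajectory.config.rate_window
    if protein_total is None:
        protein_total = trajectory.state_at(0).total_protein
    if protein_total <= 0:
        raise ValueError("protein_total must be > 0")
    if window > trajectory.time_s[-1] + 1e-12:
        raise ValueError(
            f"rate window {window} s exceeds trajectory span {trajectory.time_s[-1]} s"
        )
    mask = trajectory.time_s <= window + 1e-9
    t = trajectory.time_s[mask]
    c = trajectory.species(species)[mask]
    if t.size < 2:
        raise ValueError("need at least two samples inside the rate window")
    slope = np.polyfit(t, c, 1)[0]
    return slope / protein_total * 60.0


def acceleration_factor(rate_exchange: float, rate_nonexchange: float) -> float:
    """log10 of the exchange-to-non-exchange rate ratio for one lipid."""
    if not (rate_exchange > 0 and rate_nonexchange > 0):
        raise ValueError(
            "acceleration factor undefined for non-positive rates "
            f"({rate_exchange}, {rate_nonexchange})"
        )
    return float(np.log10(rate_exchange / rate_nonexchange))


@dataclass
class SweepResult:
    """Initial transfer rates across a rate-constant grid.

    ``rate_ps_*`` track the A-to-B PS pool, ``rate_pi4p_*`` the B-to-A
    PI(4)P pool; ``accel_*`` are the per-point log10 exchange/non-exchange
    ratios (NaN where a rate was non-positive or an integration failed).
    """

    swept_parameter: str
    grid: np.ndarray
    rate_ps_nonexchange: np.ndarray
    rate_ps_exchange: np.ndarray
    rate_pi4p_nonexchange: np.ndarray
    rate_pi4p_exchange: np.ndarray
    accel_ps: np.ndarray
    accel_pi4p: np.ndarray
    base_config: SimulationConfig | None = None
    counterligand_uM: float = 5.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter_value": self.grid,
                "rate_ps_nonexchange": self.rate_ps_nonexchange,
                "rate_ps_exchange": self.rate_ps_exchange,
                "rate_pi4p_nonexchange": self.rate_pi4p_nonexchange,
                "rate_pi4p_exchange": self.rate_pi4p_exchange,
                "accel_ps": self.accel_ps,
                "accel_pi4p": self.accel_pi4p,
            }
        )


def _rate_config(base: SimulationConfig) -> SimulationConfig:
    """A copy of ``base`` integrating only over the rate window."""
    return replace(base, t_end=base.rate_window)


def _condition_rates(
    config: SimulationConfig, counterligand_uM: float
) -> tuple[float, float, float, float]:
    """PS and PI(4)P initial rates in non-exchange and exchange conditions.

    Three integrations: PS alone, PI(4)P alone, and the joint exchange run
    (from which both exchange rates are read).
    """
    base = config.initial_state
    protein = base.total_protein
    ps_a = base.total_ps if base.total_ps > 0 else 5.0
    m = base.m_a

    cfg = _rate_config(config)
    ps_only = replace(cfg, initial_state=nonexchange_state(protein, ps_a, m))
    pi_only = replace(
        cfg,
        initial_state=ExchangeState(o_free=protein, pi4p_b=counterligand_uM,
                                    m_a=m, m_b=base.m_b),
    )
    both = replace(cfg, initial_state=exchange_state(protein, ps_a, counterligand_uM, m))

    r_ps_non = initial_transfer_rate(simulate(ps_only), "ps_b", protein)
    r_pi_non = initial_transfer_rate(simulate(pi_only), "pi4p_a", protein)
    traj_both = simulate(both)
    r_ps_ex = initial_transfer_rate(traj_both, "ps_b", protein)
    r_pi_ex = initial_transfer_rate(traj_both, "pi4p_a", protein)
    return r_ps_non, r_ps_ex, r_pi_non, r_pi_ex


def _safe_accel(r_ex: float, r_non: float) -> float:
    try:
        return acceleration_factor(r_ex, r_non)
    except ValueError:
        warnings.warn("acceleration factor undefined (non-positive rate); "
                      "recorded as NaN")
        return float("nan")


def sweep(
    base_config: SimulationConfig,
    parameter: str,
    grid,
    exchange_counterligand: float = 5.0,
) -> SweepResult:
    """Sweep one rate constant, measuring PS and PI(4)P initial rates in
    non-exchange and exchange conditions at every grid value.

    A failed integration at a single point is recorded as NaN (with a
    warning) and the sweep continues.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if np.any(grid < 0):
        raise ValueError("grid values must be >= 0")
    if parameter not in RateConstants().__dict__:
        raise ValueError(f"unknown rate-constant name {parameter!r}")

    cols = {k: np.full(grid.size, np.nan) for k in
            ("ps_non", "ps_ex", "pi_non", "pi_ex")}
    for i, value in enumerate(grid):
        rates = replace(base_config.rates, **{parameter: value})
        cfg = replace(base_config, rates=rates)
        try:
            (cols["ps_non"][i], cols["ps_ex"][i],
             cols["pi_non"][i], cols["pi_ex"][i]) = _condition_rates(
                cfg, exchange_counterligand)
        except IntegrationError as err:
            warnings.warn(f"integration failed at {parameter}={value}: {err}")

    accel_ps = np.array([_safe_accel(e, n) for e, n in
                         zip(cols["ps_ex"], cols["ps_non"])])
    accel_pi = np.array([_safe_accel(e, n) for e, n in
                         zip(cols["pi_ex"], cols["pi_non"])])
    return SweepResult(
        swept_parameter=parameter,
        grid=grid,
        rate_ps_nonexchange=cols["ps_non"],
        rate_ps_exchange=cols["ps_ex"],
        rate_pi4p_nonexchange=cols["pi_non"],
        rate_pi4p_exchange=cols["pi_ex"],
        accel_ps=accel_ps,
        accel_pi4p=accel_pi,
        base_config=base_config,
        counterligand_uM=exchange_counterligand,
    )


def log_grid(start: float = 0.01, stop: float = 10_000.0,
             per_decade: int = 25) -> np.ndarray:
    """Log-spaced sweep grid, ``per_decade`` points per decade inclusive of
    both ends."""
    n = int(round(np.log10(stop / start) * per_decade)) + 1
    return np.logspace(np.log10(start), np.log10(stop), n)


def find_rate_maximum(
    sweep_result: SweepResult,
    which: str = "nonexchange",
    rel_tol: float = 0.01,
) -> float:
    """Locate the swept-parameter value maximising the tracked-lipid rate.

    The coarse grid argmax is refined by bounded scalar maximisation in
    log-parameter space, re-invoking the simulator, until the location is
    resolved to better than ``rel_tol`` relative.  A maximum on a grid
    boundary is returned as-is with :class:`BoundaryMaximumWarning`.
    """
    if which not in ("nonexchange", "exchange"):
        raise ValueError("which must be 'nonexchange' or 'exchange'")
    tracked = ("rate_ps_nonexchange" if which == "nonexchange"
               else "rate_ps_exchange")
    if sweep_result.swept_parameter in ("k_on_pi4p", "k_off_pi4p"):
        tracked = tracked.replace("ps", "pi4p")
    rates = getattr(sweep_result, tracked)
    finite = np.isfinite(rates)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite rates to locate a maximum")
    idx = int(np.nanargmax(rates))
    if idx == 0 or idx == rates.size - 1:
        warnings.warn("maximum lies on the grid boundary; returning it "
                      "without refinement", BoundaryMaximumWarning)
        return float(sweep_result.grid[idx])
    if sweep_result.base_config is None:
        # no simulator to re-invoke: parabolic interpolation through the
        # three log-spaced points bracketing the grid argmax
        lg = np.log10(sweep_result.grid[idx - 1:idx + 2])
        r3 = rates[idx - 1:idx + 2]
        denom = (r3[0] - 2 * r3[1] + r3[2])
        if denom >= 0:
            return float(sweep_result.grid[idx])
        vertex = lg[1] - 0.5 * (lg[2] - lg[1]) * (r3[2] - r3[0]) / denom
        return float(10.0 ** vertex)

    from scipy.optimize import minimize_scalar

    lo, hi = np.log10(sweep_result.grid[idx - 1]), np.log10(sweep_result.grid[idx + 1])
    species = "pi4p_a" if "pi4p" in tracked else "ps_b"

    def objective(logk: float) -> float:
        rates_k = replace(sweep_result.base_config.rates,
                          **{sweep_result.swept_parameter: 10.0 ** logk})
        cfg = replace(sweep_result.base_config, rates=rates_k)
        r = _condition_rates(cfg, sweep_result.counterligand_uM)
        lookup = {
            ("ps_b", "nonexchange"): r[0], ("ps_b", "exchange"): r[1],
            ("pi4p_a", "nonexchange"): r[2], ("pi4p_a", "exchange"): r[3],
        }
        return -lookup[(species, which)]

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": np.log10(1.0 + rel_tol) / 2})
    return float(10.0 ** res.x)


def parametric_acceleration_curve(
    base_config: SimulationConfig,
    kon_ps_grid,
    kon_pi4p: float,
    counterligand_uM: float = 5.0,
):
    """Theoretical (acceleration_pi4p, acceleration_ps) curve traced along
    a k_on_ps grid at fixed k_on_pi4p, for overlay with experimental
    acceleration-factor scatter.  Returns a DataFrame with columns
    ``k_on_ps, accel_pi4p, accel_ps``.
    """
    import pandas as pd

    rates = replace(base_config.rates, k_on_pi4p=kon_pi4p)
    cfg = replace(base_config, rates=rates)
    result = sweep(cfg, "k_on_ps", kon_ps_grid, counterligand_uM)
    return pd.DataFrame(
        {
            "k_on_ps": result.grid,
            "accel_pi4p": result.accel_pi4p,
            "accel_ps": result.accel_ps,
        }
    )
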