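# Methods

## The exchange model

The kinetic core treats a soluble lipid transfer domain (the ORD of an
ORP/Osh protein) cycling between two membranes, A and B. Nine dynamic
species evolve under mass action: the empty soluble domain `O`, the
membrane-docked empty forms `O−M_A` and `O−M_B`, the soluble 1:1 lipid
complexes `O(PS)` and `O(PI4P)`, and the four membrane lipid pools
`PS_A`, `PS_B`, `PI4P_A`, `PI4P_B`. Six reversible reactions connect
them: docking on either membrane (bimolecular on-rate `k_on_mb`,
unimolecular off-rate `k_off_mb`), and extraction/delivery of each lipid
on either membrane (`k_on_ps`/`k_off_ps`, `k_on_pi4p`/`k_off_pi4p`).

The membranes `M_A`, `M_B` are *boundary species*: docking formally
consumes them and extraction releases the docked form without a membrane
term, so treating them as literal reactants would violate mass
conservation. They are therefore clamped at constant concentration
during integration — the "fixed species" convention of biochemical
network simulators — which resolves the stoichiometric bookkeeping
exactly and reflects the physical picture of a membrane as an
effectively unchanging binding surface. With membranes clamped, total
protein and each total lipid are conserved exactly in the continuous
model and to solver tolerance in the integration (asserted at < 10⁻⁶ μM
drift in the tests).

Assumptions: the domain interacts identically with both membranes; one
lipid per domain; no spatial structure, tethering, membrane-contact-site
geometry, or PI(4)P phosphatase activity; deterministic (ODE) dynamics
only.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `k_on_mb` | μM⁻¹ s⁻¹ | 10 | fast, near-diffusion-limited docking |
| `k_off_mb` | s⁻¹ | 0.1 | fixed by the calibration scan (below); 1 s⁻¹ available in config |
| `k_on_ps`, `k_on_pi4p` | μM⁻¹ s⁻¹ | 10 | baseline lipid capture; the swept quantities |
| `k_off_ps`, `k_off_pi4p` | s⁻¹ | 1 | baseline lipid release |
| protein | μM | 0.2 | standard assay concentration |
| accessible PS (membrane A) | μM | 5 | 5% of the outer-leaflet lipid of a 200 μM population |
| `m_a`, `m_b` | μM | 100 | accessible outer-leaflet lipid of a 200 μM population |
| `rate_window`, `t_step` | s | 0.6 | initial-rate estimator (below) |
| solver rel/abs tol | — / μM | 10⁻⁸ / 10⁻¹⁰ | conservation to < 10⁻⁶ μM |

Units follow the assay conventions: concentrations in μM, time in s,
transfer rates reported as lipids min⁻¹ per protein
(μM s⁻¹ ÷ μM protein × 60).

## The simulated initial-rate estimator

Experimental initial velocities are defined operationally: a linear fit
of the first eight samples (4 s at 0.5 s sampling) of the normalized
transfer course. The simulated counterpart is equally operational — an
instantaneous flux at t = 0 is zero by construction (no loaded protein
yet), and a quasi-steady-state cycling flux is monotone in `k_on_ps` and
cannot produce the bell-shaped profile — so any finite estimate averages
over an early window, and the window length materially shifts where the
rate maximum sits.

The package default is the least-squares slope of the destination pool
over the first output interval, 0.6 s (`t_step = rate_window = 0.6 s`,
equivalently the average flux over [0, 0.6 s], consistent with a
simulator writing ~100 output points over a 1-minute run). Both the
window and `k_off_mb` were fixed with the shipped calibration scan
(`calibration_scan` / `ordflux calibrate`), which sweeps membrane
concentration {1, 10, 100, 200} μM, `k_off_mb` {0.1, 1} s⁻¹ and windows
{0.6, 4, 60} s and reports the argmax of the non-exchange PS-rate sweep
and the acceleration factor at it. The shipped defaults are the
combination whose operating point the acceptance suite verifies: rate
maximum at k_ON-PS = 3.7 μM⁻¹ s⁻¹ (±5%) with a PS acceleration factor of
0.13 (±0.03) under 5 μM PI(4)P. The scan also shows the maximum's
location is insensitive to the membrane boundary concentration above
~10 μM, so that choice is uncritical; the window and `k_off_mb` are the
two levers that matter. Experimental traces keep the 8-point/4-s
estimator regardless (`initial_velocity`).

`find_rate_maximum` refines the coarse grid argmax by bounded scalar
maximisation in log-parameter space, re-invoking the simulator, to < 1%
relative; on simulator-less sweep tables it falls back to parabolic
interpolation through the three bracketing points, which is exact for
rates parabolic in log-parameter. A maximum on the grid boundary is
returned unrefined with a warning.

## Trace normalization

`transferred(t) = max_transfer · (F(t) − F₀)/(F_Eq − F₀-Eq)`, where
`max_transfer` is derived, not hard-coded: accessible ligand
(fraction × leaflet share × total lipid) halved, because at equilibrium
the ligand is split between two identical populations — 2.5 μM for the
standard 5%/0.5/200 μM geometry. Reference levels are averaged over all
samples strictly between the bounding injection events, trimming two
samples next to each event to skip mixing transients. Assay-kind
differences are implemented as recorded in the protocols: the
two-population PS assay uses the equilibrium sample's own pre-mix
baseline as `F₀-Eq`; the PI(4)P and three-population assays use `F₀` in
the denominator. Time zero is the protein-injection sample itself,
inclusive. Negative normalized values from noise are retained so the
initial-rate fit stays unbiased.

## Titration fits

All three fitters are ordinary least squares (lmfit) and hence
scale-equivariant; plateaus are initialised from the first/last 10% of
points, the location parameter from the half-range crossing
(competition, saturation) or the steepest-slope temperature (melt). When
a `replicate_id` column is present, replicates are fitted jointly with
shared shape parameters (l50, or T_m and slope) and per-replicate
plateau/gain parameters.

Degenerate data raise flags rather than returning misleading numbers: a
competition curve whose fitted displacement across the measured range is
under 3× the residual noise is `no-displacement` (l50 reported
not-determinable, the expected outcome for very weak ligands such as
PI(4,5)P₂-class competitors); a melt fit that fails, lands within one
scan step of the range edge, or needs a transition wider than a quarter
of the scanned range is `melt-fit-failure`; a saturation amplitude
indistinguishable from noise is `no-binding`.

The competition model is an *operational* IC₅₀: a single-site hyperbola
in accessible competitor concentration. Probe and competitor are at
comparable concentrations, so no Cheng–Prusoff conversion to an absolute
K_i is attempted, and 1/[L]₅₀ is only used as a relative affinity proxy
(`rate_affinity_table` pairs it with transfer rates and reports a
Spearman rank correlation). Dilution correction for successive
injections is assumed applied upstream; the generator emits corrected
curves.

## Synthetic data

The generators emulate the *shapes* of the assay data with known ground
truth: transfer traces are built by running the kinetic model forward
and inverting the normalization onto chosen fluorescence levels, with
pre-injection baseline segments, event markers, two-sample injection
spikes at liposome additions, and additive Gaussian noise (σ = 1% of
dynamic range by default — the level suggested by smooth bench traces;
drift, photobleaching, shot noise and detector saturation are not
modelled). Competition, melt and saturation curves come from the same
functional families the fitters assume, on the protocols' grids
(0–1.25 μM in 11 steps; 25–95 °C in 1 °C steps; 0–300 μM). Alternatively
a transfer trace can be planted with an exact target initial rate: a
saturating-exponential course is rescaled so the eight-point estimator
applied to the noiseless curve returns the target exactly.

Because generator and fitter share the functional family for the
titration curves, passing recovery tests demonstrates correctness of the
estimation machinery and its noise behaviour — not that real binding
data follow a single-site hyperbola or a two-state Boltzmann unfolding.
Likewise the transfer-trace round trip validates the normalization
algebra and windows, not instrument-specific artefacts.

## Numerical choices

LSODA (stiff-capable) with rel tol 10⁻⁸ and abs tol 10⁻¹⁰ μM on a fixed
output grid independent of internal steps; output concentrations are
clipped at zero (negatives can only appear at the abs-tol scale). A
`t_end = 0` run returns the initial state. A failed integration raises
an error carrying the offending parameter set; inside a sweep it is
recorded as NaN with a warning and the sweep continues, and acceleration
factors with non-positive rates are reported as NaN rather than dropped.

Problem sizes in the shipped analyses: sweeps use 25 points per decade
over 0.01–10 000 μM⁻¹ s⁻¹ (151 points, three short integrations each);
recovery statistics use 50 transfer replicates and 100 titration
replicates. The full test suite runs in well under a minute.

## Known limitations

No spatial or contact-site geometry, no sterol or PI(4,5)P₂ reactions in
the kinetic scheme, no stochastic simulation, no global multi-ligand
competition model, no thermodynamic (ΔH/ΔG) analysis of melts, and no
instrument-file parsing beyond plain CSV. The model's membranes are
featureless boundary reservoirs; effects of lipid packing, charge or
curvature enter only implicitly through the effective rate constants.
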