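# ordflux

Kinetic modelling and fluorescence-assay analysis of lipid transfer by
OSBP-related domains (ORDs), the lipid-binding modules of ORP/Osh
proteins that shuttle phosphatidylserine (PS) and PI(4)P between the
endoplasmic reticulum and the plasma membrane in an antiport-like
exchange cycle.

The package has two halves that meet in the middle:

* **A mass-action kinetic model** of an ORD exchanging PS and PI(4)P
  between two membranes, A and B, through six reversible reactions —
  membrane docking (`O + M_A ⇌ O−M_A`, `O + M_B ⇌ O−M_B`) and lipid
  extraction/delivery on either membrane
  (`O−M_X + PS_X ⇌ O(PS)`, `O−M_X + PI4P_X ⇌ O(PI4P)`), with membranes
  treated as constant boundary species. The model answers a mechanistic
  question: how does the affinity of the domain for a lipid (set by
  k<sub>ON</sub>/k<sub>OFF</sub>) control how fast it transfers that
  lipid, alone or in exchange for a counterligand? Sweeping
  k<sub>ON-PS</sub> produces a bell-shaped initial-rate profile — a
  domain can transfer a low-affinity ligand *faster* than a high-affinity
  one — and comparing exchange with non-exchange runs yields
  *acceleration factors*, log₁₀(rate with counterligand / rate without).

* **The quantitative analysis pipeline** for the corresponding in vitro
  fluorescence assays: normalization of FRET dequenching/quenching
  transfer traces into absolute transferred-lipid time courses
  (`transferred = max_transfer · (F − F₀)/(F_Eq − F₀-Eq)`) with
  initial velocities from an eight-point linear fit; competition-binding
  curves fit with a single-site hyperbola to report [L]₅₀ (the accessible
  competitor concentration displacing half of the fluorescent reporter
  lipid, 1/[L]₅₀ serving as an affinity proxy); thermal-shift melt curves
  fit with a Boltzmann sigmoid to report T_m; and saturation
  membrane-binding curves. A seeded synthetic-data module generates all
  four data shapes with known ground truth, which is how the pipeline is
  validated end to end.

## Worked example

```python
from ordflux import (SimulationConfig, simulate, initial_transfer_rate,
                     sweep, find_rate_maximum, log_grid)

cfg = SimulationConfig()                      # 0.2 uM ORD, 5 uM PS in membrane A
traj = simulate(cfg)
print(initial_transfer_rate(traj))            # 16.28 lipids/min per protein

result = sweep(cfg, "k_on_ps", log_grid(per_decade=25))
print(find_rate_maximum(result, "nonexchange"))   # 3.72 uM^-1 s^-1
```

The first number is the initial PS transfer rate at the default
k<sub>ON-PS</sub> = 10 μM⁻¹ s⁻¹: about 16 PS molecules moved from
membrane A to membrane B per minute per protein. The sweep then shows
this rate is not monotone in affinity — it peaks at
k<sub>ON-PS</sub> ≈ 3.7 μM⁻¹ s⁻¹ and falls toward zero on both sides,
because a domain that binds its cargo too weakly rarely extracts it,
while one that binds too tightly rarely lets it go.

The same analysis from the shell, including the exchange condition and
acceleration factors:

```
$ ordflux sweep-analysis --out results/ --per-decade 10 --skip-variants
argmax k_on_ps = 3.71 uM^-1 s^-1, PS acceleration at argmax = 0.141
```

which writes `sweep.csv` (rates and acceleration factors across the
grid), `curves.csv` (parametric acceleration curves), `summary.json`,
and a `manifest.json` with content hashes for reproducibility checks.

Other entry points: `ordflux simulate`, `ordflux sweep`,
`ordflux calibrate` (sensitivity of the rate maximum to membrane
concentration, docking off-rate and rate window), `ordflux normalize`,
`ordflux fit`, and `ordflux synth`.

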