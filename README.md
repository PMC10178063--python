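# vasonet

Reduced-order hemodynamics and shear-driven sprouting for planar networks of
rigid cylindrical vessels.

Each vessel segment is an exact Hagen–Poiseuille resistor
(`R = 8 μ L / (π r⁴)`) and mass is balanced at every node, which is the
network form of steady incompressible laminar flow. Velocity inlets
prescribe a volumetric inflow `Q = v π r²`; pressure outlets pin the gauge
pressure. Wall shear stress per segment follows `τ = 4 μ |Q| / (π r³)`.
On top of the solver sit:

- **contour binning** of shear values (0.42 Pa bins by default), per-wall and
  per-junction snapped intervals, and the **junction overlap region** — the
  intersection of all junction intervals of a model (touching endpoints do
  not count as overlap);
- an **iterative growth engine** that solves the network, finds walls whose
  binned shear meets the overlap region, sprouts a perpendicular 0.05 m
  vessel there, and repeats;
- **benchmark model builders** (`1A`–`1G`, `2A`–`2C`) and their reported
  junction shear ranges as regression fixtures;
- **synthetic generators** for ladder networks, random boundary-condition
  assignments and noisy per-region shear sample tables with known ground
  truth.

## CLI

```sh
vasonet fixture 1C -o model1c.yaml        # write a benchmark network file
vasonet solve model1c.yaml -o table.tsv   # pressures, flows, shear, Re
vasonet analyze model1c.yaml              # Table-style report with overlap
vasonet analyze samples.tsv --samples     # same, from external WSS samples
vasonet grow model1c.yaml -o run/         # growth trace + per-iteration nets
vasonet verify                            # straight-pipe analytic check
```

All commands accept `-c config.yaml` plus `--fluid-viscosity` /
`--fluid-density` overrides; configs with unknown keys are rejected.
Network files are YAML with SI units; sample tables and reports are TSV.

## Python API

```python
from vasonet import (FluidProperties, build_fixture, assemble_and_solve,
                     BinningScheme, junction_overlap_region, run_growth)

fluid = FluidProperties()            # blood: 1060 kg/m³, 0.0035 Pa·s
net = build_fixture("1C").network
sol = assemble_and_solve(net, fluid)
overlap = junction_overlap_region(sol, BinningScheme())   # [0.84, 1.26] Pa
trace = run_growth(net, fluid)       # two sprouts: walls 4 then 5
```

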