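# biodyn

A modular, desk-scale agent-based simulation engine for biological
tissues, with three validated demonstration models:

* a **spatial SIR epidemic** — susceptible/infected/recovered person
  agents moving randomly in a toroidal box, compared against the
  Kermack–McKendrick ODE system and calibrated with particle swarm
  optimization;
* a **tumor spheroid** — growing, dividing, migrating and dying cancer
  cells whose spheroid diameter is read off the convex hull of the cell
  positions, as in wet-lab spheroid assays;
* **pyramidal-cell dendritic growth** — dendrites as trees of cylindrical
  neurite agents elongating along chemical gradients, with tapering,
  stochastic bifurcation, morphometrics and SWC input/output.

The package is aimed at computational biologists who want a small,
fully deterministic, testable engine for agent-based tissue models — the
kind of model usually run in large C++ frameworks — in plain scientific
Python (numpy/scipy/pandas).

## The core abstractions

Agents carry a position, a diameter and an ordered list of *behaviors*
(per-agent update rules). The engine executes *operations* each
iteration — per-agent operations (behaviors, mechanics) followed by
standalone operations (substance updates, data collection) — each with an
execution frequency `f` (due at iterations 0, f, 2f, …). Agent creation
and removal are *deferred*: an agent created at iteration `i` becomes
visible to neighbor queries at `i + 1`. Neighbor search uses a uniform
grid: space is split into cubic boxes no smaller than the largest agent,
so a fixed-radius query only scans the agent's box and its 26 neighbors
(27 boxes), and is verified against a brute-force O(n²) oracle.

The SIR comparator integrates (classic RK4)

```
dS/dt = −β S I / N,   dI/dt = β S I / N − γ I,   dR/dt = γ I
```

with `β = R0·γ` and `γ = 1/T_R`; preset diseases are measles
(R0 = 12.9, T_R = 8 d) and seasonal influenza (R0 = 1.3, T_R = 4.1 d).
The epidemic's total attack fraction is checked against the final-size
relation `z = 1 − exp(−R0 z)`.

## Worked example

Run the measles scenario three times with consecutive seeds:

```bash
$ biodyn run sir --seed 3 --repeats 3 --iterations 120 --out sir_demo
seed=3: 121 rows -> sir_demo/run_seed3.csv
seed=4: 121 rows -> sir_demo/run_seed4.csv
seed=5: 121 rows -> sir_demo/run_seed5.csv
summary -> sir_demo/summary.csv
```

Each per-seed CSV holds the compartment counts per day
(`iteration,t,S,I,R`); `summary.csv` adds mean/min/max over the seeds:

```
iteration      I_mean  I_min  I_max       R_mean
        0   10.000000   10.0   10.0     0.000000
       20  473.666667  454.0  486.0  1534.000000
       40   35.333333   31.0   42.0  1974.333333
      119    0.000000    0.0    0.0  2009.666667
```

Out of N = 2010 people (10 initially infected), the outbreak peaks
around day 17–20 and burns through essentially the whole population
(R(∞) ≈ 2009 of 2010) — as expected for R0 = 12.9, whose final-size
fraction is ≈ 0.99999. The same interface runs the other scenarios:

```bash
biodyn run spheroid --seed 0 --out spheroid_out     # t, n_cells, diameter_um
biodyn run pyramidal --seed 0 --out pyr_out         # per-tree morphometrics
biodyn validate-config my_scenario.toml
```

From Python, the library surface is richer — e.g. calibrating the
spatial epidemic against the ODE:

```python
from biodyn import epi

ode = epi.disease_ode_params("measles")
template = epi.disease_abm_template("measles")
fitted, result = epi.calibrate_sir_abm(ode, template, n_steps=100,
                                       swarm_size=30, n_iterations=100, seed=1)
mean = epi.mean_trajectory(fitted, 100, seeds=range(10))
```

## Layout

```
src/biodyn/
  engine.py        simulation loop, behaviors, operations, deferred lifecycle
  environment.py   uniform-grid neighbor search + brute-force oracle + kd-tree
  fields.py        Gaussian guidance cues, FTCS diffusion lattice
  mechanics.py     sphere-sphere repulsion, overdamped displacement updates
  epi.py           spatial SIR, RK4 ODE, final-size relation, calibration
  onco.py          tumor spheroid scenario, convex-hull diameter
  neuro.py         neurite growth, morphometrics, SWC I/O
  pso.py           global-best particle swarm optimizer
  timeseries.py    collector tables, CSV export
  config.py        TOML scenario configs, multi-seed runner
  cli.py           `biodyn` command-line entry points
```

See `docs/methods.md` for the models, their assumptions, parameter
defaults and numerical choices.
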