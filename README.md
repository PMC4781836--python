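# placeschema

Learning topological *schemas* of space from hippocampal place-cell
coactivity.

As a rodent explores an environment, its hippocampal place cells fire
in restricted regions (place fields), and downstream readout neurons
can detect which cells fire *together*.  This package asks how much of
the environment's large-scale structure can be assembled from that
relational information alone, with no coordinates ever observed.  It
simulates place-cell spiking along exploratory trajectories and trains
four schema learners on the spike trains:

| schema | relations learned | large-scale integrals |
| --- | --- | --- |
| graph `G` | pairwise coactivity `C_ij` | path connectivity, Eulerian paths, cliques |
| simplicial `T` | multi-way coactivity (maximal simplexes) | Betti numbers `b0`, `b1`, persistence barcodes |
| mereological `M` | pair-covers-single containment `V ◂ U` | composite (covered) regions |
| RCC5 `R` | qualitative region relations DR / PO / PP / PPi / EQ | track endpoints, midpoints, junctions |

Two timescales are tracked for each schema: the *physiological*
learning time `T_N`, when the relationship network stops changing, and
the *schematic* learning time `T_min`, when the large-scale integrals
stabilize.  Schematic learning typically finishes first: global
structure emerges from a partially trained network.

## The model

Each of `N` place cells fires as an inhomogeneous Poisson process with
a Gaussian tuning curve

```
lambda_i(r) = f_i * exp(-|r - r_i|^2 / (2 sigma_i^2)),
```

theta-modulated by `1 + cos(2 pi f_theta t)`.  Peak rates `f_i` and
place-field sizes `s_i` (field diameter at the 20%-of-peak contour,
`sigma_i = s_i / (2 sqrt(2 ln 5))`) are gamma-distributed; defaults are
`N = 200`, `f = 12 Hz`, `s = 20 cm`, theta at 8 Hz, a 1×1 m arena with
a central 0.3 m hole, and a 25-min session.  Cells spiking within the
same two-theta-period window (250 ms) are coactive; coactivity events
drive all four learners.  Homology is computed over Z2 on the
2-skeleton of the coactivity complex, with the persistence filtration
given by first-detection times.

## Worked example

```python
import placeschema as ps

env = ps.build_environment()                              # 1x1 m arena, 0.3 m hole
traj = ps.simulate_trajectory(env, duration=1500, seed=1) # 25 min session
cells = ps.sample_ensemble(env, n=200, seed=1)            # f=12 Hz, s=20 cm
trains = ps.generate_spikes(cells, traj, seed=1)          # theta at 8 Hz

g = ps.GraphSchema().fit(trains)
s = ps.SimplicialSchema().fit(trains)
print(f"links learned: {g.graph_.n_edges}  H_G = {g.entropy_:.3f} bits")
print(f"graph integral: distant pairs connected at T_min = {g.t_min_/60:.1f} min "
      f"({g.frac_links_at_t_min_:.0%} of links present)")
print(f"final Betti numbers (b0, b1): {s.betti_}   surviving 1-loops: {s.n_surviving_loops_}")
print(f"topological learning time T_min = {s.t_min_/60:.1f} min")
```

prints

```
links learned: 3941  H_G = 0.718 bits
graph integral: distant pairs connected at T_min = 3.6 min (70% of links present)
final Betti numbers (b0, b1): (1, 2)   surviving 1-loops: 2
topological learning time T_min = 19.8 min
```

The graph schema has learned ~20% of all possible pair relations
(binary entropy 0.72 bits), yet the most distant regions were already
path-connected after 3.6 min.  The coactivity complex ends connected
(`b0 = 1`); its surviving 1-loops include the loop encircling the
central hole — the topological signature of the environment — plus,
on this seed, one residual loop among weakly sampled cells.

A command-line interface wraps the same pipeline:

```
placeschema simulate --seed 1 --out out/         # trajectory + spike CSVs
placeschema learn --seed 1 --out out/            # fit all schemas, write reports
placeschema report --config cfg.yaml --out out/  # multi-seed medians + IQRs
placeschema reproduce-figures --out figures/     # link growth, barcodes, ...
```

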