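# hydrashell

Hydration-shell structure and dynamics analysis for molecular-dynamics
trajectories, plus a synthetic-data generator that plants known hydration
structure so every analysis stage can be verified against ground truth.

## What it computes

* **Water density grid** — bulk-normalized 3D water-oxygen density on a
  0.5 Å grid over the Cα-superposed ensemble, with minimum-image
  re-wrapping of waters and bulk estimated in the 8–10 Å shell from the
  protein surface (nearest heavy-atom distance).
* **Hydration sites** — local density maxima within a 1.4 Å radius at
  ≥ 2.0× bulk, annotated with surface distance and shell label; exported
  as a pseudo-atom PDB, CSV/JSON tables and an OpenDX map.
* **Surface G(r)** — water distribution vs. distance from the protein
  surface, sampled in a 4 Å cylinder scanned over two Euler angles (20°
  steps), volume-corrected per bin and bulk-normalized; peaks and shell
  boundaries located on the smoothed curve.
* **Residence times** — per-site occupancy autocorrelation (continuous or
  intermittent survival), single-exponential fits, a 1 ns
  "superstructured" flag, and shell-wise summaries that exclude
  superstructured sites.
* **H-bond lifetimes** — protein–water hydrogen-bond events
  (3.5 Å / 150° defaults) and their mean durations.
* **Protein metrics** — RMSF, backbone N–H order parameters S²
  (full-trajectory or windowed), radius of gyration, fitted Cα-RMSD
  series, and Shrake–Rupley SASA.
* **Chemical-shift restraints** — flat-bottom harmonic energy and
  gradient over the six backbone shift types (Cα, Cβ, C′, N, HN, Hα), and
  the equilibration weight ramp (evaluator only, no MD engine).
* **Synthetic systems** — bulk waters (i.i.d. or diffusive), planted
  hydration sites with two-state-Markov occupancy (exponential dwell in
  the continuous limit), and shell-profile enrichment, all deterministic
  per seed, with ground-truth records.

## CLI

```bash
# generate a synthetic system (GRO + multi-model PDB + ground truth)
hydrashell simulate --spec spec.yaml --seed 1 --out out/system

# run the full analysis (defaults mirror the published parameters)
hydrashell analyze --topology out/system.gro --trajectory out/system.pdb \
    --dt 2.0 --out out/analysis

# compare two reports side by side
hydrashell compare a/report.json b/report.json
```

`analyze` writes `report.json` (deterministic: identical inputs give
byte-identical reports) plus CSV tables, the OpenDX density map and the
hydration-site PDB. A YAML config (`--config`) can override any analysis
parameter; see `hydrashell.config.AnalysisConfig` for the schema.

Example `spec.yaml` for `simulate`:

```yaml
scaffold: {kind: single_sphere, radius: 6.0, n_atoms: 120}
n_bulk_waters: 1500
box: 36.0
n_frames: 2000
dt: 2.0
sites:
  - {position: [26.0, 18.0, 18.0], dwell_time: 80.0, occupancy: 0.6,
     capture_radius: 0.8, placement_sigma: 0.3}
```

## Python API

```python
import hydrashell as h

spec = h.SyntheticSpec(scaffold=h.Scaffold(), n_bulk_waters=1500,
                       box=36.0, n_frames=2000, dt=2.0, seed=1)
traj, truth = h.generate_system(spec)

grid = h.compute_density_grid(traj)
sites = h.detect_hydration_sites(grid, traj.frames[0],
                                 traj.protein_heavy_indices())
rdf = h.compute_surface_rdf(traj)
for site in sites:
    trace = h.build_occupancy_trace(traj, site)
    curve = h.survival_function(trace, "continuous")
    print(site.id, h.fit_residence_time(curve).tau)
```

## Layout

```
src/hydrashell/
  trajectory.py   data model, Kabsch superposition, wrapping, surface distance
  io.py           MDAnalysis-backed reader; plain-text PDB/GRO writers
  synthetic.py    seeded generator with planted ground truth
  structure.py    density grid, site detection, surface G(r), shells, contacts
  dynamics.py     occupancy traces, survival curves, residence fits, H-bonds
  protein.py      RMSF, S², Rg, RMSD series, SASA
  restraints.py   flat-bottom chemical-shift restraint energy/gradient/ramp
  config.py       YAML config with published-parameter defaults
  pipeline.py     orchestration, deterministic report, comparisons
  cli.py          `hydrashell` command group
```

Only orthorhombic boxes are supported; coordinates are in Å and times in
ps throughout.
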