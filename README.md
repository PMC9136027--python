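# mgpit — Monte Carlo pitting corrosion of Mg-alloy specimens

Biodegradable magnesium-alloy (AZ61) implants lose strength as corrosion
eats into them, and the loss is dominated by *pitting*: localized attack
that nucleates at defective spots in the slow-corroding surface oxide
film and then burrows into the fast-corroding alloy beneath. `mgpit` is
a voxel-based, semi-autonomous 3D Monte Carlo simulator of this process
for researchers developing degradable implants: it evolves the specimen
geometry under an experimentally measured mass-loss rate, quantifies the
resulting pit morphology the same way micro-CT scans are quantified, and
exports the corroded geometry for finite-element stress analysis.

## The model

The specimen is a regular grid of cubic elements of edge *a* (default
0.125 mm; a 15 × 15 × 2 mm specimen is 230,400 elements). Each element
*i* carries:

* an **exposure attribute** `EA_i ∈ {0..6}` — the number of its six faces
  in contact with saline (void or exterior); interior elements have
  `EA = 0` and cannot corrode,
* an **oxide attribute** `OA_i ∈ [0, 1]` — its relative corrosion speed:
  1 for intact Mg, 0.07 for the passivating oxide shell, and 0.4–0.6 for
  the sparse porous spots where pits nucleate.

Each time step Δt (default 25 h):

1. the exposed surface *S* sets the step's mass budget
   `ML = ṀL · S · Δt`, with `ṀL` the measured rate
   (default 0.003 mg/cm²·h); `ML / Me` (element mass `Me = a³ρ`,
   ρ = 1.7 mg/mm³) is the number of elements to remove, with a
   fractional-mass carry between steps,
2. every element gets a corrosion attribute `CA_i = EA_i · OA_i` and a
   corrosion probability `CP_i = (ML/Me) · CA_i / Σ CA`,
3. a Monte Carlo draw removes the budgeted elements (weighted sampling
   without replacement by default, or per-element Bernoulli trials), and
   the exposure of their neighbours is updated.

Because removal weight grows with exposed area and bare Mg corrodes
~14× faster than the shell, pits accelerate once they breach the oxide —
the simulated mass loss becomes super-linear at long times.

The quantification suite mirrors micro-CT image analysis: 26-connected
pit labeling, maximum pit depth `D_m` (z-extent), Canny-edge +
region-fill pit masks on cross sections, projected corrosion areas
`A_C / A_O` on the planes z = 0, 0.125, 0.25 mm, the linear
mass-loss fit `MLPA = c·T` and the saturating depth fit
`D(T) = A(1 − e^(−kT))`.

## Worked example

```python
import mgpit as m

config = m.CorrosionConfig(rng_seed=1)          # 15 x 15 x 2 mm, 20 x 25 h
grid, history = m.run_simulation(config)

final = history.records[-1]
print(f"T = {final.time:.0f} h: mass {final.mass_remaining:.2f} mg, "
      f"MLPA = {final.mlpa:.5f} mg/mm^2, S = {final.surface:.1f} mm^2")

fit = m.fit_mlpa_slope(history)
print(f"MLPA slope (origin fit): {fit.params['slope'] * 100:.5f} mg/cm^2/h")

metrics = m.pit_metrics(grid, planes=(0.0, 0.125, 0.25))
print(f"pits: {metrics.pit_count}, max depth D_m = {metrics.max_depth:.3f} mm")
for z, (a_c, frac) in metrics.plane_areas.items():
    print(f"  z = {z:5.3f} mm: A_C = {a_c:6.2f} mm^2 "
          f"(A_C/A_O = {frac:.4f}, {metrics.plane_pit_counts[z]} 2D pits)")
```

prints

```
T = 500 h: mass 755.31 mg, MLPA = 0.01699 mg/mm^2, S = 723.9 mm^2
MLPA slope (origin fit): 0.00330 mg/cm^2/h
pits: 1254, max depth D_m = 0.750 mm
  z = 0.000 mm: A_C =  11.62 mm^2 (A_C/A_O = 0.0517, 546 2D pits)
  z = 0.125 mm: A_C =   5.50 mm^2 (A_C/A_O = 0.0244, 175 2D pits)
  z = 0.250 mm: A_C =   1.67 mm^2 (A_C/A_O = 0.0074, 58 2D pits)
```

The specimen starts at 765.0 mg with 570 mm² of surface; after 500 h
it has lost ~9.7 mg, its exposed surface has grown by ~27% as pits
opened, and the fitted mass-loss slope (0.0033 mg/cm²·h) sits slightly
above the configured rate — the expected super-linearity of
current-surface budgeting. The projected corrosion area falls off
sharply with depth at 500 h: the surface plane is ~5% corroded while
the 0.25 mm plane is below 1%.

The same workflow is available from the shell:

```sh
mgpit simulate --outdir run1 --seed 1
mgpit quantify run1/final.voxels.txt --planes 0,0.125,0.25 --out metrics.json
mgpit export run1/final.voxels.txt --format stl --out specimen.stl
```

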