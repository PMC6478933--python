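# poreclog

Post-processing toolkit for molecular-dynamics trajectories of biological
nanopores (α-hemolysin and similar channels) with an analyte — e.g. a
homopeptide — lodged in the lumen. It answers the question *how much of the
pore's conductance does the analyte take away?* from two independent
directions:

1. **Equilibrium route — electrolyte occupancy and pore clogging.**
   Water and ion atoms are rasterized onto a cubic grid (1 Å cells by
   default): a cell is occupied when its center lies within the Van der Waals
   radius of an electrolyte atom. Frame-averaged and bulk-normalized, this
   yields the occupancy map *M*. Electrolyte pockets — cavities connected to
   the lumen only through reentrant paths, which carry no trans-membrane
   current — are removed by a directional accessibility filter: a cell
   belongs to the trans→cis accessible channel if an open path with
   monotonically non-decreasing *z* reaches it from the trans entrance
   (lateral steps free), and symmetrically for cis→trans; the through-channel
   map *M̃* is the intersection. The available cross-section per slice is

       A_z = Σ_{x,y} M̃_{x,y,z} Δx Δy

   and the quasi-1D pore resistance (access resistance neglected, constant
   resistivity ρ)

       R̃ = Σ_i ρ Δz / A_{z,i} .

   The **pore-clogging estimator** compares the clogged pore with the empty
   one:

       b = 1 − R̃₀ / R̃ ,

   so b = 0 for no obstruction and b = 1 for a fully blocked slice. A
   truncated variant starts the sum a configurable distance above the trans
   entrance, emulating a barrel-shortened pore.

2. **Non-equilibrium route — displacement current and blockage.**
   The windowed ionic current is computed from charge displacement along the
   pore axis,

       I(t) = 1/(Δt L_z) Σ_i q_i [z_i(t+Δt) − z_i(t)] ,

   with minimum-image unwrapping across the periodic boundary, per-species
   (K⁺/Cl⁻) decomposition, transient discard and block-averaged errors. The
   relative blockage is ΔI/I₀ = (I₀ − I)/I₀.

A statistics layer provides the 20-residue physicochemical table (VdW volume,
apparent residue volume, accessible surface area, hydropathy class), replica
mean ± SEM aggregation, Pearson/least-squares regression (clogging vs.
blockage, clogging vs. residue volume), Welch class contrasts, the ion/water
ratio inside the pore, radius-of-gyration relaxation and steered-MD
displacement arithmetic.

Because no public reference trajectory of a peptide-clogged pore exists to
test against, the package ships a first-class synthetic-data generator: frozen VdW-sphere pore walls
(cylinder, hourglass, pocketed/reentrant variants), mobile water/ion beads
with optional drift and diffusion, and concentric obstruction chains — all
with analytic ground truth for every pipeline stage (area profiles,
resistances, currents). See `docs/methods.md` for the model details and
error budget.

## Worked example

Clog a 5 Å × 50 Å cylindrical pore with a concentric 3 Å rod over its lower
30 Å, recover the clogging estimator from sampled occupancy maps, and
measure a drift current:

```python
import numpy as np
from poreclog import synthetic as syn, occupancy as occ, channel as ch
from poreclog import conductance as cond, current as cur, trajio

pore = syn.make_pore(syn.cylinder_pore(radius=5.0, length=50.0))
clogged = syn.insert_obstruction(pore, bead_radius=3.0, z_lo=0.0, z_hi=30.0)

grid = pore.default_grid(cell_size=1.0)
bulk = occ.region_from_bounds(grid, ((-2, 2), (-2, 2), (35, 47)))

def channel_profile(system, seed):
    spec = syn.ElectrolyteSpec(n_water=66, n_k=4, n_cl=4, seed=seed)
    traj = syn.make_trajectory(system, spec, n_frames=2000, mode="resample")
    electrolyte = trajio.select(traj, trajio.ELECTROLYTE)
    averaged = occ.trajectory_occupancy(traj, electrolyte, grid)
    normalized, _ = occ.normalize_bulk(averaged, bulk)
    return cond.area_profile(ch.through_channel(normalized), z_range=(0.0, 50.0))

result = cond.clogging_from_profiles(channel_profile(clogged, seed=2),
                                     channel_profile(pore, seed=1))
print(f"R_clogged = {result.R_tilde:.4f}  R_empty = {result.R0_tilde:.4f}  b = {result.b:.3f}")

spec = syn.ElectrolyteSpec(n_k=38, n_cl=38, drift_k=0.025, drift_cl=-0.025, seed=3)
traj = syn.make_trajectory(pore, spec, n_frames=100)
trace = cur.displacement_current(traj, trajio.select(traj, {"ION_K", "ION_CL"}))
mean = cur.mean_current(trace, block=400.0)
print(f"I = {mean.mean:.4f} ± {mean.se:.4f} nA "
      f"(expected {syn.expected_drift_current(pore, spec):.4f} nA)")
```

Output:

```
R_clogged = 0.8340  R_empty = 0.6302  b = 0.244
I = 6.0883 ± 0.0000 nA (expected 6.0883 nA)
```

The sampled b = 0.244 sits next to the analytic value 0.252 for this
geometry (R̃ = 30/(πr² − πr_rod²) + 20/(πr²) vs. R̃₀ = 50/(πr²), ρ = 1); the
drift-only current reproduces Σ qᵢvᵢ/L_z to machine precision.

The same chain is scriptable from the shell: `poreclog synth` →
`poreclog occupancy` → `poreclog channel` → `poreclog clog`, plus
`poreclog current` and `poreclog stats` (see `poreclog --help`). Each stage
writes its artifact together with a manifest of parameters and input hashes.

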