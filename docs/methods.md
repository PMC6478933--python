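# Methods

This note documents the models and numerical choices behind poreclog: what
each stage computes, the conventions it fixes, what the synthetic-data
generator does and does not emulate, and the resulting error budget.

## Coordinate and unit conventions

Lengths are Å, times ps, charges elementary charges; currents are reported
in nA (1 e/ps = 160.2176634 nA). The pore axis is *z*, increasing from the
trans side (barrel entrance) to the cis side (vestibule). Grids are regular;
cell (i, j, k) spans the half-open box `[origin + idx·Δ, origin + (idx+1)·Δ)`
and is represented by its center. Slice *k* of an area profile covers
`[z_k − Δz/2, z_k + Δz/2)`; the half-open convention makes the quasi-1D
resistance exactly additive over adjacent windows. Indices are 0-based in
code, 1-based in printed reports.

## Occupancy maps

Per frame, a cell is occupied (1) when its **center** lies within the VdW
radius of at least one selected electrolyte atom, else 0. The center test is
the cheap, standard voxel-occupancy convention; an any-overlap mode
(sphere-to-box distance) is available but biases areas outward by up to half
a cell diagonal and is not used by default. Binary frame maps are averaged
arithmetically and normalized by the mean averaged occupancy of a
user-chosen bulk region — a slab of unconfined electrolyte. The package does
not define "bulk" spatially; synthetic systems place it on the pore axis in
an unobstructed section, and real-system users should place it in the
reservoir far from the membrane. Atoms outside the grid are ignored (the
grid is the analysis window); a zero-occupancy bulk region is an error, not
a silent division.

Occupancy is computed from water and ions jointly by default ("electrolyte");
the selection is configurable per species.

## Accessible-channel filtering

Electrolyte pockets are solvent cavities connected to the lumen only through
reentrant paths; they carry no trans-membrane current and would otherwise
inflate A(z). The filter formalizes "accessible when moving from the barrel
entrance towards the vestibule" as **monotone-z reachability**: a cell is in
the trans→cis mask iff an open path (every cell above the occupancy
threshold θ) of face-adjacent steps with non-decreasing z reaches it from an
open cell of the entrance slice; lateral steps at constant z are
unrestricted, so side lobes that open sideways are kept. The cis→trans mask
uses non-increasing z, and the through-channel is the intersection — a
pocket opening towards either side is removed by one of the two sweeps.

θ defaults to 0 (any normalized occupancy opens a cell); 6-connectivity is
the default, 26-connectivity an option. Seeds are all open cells of the
entrance slice, optionally restricted to a lateral disk to avoid seeding
bulk regions outside the pore. The sweep is implemented as a per-slice
2-D connected-component pass (scipy.ndimage) with an axial carry, which is
equivalent to BFS over the directed lateral+axial edge graph; the test suite
checks it against an independent brute-force BFS on random grids. For
per-replica analyses, one mask is computed per trajectory from that
replica's averaged, normalized map.

## Quasi-1D resistance and clogging

A(z) sums the through-channel map per slice (fractional occupancies
contribute fractionally); R̃ = Σ ρΔz/A_z with constant resistivity ρ
(default 1 — the clogging estimator b = 1 − R̃₀/R̃ is exactly
ρ-independent, so absolute units only matter if the user supplies a real
electrolyte resistivity). A slice with zero area makes the pore BLOCKED
(R̃ = +∞, b = 1). b < 0 (empty pore resisting more) is permitted and logged
as anomalous — with sampled maps it occurs at the noise level for weak
obstructions. Access resistance is excluded throughout. The integration
window [z_lo, z_hi] is configuration, not auto-detection; the truncated
variant moves z_lo up by an offset (default 20 Å) to emulate a
barrel-truncated pore.

## Displacement current

The windowed current sums q_i·Δz_i over consecutive frames, divided by
Δt·L_z. Δz is minimum-image unwrapped by default (|Δz| > L_z/2 folds back by
L_z); without unwrapping, one boundary crossing per 40 ps window would
corrupt the estimate completely. L_z is taken per window from the first
frame's box (NPT boxes fluctuate); a mean-box mode exists. Species currents
restrict the sum to one species; the TOTAL trace sums all selected
electrolyte atoms (neutral waters contribute zero unless given partial
charges). Mean currents discard a configurable transient and use block
averaging (default 8 ns blocks) for the standard error, since window
currents are autocorrelated; with fewer than two blocks the naive SE is
used. Across replicas, means are combined as independent measurements
(SEM = sd/√n).

## Amino-acid table

The packaged TSV carries, per residue: side-chain-inclusive VdW volume
(Zamyatnin's tabulation), mean residue volume in folded proteins
(Harpaz–Gerstein–Chothia) as the "apparent volume", Gly-X-Gly accessible
surface area (Miller et al.), and a hydropathy class. Classes partition the
20 residues as: positive {R, K}, negative {D, E}, hydrophobic
{A, V, L, I, M, F, W, C}, polar {G, S, T, Y, N, Q, P, H}. Histidine is
POLAR by default (it titrates near neutral pH) and reclassifiable at load
time. Class contrasts use Welch's unequal-variance t-test; classes with
fewer than two members are excluded with a warning.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a physics
engine. A pore is a frozen wall of VdW spheres (radius w, spacing 0.8 w
axially and circumferentially, so the wall has no gaps wider than w) around
an analytic radius profile r(z): constant (cylinder), linear taper
(hourglass), or cylinder plus a lateral dead-end pocket connected to the
lumen only at its top (POCKETED) or bottom (REENTRANT) — entering the
pocket body from the lumen requires a z-reversal, which is exactly what the
monotone filter removes. The pocket's lateral gap (default 4 Å) exceeds one
water diameter so that VdW smearing cannot bridge it.

**Center-accessible convention.** r(z) bounds mobile-particle *centers*, and
the analytic area A(z) = πr(z)² (minus the obstruction annulus πr_rod²) is
that center-accessible cross-section. This makes the occupancy pipeline
exactly consistent with the ground truth for an ideal (non-interacting) bead
fluid: writing the per-frame occupancy of a cell as 1 − exp(−λ V_ov), with
λ the particle density and V_ov the overlap of the cell-center's VdW ball
with the accessible region, the dilute-limit map is proportional to V_ov,
and summing V_ov over a slice integrates to V_sphere × A exactly — the VdW
smearing cancels. Two correction terms remain:

* **Saturation bias**, from the concavity of 1 − exp(−λV): partial cells are
  over-counted by O(λV_sphere). At half of liquid-water density
  (λV ≈ 0.2) the bias is ~1%; at full liquid density ~3%. Closure fixtures
  therefore sample at half-liquid density — the generator's ceiling remains
  "liquid-like or lower", enforced by a Monte-Carlo overfill check.
* **Monte-Carlo noise**, ∝ 1/√(frames). Closure fixtures use 4000
  independently resampled frames, putting per-slice noise near 1%.

With both, the sampled pipeline recovers A(z) = πr² within ~2.5% per
interior slice at 1 Å and 0.5 Å cells, and R̃ within ~0.5% of ρL/(πr²). The
first and last water-diameter of the window lose part of their smearing
mass to the window edge (an artifact of any finite analysis window), so
per-slice closure is asserted on interior slices; the resistance sums the
full window. The *deterministic* discretization error of the pipeline is
characterized separately through the indicator map (the infinite-sampling
limit): −1.8% at Δ = 1 Å, −0.6% at Δ = 0.5 Å for the reference cylinder,
with the pore axis placed on a cell corner so the circle is discretized
symmetrically.

**Dynamics.** Two trajectory modes exist. `resample` draws fresh uniform
positions in the accessible region each frame — ideally decorrelated
equilibrium sampling, used for occupancy convergence. `brownian` (default)
advances particles by an operator-split step: a lateral Gaussian substep
rejected at the walls (a cheap reflecting boundary), then an axial substep
(drift·Δt plus Gaussian noise, z-periodic). In z-invariant geometries the
axial substep is never rejected, so the imposed drift — and hence the
expected current Σ qᵢvᵢ/L_z — is exact to machine precision; diffusive
fixtures agree within standard errors. All randomness flows from one seeded
`numpy` generator; fixed seed ⇒ bit-identical trajectories.

**Obstructions** are concentric bead chains rendered as frozen atoms but
modeled as a rod of the bead radius for exclusion and analytic area — the
annulus π(r² − r_rod²) is then exact rather than scalloped between beads. A
bead radius at or above the channel radius is valid input (the b = 1 limit)
and warns.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: electrostatics and applied fields (drift is
imposed kinematically), correlated liquid structure (real water saturates
per-frame occupancy; the ideal-bead fluid is Poisson, which is why the
estimator is operated in its dilute regime), peptide conformational
dynamics, protein atomic roughness, and the actual α-hemolysin geometry.
Consequently production-scale quantities (per-residue clogging values,
blockage magnitudes, ion/water ratios of the real pore) are outside the
scope of the test suite; what is verified is that every operator reproduces
its analytic ground truth and that the equilibrium clogging estimator tracks
the independently simulated current blockage (Pearson r > 0.9 across
obstruction radii at desk scale).

## Problem sizes

Default verification sizes, chosen to keep the full suite within a few
minutes on one CPU: closure fixtures 66 waters + 2 ions × 4000 resampled
frames (1 Å and 0.5 Å grids, 16×16×50 to 32×32×100 cells); mask-oracle
comparisons 100 random grids up to 12³; current oracles 20–40 ions × 60–250
windows; correlation study 7 obstruction radii × 300 frames. The acceptance
script re-runs the same computations from a single seed in ~30 s.

## Known limitations

* The directional filter assumes the pore axis is grid-aligned; tilted
  channels would need a rotated grid.
* Block-averaged errors require the block length to exceed the current
  autocorrelation time; the 8 ns default matches typical nanopore MD frame
  economies but is configuration, not inference.
* The relaxation-time estimator (first entry into a ±5% band around the
  tail mean) is a pragmatic equilibration check, not a fit of a relaxation
  model; it is accurate to a factor ~2 on noisy exponentials.
* HDF5 map files store raw arrays with grid metadata; no chunked streaming
  is implemented, so maps must fit in memory (a non-issue at 1 Å for
  pore-scale windows).
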