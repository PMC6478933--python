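"""Self-contained synthetic fixtures with analytic ground truth.

The generator builds a frozen pore wall out of VdW spheres (so fixtures
exercise the real rasterizer, not an idealized surface), fills the channel
with mobile "water" and "ion" beads, and optionally inserts an obstructing
bead chain along the axis. Every stage of the analysis pipeline has a closed
form on these systems: the available area is π r(z)² (minus the obstruction
annulus), the quasi-1D resistance follows from it, and drift-only
trajectories carry the exact current Σ q_i v_i / L_z.

Geometries:

* ``CYLINDER`` — constant radius r.
* ``HOURGLASS`` — radius tapering linearly r_end → r_waist → r_end.
* ``POCKETED`` — cylinder plus a lateral dead-end pocket opening towards the
  cis side: its body extends towards trans, so entering it during the
  trans→cis monotone sweep would require a −z step. The through-channel
  equals the plain cylinder by construction.
* ``REENTRANT`` — as POCKETED with the opening towards trans.

Coordinates: the pore axis is z, increasing trans→cis, spanning [0, length];
the axis sits at (x, y) = (0, 0) and mobile particles are z-periodic over the
box height (= pore length). Mobile-bead radii are round synthetic values
(water 1.4 Å, K 1.5 Å, Cl 1.8 Å), not force-field radii.

The radius profile r(z) bounds mobile-particle *centers*, and the analytic
ground-truth area A(z) = π r(z)² is that center-accessible cross-section.
This convention makes the occupancy pipeline exactly consistent with the
ground truth: for an ideal (non-interacting) bead fluid the frame-averaged,
bulk-normalized occupancy summed over a slice equals the center-accessible
area — the VdW smearing of each bead integrates out (Σ_cells V_overlap =
V_sphere × A per slice), up to a small saturation bias that grows with the
per-frame coverage density. See docs/methods.md for the error budget.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import PlacementError, ValidationError
from .occupancy import GridSpec, OccupancyMap, Stage
from .trajio import AtomMeta, Species, SpeciesRules, Trajectory
from .units import E_PER_PS_TO_NA

#: number density of liquid water, Å⁻³ — the "liquid-like" filling ceiling
WATER_NUMBER_DENSITY = 0.0334
#: ion-pair number density of a 2 M solution, Å⁻³ (per ion species)
ION_DENSITY_2M = 2.0 * 6.02214076e-4


class PoreShape(enum.Enum):
    CYLINDER = "CYLINDER"
    HOURGLASS = "HOURGLASS"
    POCKETED = "POCKETED"
    REENTRANT = "REENTRANT"


@dataclass(frozen=True)
class PocketSpec:
    """Lateral dead-end pocket on the +x side of the channel.

    The body is the slab x ∈ [r_wall + gap, r_wall + gap + depth],
    |y| ≤ half_width, z ∈ [z_lo, z_hi]; the neck connects it to the lumen
    over the top ``neck_height`` Å (``opening="cis"``) or the bottom
    (``opening="trans"``)."""

    z_lo: float
    z_hi: float
    gap: float = 4.0       # > 2 x water radius so VdW halos cannot bridge it
    depth: float = 6.0
    half_width: float = 3.0
    neck_height: float = 4.0
    opening: str = "cis"

    def __post_init__(self) -> None:
        if not self.z_lo < self.z_hi:
            raise ValidationError("pocket needs z_lo < z_hi")
        if self.opening not in ("cis", "trans"):
            raise ValidationError("pocket opening must be 'cis' or 'trans'")
        if self.neck_height >= self.z_hi - self.z_lo:
            raise ValidationError("neck_height must be smaller than the pocket height")


@dataclass(frozen=True)
class PoreGeometry:
    shape: PoreShape
    radius: float                      # channel radius at the entrances, Å
    length: float                      # pore length, Å
    radius_waist: float | None = None  # HOURGLASS midpoint radius
    wall_sphere_radius: float = 1.0
    pocket: PocketSpec | None = None

    def __post_init__(self) -> None:
        if not (self.radius > 0 and self.length > 0 and self.wall_sphere_radius > 0):
            raise ValidationError("radius, length and wall_sphere_radius must be > 0")
        if self.shape is PoreShape.HOURGLASS and not self.radius_waist:
            raise ValidationError("HOURGLASS requires radius_waist")
        if self.shape in (PoreShape.POCKETED, PoreShape.REENTRANT) and self.pocket is None:
            object.__setattr__(
                self,
                "pocket",
                PocketSpec(
                    z_lo=0.3 * self.length,
                    z_hi=0.6 * self.length,
                    opening="cis" if self.shape is PoreShape.POCKETED else "trans",
                ),
            )

    def radius_at(self, z) -> np.ndarray:
        """Through-channel radius profile r(z) (pockets excluded)."""
        z = np.asarray(z, dtype=float)
        if self.shape is PoreShape.HOURGLASS:
            half = self.length / 2.0
            frac = np.abs(z - half) / half
            return self.radius_waist + (self.radius - self.radius_waist) * frac
        return np.full_like(z, self.radius)

    @property
    def min_radius(self) -> float:
        return float(self.radius_waist) if self.shape is PoreShape.HOURGLASS else self.radius


def cylinder_pore(radius: float = 5.0, length: float = 50.0, **kw) -> PoreGeometry:
    return PoreGeometry(PoreShape.CYLINDER, radius, length, **kw)


def hourglass_pore(radius: float = 8.0, radius_waist: float = 3.0, length: float = 50.0, **kw) -> PoreGeometry:
    return PoreGeometry(PoreShape.HOURGLASS, radius, length, radius_waist=radius_waist, **kw)


def pocketed_pore(radius: float = 5.0, length: float = 50.0, pocket: PocketSpec | None = None, **kw) -> PoreGeometry:
    return PoreGeometry(PoreShape.POCKETED, radius, length, pocket=pocket, **kw)


@dataclass(frozen=True)
class Obstruction:
    """Concentric bead chain along the axis, modeled as a rod of
    ``bead_radius`` over [z_lo, z_hi] for exclusion and analytic area."""

    bead_radius: float
    z_lo: float
    z_hi: float
    n_beads: int

    def __post_init__(self) -> None:
        if self.bead_radius < 0 or not self.z_lo < self.z_hi or self.n_beads < 1:
            raise ValidationError("invalid obstruction spec")


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Mobile-particle content and dynamics of a synthetic trajectory."""

    n_water: int = 0
    n_k: int = 0
    n_cl: int = 0
    drift_water: float = 0.0   # Å/ps along z
    drift_k: float = 0.0
    drift_cl: float = 0.0
    diffusion: float = 0.0     # Å²/ps, all species
    seed: int = 0
    water_radius: float = 1.4
    k_radius: float = 1.5
    cl_radius: float = 1.8

    def __post_init__(self) -> None:
        if min(self.n_water, self.n_k, self.n_cl) < 0:
            raise ValidationError("particle counts must be >= 0")
        if self.diffusion < 0:
            raise ValidationError("diffusion must be >= 0")


@dataclass
class SyntheticSystem:
    """A pore-wall topology with analytic geometry attached."""

    geometry: PoreGeometry
    wall_coords: np.ndarray
    wall_meta: list[AtomMeta]
    obstruction: Obstruction | None = None
    obstruction_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    obstruction_meta: list[AtomMeta] = field(default_factory=list)

    # -- analytic ground truth -------------------------------------------

    def analytic_area(self, z) -> np.ndarray:
        """Exact through-channel area π(r(z)² − r_rod²) per z (Å²)."""
        z = np.asarray(z, dtype=float)
        r2 = self.geometry.radius_at(z) ** 2
        if self.obstruction is not None:
            span = (z >= self.obstruction.z_lo) & (z < self.obstruction.z_hi)
            r2 = r2 - span * min(self.obstruction.bead_radius, self.geometry.min_radius) ** 2
        return np.pi * np.clip(r2, 0.0, None)

    def analytic_resistance(self, dz: float = 0.1, rho: float = 1.0) -> float:
        z = np.arange(dz / 2.0, self.geometry.length, dz)
        area = self.analytic_area(z)
        if np.any(area == 0):
            return float("inf")
        return float(np.sum(rho * dz / area))

    # -- accessibility ----------------------------------------------------

    def accessible(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask: which points a bead of radius ``margin`` may occupy."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        d = np.hypot(x, y)
        inside = d <= self.geometry.radius_at(z) - margin
        inside &= (z >= 0) & (z < self.geometry.length)
        if self.obstruction is not None:
            ob = self.obstruction
            span = (z >= ob.z_lo) & (z < ob.z_hi)
            inside &= ~(span & (d < ob.bead_radius + margin))
        pk = self.geometry.pocket
        if pk is not None:
            r_wall = self.geometry.radius
            x_lo, x_hi = r_wall + pk.gap, r_wall + pk.gap + pk.depth
            body = (
                (x >= x_lo + margin) & (x <= x_hi - margin)
                & (np.abs(y) <= pk.half_width - margin)
                & (z >= pk.z_lo + margin) & (z <= pk.z_hi - margin)
            )
            if pk.opening == "cis":
                nz_lo, nz_hi = pk.z_hi - pk.neck_height, pk.z_hi
            else:
                nz_lo, nz_hi = pk.z_lo, pk.z_lo + pk.neck_height
            neck = (
                (x >= 0) & (x <= x_hi - margin)
                & (np.abs(y) <= pk.half_width - margin)
                & (z >= nz_lo + margin) & (z <= nz_hi - margin)
            )
            inside |= body | neck
        return inside

    # -- grids ------------------------------------------------------------

    def default_grid(self, cell_size: float = 1.0, lateral_pad: float = 2.0) -> GridSpec:
        """Grid covering the system with the axis on a cell corner, so that a
        cylinder centered on the axis is discretized symmetrically."""
        g = self.geometry
        half = g.radius + g.wall_sphere_radius + lateral_pad
        x_hi = half
        if g.pocket is not None:
            x_hi = max(x_hi, g.radius + g.pocket.gap + g.pocket.depth + lateral_pad)
        i_lo = int(np.floor(-half / cell_size))
        nx = int(np.ceil(x_hi / cell_size)) - i_lo
        j_lo = int(np.floor(-half / cell_size))
        ny = int(np.ceil(half / cell_size)) - j_lo
        nz = int(round(g.length / cell_size))
        return GridSpec(
            origin=(i_lo * cell_size, j_lo * cell_size, 0.0),
            cell=(cell_size,) * 3,
            dims=(nx, ny, nz),
        )

    def bulk_region(self, grid: GridSpec, half_extent: float = 2.0) -> tuple:
        """Index bounds of a core slab on the axis, middle third of the pore —
        a region of bulk-like electrolyte used for map normalization."""
        he = min(half_extent, self.geometry.min_radius / 2.0)
        bounds = []
        for axis, (lo, hi) in enumerate(
            [(-he, he), (-he, he), (self.geometry.length / 3.0, 2.0 * self.geometry.length / 3.0)]
        ):
            i_lo = int(np.floor((lo - grid.origin[axis]) / grid.cell[axis]))
            i_hi = int(np.ceil((hi - grid.origin[axis]) / grid.cell[axis]))
            bounds.append((max(i_lo, 0), min(i_hi, grid.dims[axis])))
        return tuple(bounds)

    @property
    def frozen_coords(self) -> np.ndarray:
        if len(self.obstruction_meta):
            return np.vstack([self.wall_coords, self.obstruction_coords])
        return self.wall_coords

    @property
    def frozen_meta(self) -> list[AtomMeta]:
        return self.wall_meta + self.obstruction_meta

    @property
    def box(self) -> tuple[float, float, float]:
        g = self.geometry
        half = g.radius + g.wall_sphere_radius + 2.0
        if g.pocket is not None:
            half = max(half, g.radius + g.pocket.gap + g.pocket.depth + 2.0)
        return (2 * half, 2 * half, g.length)


def make_pore(geometry: PoreGeometry, wall_spacing_factor: float = 0.8) -> SyntheticSystem:
    """Build the frozen wall-sphere topology for a geometry.

    Wall spheres of radius w are centered at r(z) + w so their inner surface
    sits at the nominal channel radius; rings are spaced 0.8 w axially and
    circumferentially so the wall has no gaps wider than w.
    """
    w = geometry.wall_sphere_radius
    if geometry.min_radius < w:
        raise ValidationError(
            f"channel radius {geometry.min_radius} Å < wall sphere radius {w} Å: degenerate geometry"
        )
    spacing = wall_spacing_factor * w
    zs = np.arange(spacing / 2.0, geometry.length, spacing)
    coords = []
    for z in zs:
        ring_r = float(geometry.radius_at(z)) + w
        n_ring = max(8, int(np.ceil(2 * np.pi * ring_r / spacing)))
        ang = 2 * np.pi * np.arange(n_ring) / n_ring
        ring = np.column_stack([ring_r * np.cos(ang), ring_r * np.sin(ang), np.full(n_ring, z)])
        coords.append(ring)
    wall_coords = np.vstack(coords)
    meta = [
        AtomMeta(atom_id=i, name="WL", residue="WAL", species=Species.PORE,
                 charge=0.0, vdw_radius=w)
        for i in range(wall_coords.shape[0])
    ]
    return SyntheticSystem(geometry=geometry, wall_coords=wall_coords, wall_meta=meta)


def insert_obstruction(
    system: SyntheticSystem,
    bead_radius: float,
    z_lo: float | None = None,
    z_hi: float | None = None,
    spacing: float | None = None,
) -> SyntheticSystem:
    """Return a copy of the system with a frozen concentric bead chain.

    A bead radius at or above the local channel radius blocks the pore
    completely; this is valid input (the b = 1 limit) and only warns.
    """
    g = system.geometry
    z_lo = 0.0 if z_lo is None else float(z_lo)
    z_hi = g.length if z_hi is None else float(z_hi)
    if not 0 <= z_lo < z_hi <= g.length:
        raise ValidationError("obstruction span must lie inside the pore")
    if bead_radius >= g.min_radius:
        warnings.warn(
            f"bead radius {bead_radius} Å >= channel radius {g.min_radius} Å: pore fully blocked",
            stacklevel=2,
        )
    if spacing is None:
        spacing = max(0.5 * bead_radius, 0.5) if bead_radius > 0 else 1.0
    zs = np.arange(z_lo + spacing / 2.0, z_hi, spacing)
    coords = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
    n0 = len(system.wall_meta)
    meta = [
        AtomMeta(atom_id=n0 + i, name="BD", residue="OBS", species=Species.PEPTIDE,
                 charge=0.0, vdw_radius=max(bead_radius, 1e-6))
        for i in range(coords.shape[0])
    ]
    ob = Obstruction(bead_radius=bead_radius, z_lo=z_lo, z_hi=z_hi, n_beads=len(meta))
    return replace(system, obstruction=ob, obstruction_coords=coords, obstruction_meta=meta)


# ---------------------------------------------------------------------------
# mobile particles


def _accessible_volume(system: SyntheticSystem, margin: float, n_grid: int = 200_000, seed: int = 7) -> float:
    """Monte-Carlo accessible volume for the overfill check."""
    rng = np.random.default_rng(seed)
    box = system.box
    pts = rng.random((n_grid, 3)) * np.array([box[0], box[1], box[2]])
    pts[:, 0] -= box[0] / 2.0
    pts[:, 1] -= box[1] / 2.0
    frac = system.accessible(pts, margin=margin).mean()
    return float(frac * box[0] * box[1] * box[2])


def _sample_uniform(
    system: SyntheticSystem, n: int, margin: float, rng: np.random.Generator, max_batches: int = 500
) -> np.ndarray:
    box = system.box
    out = np.empty((0, 3))
    for _ in range(max_batches):
        if out.shape[0] >= n:
            break
        batch = rng.random((max(4 * n, 256), 3)) * np.array(box)
        batch[:, 0] -= box[0] / 2.0
        batch[:, 1] -= box[1] / 2.0
        batch = batch[system.accessible(batch, margin=margin)]
        out = np.vstack([out, batch])
    if out.shape[0] < n:
        raise PlacementError(
            f"could not place {n} particles of radius {margin} Å after bounded retries"
        )
    return out[:n]


def make_trajectory(
    system: SyntheticSystem,
    spec: ElectrolyteSpec,
    n_frames: int,
    frame_interval: float = 40.0,
    mode: str = "brownian",
) -> Trajectory:
    """Generate a deterministic synthetic trajectory.

    ``mode="brownian"``: particles take drift + Gaussian diffusion steps,
    rejected (kept in place) when they would leave the accessible region —
    a cheap reflecting-wall scheme — and wrap periodically in z.
    ``mode="resample"``: every frame draws fresh uniform positions in the
    accessible region (drift and diffusion ignored); this emulates ideally
    decorrelated equilibrium sampling and is what occupancy-convergence
    studies use.
    """
    if mode not in ("brownian", "resample"):
        raise ValidationError(f"unknown trajectory mode {mode!r}")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)

    groups = [
        (spec.n_water, spec.water_radius, "OW", "SOL", Species.WATER, 0.0, spec.drift_water),
        (spec.n_k, spec.k_radius, "K", "ION", Species.ION_K, 1.0, spec.drift_k),
        (spec.n_cl, spec.cl_radius, "CL", "ION", Species.ION_CL, -1.0, spec.drift_cl),
    ]
    n_mobile = sum(g[0] for g in groups)
    if n_mobile:
        vol = _accessible_volume(system, margin=0.0)
        bead_vol = sum(n * 4.0 / 3.0 * np.pi * r**3 for n, r, *_ in groups)
        if vol <= 0 or bead_vol / vol > 0.74:
            raise PlacementError(
                f"requested particle volume {bead_vol:.0f} Å³ overfills the accessible "
                f"volume {vol:.0f} Å³"
            )

    frozen_meta = system.frozen_meta
    mobile_meta: list[AtomMeta] = []
    positions: list[np.ndarray] = []
    drifts: list[float] = []
    n0 = len(frozen_meta)
    for n, r, name, res, species, q, v in groups:
        if n == 0:
            continue
        pts = _sample_uniform(system, n, margin=0.0, rng=rng)
        positions.append(pts)
        drifts.extend([v] * n)
        for _ in range(n):
            mobile_meta.append(
                AtomMeta(atom_id=n0 + len(mobile_meta), name=name, residue=res,
                         species=species, charge=q, vdw_radius=r)
            )
    mobile = np.vstack(positions) if positions else np.empty((0, 3))
    drift_arr = np.asarray(drifts)

    box = np.asarray(system.box)
    frozen = system.frozen_coords
    n_total = n0 + mobile.shape[0]
    coords = np.empty((n_frames, n_total, 3))
    sigma = np.sqrt(2.0 * spec.diffusion * frame_interval)

    current = mobile.copy()
    for f in range(n_frames):
        if f > 0 and current.shape[0]:
            if mode == "resample":
                current = _sample_uniform(system, current.shape[0], margin=0.0, rng=rng)
            else:
                # Operator-split update: the lateral diffusion substep is
                # rejected at the walls (cheap reflecting boundary), then the
                # axial substep (drift + noise, z-periodic) is applied. In
                # z-invariant geometries the axial substep is never rejected,
                # so the imposed drift — and hence Σ q v / L_z — is exact.
                if sigma > 0:
                    lateral = current.copy()
                    lateral[:, :2] += rng.normal(0.0, sigma, size=(current.shape[0], 2))
                    ok = system.accessible(lateral, margin=0.0)
                    current = np.where(ok[:, None], lateral, current)
                axial = current.copy()
                axial[:, 2] += drift_arr * frame_interval
                if sigma > 0:
                    axial[:, 2] += rng.normal(0.0, sigma, size=current.shape[0])
                axial[:, 2] %= box[2]
                ok = system.accessible(axial, margin=0.0)
                current = np.where(ok[:, None], axial, current)
        coords[f, :n0] = frozen
        coords[f, n0:] = current

    return Trajectory(
        topology=frozen_meta + mobile_meta,
        coords=coords,
        boxes=np.tile(box, (n_frames, 1)),
        times=np.arange(n_frames) * frame_interval,
        frame_interval=frame_interval,
    )


def expected_drift_current(system: SyntheticSystem, spec: ElectrolyteSpec) -> float:
    """Exact mean current (nA) of a drift-only trajectory: Σ q_i v_i / L_z."""
    lz = system.box[2]
    e_per_ps = (spec.n_k * 1.0 * spec.drift_k + spec.n_cl * (-1.0) * spec.drift_cl) / lz
    return e_per_ps * E_PER_PS_TO_NA


def geometry_occupancy(system: SyntheticSystem, grid: GridSpec) -> OccupancyMap:
    """Analytic indicator occupancy: 1 on cell centers inside the accessible
    region (channel, pocket, minus obstruction), 0 elsewhere. Serves as the
    infinite-sampling limit of the rasterized, averaged, normalized map."""
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    zs = grid.axis_centers(2)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    values = system.accessible(pts, margin=0.0).astype(float).reshape(grid.dims)
    return OccupancyMap(grid=grid, values=values, stage=Stage.NORMALIZED)


# ---------------------------------------------------------------------------
# file output


def synthetic_species_rules(bead_radius: float | None = None) -> SpeciesRules:
    """The species/charge/radius rules matching generator output; pass the
    actual obstruction bead radius when one was inserted."""
    from importlib import resources

    with resources.files("poreclog.data").joinpath("synthetic_species.yaml").open() as fh:
        import yaml

        cfg = yaml.safe_load(fh)
    if bead_radius is not None:
        cfg["radii"]["by_name"]["BD"] = max(float(bead_radius), 1e-6)
    return SpeciesRules.from_mapping(cfg)


def write_trajectory(trajectory: Trajectory, pdb_path: str | Path, dcd_path: str | Path) -> None:
    """Write topology as PDB and frames as DCD (MDAnalysis writers)."""
    import MDAnalysis as mda

    n = trajectory.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in trajectory.topology])
    u.add_TopologyAttr("resnames", [a.residue for a in trajectory.topology])
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = trajectory.coords[0]
    u.dimensions = [*trajectory.boxes[0], 90.0, 90.0, 90.0]
    u.atoms.write(str(pdb_path))
    with mda.Writer(str(dcd_path), n_atoms=n) as writer:
        for i in range(trajectory.n_frames):
            u.atoms.positions = trajectory.coords[i]
            u.dimensions = [*trajectory.boxes[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.dt = trajectory.frame_interval
            writer.write(u.atoms)


def write_ground_truth(system: SyntheticSystem, spec: ElectrolyteSpec | None, path: str | Path) -> None:
    """JSON sidecar with the geometry, seeds and analytic ground truth."""
    g = system.geometry
    zs = np.arange(0.5, g.length, 1.0)
    payload = {
        "shape": g.shape.value,
        "radius": g.radius,
        "length": g.length,
        "radius_waist": g.radius_waist,
        "wall_sphere_radius": g.wall_sphere_radius,
        "pocket": None if g.pocket is None else vars(g.pocket) | {},
        "obstruction": None if system.obstruction is None else {
            "bead_radius": system.obstruction.bead_radius,
            "z_lo": system.obstruction.z_lo,
            "z_hi": system.obstruction.z_hi,
            "n_beads": system.obstruction.n_beads,
        },
        "box": list(system.box),
        "analytic_area_z": zs.tolist(),
        "analytic_area": system.analytic_area(zs).tolist(),
        "analytic_resistance_rho1": system.analytic_resistance(),
        "electrolyte": None if spec is None else {
            **{k: getattr(spec, k) for k in (
                "n_water", "n_k", "n_cl", "drift_water", "drift_k", "drift_cl",
                "diffusion", "seed", "water_radius", "k_radius", "cl_radius")},
            "expected_drift_current_nA": expected_drift_current(system, spec),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
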