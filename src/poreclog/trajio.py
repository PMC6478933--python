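"""Trajectory input and the uniform in-memory frame model.

Topology (PDB) and coordinate frames (DCD/XTC) are read with MDAnalysis and
converted into a plain :class:`Trajectory` of numpy arrays plus per-atom
metadata. Species (water / K / Cl / peptide / pore / lipid), partial charges
and Van der Waals radii are assigned from a rule table rather than hard-coded,
because force-field naming dialects vary; radii missing from the table raise
rather than defaulting silently.

Units: Å for coordinates and radii, ps for times, elementary charges for q.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import FormatError, LookupTableError, ValidationError


class Species(enum.Enum):
    """Coarse atom classification used by selections throughout the package."""

    WATER = "WATER"
    ION_K = "ION_K"
    ION_CL = "ION_CL"
    PEPTIDE = "PEPTIDE"
    PORE = "PORE"
    LIPID = "LIPID"
    OTHER = "OTHER"


#: Species whose atoms constitute the electrolyte in occupancy maps.
ELECTROLYTE = frozenset({Species.WATER, Species.ION_K, Species.ION_CL})


@dataclass(frozen=True)
class AtomMeta:
    """Per-atom metadata: identity, species, charge (e) and VdW radius (Å)."""

    atom_id: int
    name: str
    residue: str
    species: Species
    charge: float
    vdw_radius: float
    mass: float = 1.0

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise ValidationError(
                f"atom {self.atom_id} ({self.name}): vdw_radius must be > 0, "
                f"got {self.vdw_radius}"
            )
        if not np.isfinite(self.charge):
            raise ValidationError(f"atom {self.atom_id}: non-finite charge")


@dataclass(frozen=True)
class Frame:
    """One snapshot: time (ps), (N, 3) coordinates (Å) and box lengths (Å)."""

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.box).shape != (3,) or not np.all(np.asarray(self.box) > 0):
            raise ValidationError(f"frame at t={self.time}: box must be 3 positive lengths")


@dataclass
class Trajectory:
    """An ordered stack of frames over a fixed topology.

    Coordinates are stored as one (n_frames, n_atoms, 3) array; ``frames``
    exposes lightweight per-frame views for code written against the frame
    model.
    """

    topology: list[AtomMeta]
    coords: np.ndarray           # (F, N, 3) Å
    boxes: np.ndarray            # (F, 3) Å
    times: np.ndarray            # (F,) ps
    frame_interval: float        # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise FormatError(
                f"coordinate frames carry {self.coords.shape[1]} atoms but the "
                f"topology defines {len(self.topology)}"
            )
        if self.boxes.shape != (self.n_frames, 3) or not np.all(self.boxes > 0):
            raise ValidationError("boxes must be (n_frames, 3) positive lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, self.frame_interval, rtol=1e-3, atol=1e-6):
                raise ValidationError(
                    "frame times are inconsistent with frame_interval "
                    f"({self.frame_interval} ps)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frames(self) -> list[Frame]:
        return [
            Frame(time=float(self.times[i]), coords=self.coords[i], box=self.boxes[i])
            for i in range(self.n_frames)
        ]

    @classmethod
    def from_frames(
        cls, topology: Sequence[AtomMeta], frames: Sequence[Frame], frame_interval: float | None = None
    ) -> "Trajectory":
        if not frames:
            raise ValidationError("at least one frame is required")
        times = np.array([f.time for f in frames], dtype=float)
        if frame_interval is None:
            if len(frames) < 2:
                raise ValidationError("frame_interval required for single-frame trajectories")
            frame_interval = float(times[1] - times[0])
        return cls(
            topology=list(topology),
            coords=np.stack([np.asarray(f.coords, dtype=float) for f in frames]),
            boxes=np.stack([np.asarray(f.box, dtype=float) for f in frames]),
            times=times,
            frame_interval=float(frame_interval),
        )

    def charges(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.topology if indices is None else [self.topology[i] for i in indices]
        return np.array([a.charge for a in atoms], dtype=float)

    def radii(self, indices: Sequence[int] | None = None) -> np.ndarray:
        atoms = self.topology if indices is None else [self.topology[i] for i in indices]
        return np.array([a.vdw_radius for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# species / radius / charge rule tables


def _as_set(values: Iterable[str] | None) -> frozenset[str]:
    return frozenset(str(v).upper() for v in (values or ()))


@dataclass
class SpeciesRules:
    """Classification and property-assignment rules loaded from YAML.

    Precedence for species: ion atom names, then water residues, then pore /
    peptide / lipid residues, else OTHER. Charges come from ``charges.by_name``
    with per-species fallbacks (K +1, Cl −1) and a configurable default of 0 e.
    Radii come from ``radii.by_name``, then ``radii.by_element`` keyed on the
    leading alphabetic character of the atom name; a miss raises.
    """

    water_residues: frozenset[str] = frozenset()
    ion_k_names: frozenset[str] = frozenset()
    ion_cl_names: frozenset[str] = frozenset()
    pore_residues: frozenset[str] = frozenset()
    peptide_residues: frozenset[str] = frozenset()
    lipid_residues: frozenset[str] = frozenset()
    charges_by_name: dict[str, float] = field(default_factory=dict)
    charge_default: float = 0.0
    radii_by_name: dict[str, float] = field(default_factory=dict)
    radii_by_element: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "SpeciesRules":
        sp = cfg.get("species", {})
        ch = cfg.get("charges", {})
        ra = cfg.get("radii", {})
        return cls(
            water_residues=_as_set(sp.get("water_residues")),
            ion_k_names=_as_set(sp.get("ion_k_names")),
            ion_cl_names=_as_set(sp.get("ion_cl_names")),
            pore_residues=_as_set(sp.get("pore_residues")),
            peptide_residues=_as_set(sp.get("peptide_residues")),
            lipid_residues=_as_set(sp.get("lipid_residues")),
            charges_by_name={str(k).upper(): float(v) for k, v in (ch.get("by_name") or {}).items()},
            charge_default=float(ch.get("default", 0.0)),
            radii_by_name={str(k).upper(): float(v) for k, v in (ra.get("by_name") or {}).items()},
            radii_by_element={str(k).upper(): float(v) for k, v in (ra.get("by_element") or {}).items()},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesRules":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    # -- assignment -------------------------------------------------------

    def classify(self, name: str, residue: str) -> Species:
        name_u, res_u = name.upper(), residue.upper()
        if name_u in self.ion_k_names:
            return Species.ION_K
        if name_u in self.ion_cl_names:
            return Species.ION_CL
        if res_u in self.water_residues:
            return Species.WATER
        if res_u in self.pore_residues:
            return Species.PORE
        if res_u in self.peptide_residues:
            return Species.PEPTIDE
        if res_u in self.lipid_residues:
            return Species.LIPID
        return Species.OTHER

    def charge(self, name: str, species: Species) -> float:
        name_u = name.upper()
        if name_u in self.charges_by_name:
            return self.charges_by_name[name_u]
        if species is Species.ION_K:
            return 1.0
        if species is Species.ION_CL:
            return -1.0
        return self.charge_default

    def radius(self, name: str) -> float:
        name_u = name.upper()
        if name_u in self.radii_by_name:
            return self.radii_by_name[name_u]
        element = next((c for c in name_u if c.isalpha()), "")
        if element in self.radii_by_element:
            return self.radii_by_element[element]
        raise LookupTableError(
            f"no VdW radius for atom name {name!r}: add it to radii.by_name or "
            f"radii.by_element in the species config"
        )


def default_radius_table() -> dict[str, float]:
    """Element-keyed VdW radii (Å) shipped with the package (Bondi-style)."""
    with resources.files("poreclog.data").joinpath("vdw_radii.yaml").open() as fh:
        return {str(k).upper(): float(v) for k, v in yaml.safe_load(fh).items()}


# ---------------------------------------------------------------------------
# loading


def load_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path,
    species_config: SpeciesRules | Mapping | str | Path,
    radius_table: Mapping[str, float] | None = None,
    frame_interval: float | None = None,
) -> Trajectory:
    """Read a PDB topology plus DCD/XTC frames into a :class:`Trajectory`.

    ``radius_table`` supplements ``radii.by_element`` of the rules (explicit
    by-name entries win). ``frame_interval`` (ps) overrides the file's frame
    spacing; DCD headers written by some engines carry dummy times.
    """
    import MDAnalysis as mda

    if isinstance(species_config, (str, Path)):
        rules = SpeciesRules.from_yaml(species_config)
    elif isinstance(species_config, SpeciesRules):
        rules = species_config
    else:
        rules = SpeciesRules.from_mapping(species_config)
    if radius_table:
        merged = dict(rules.radii_by_element)
        merged.update({str(k).upper(): float(v) for k, v in radius_table.items()})
        rules.radii_by_element = merged

    try:
        universe = mda.Universe(str(topology_path), str(trajectory_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read trajectory: {exc}") from exc

    atoms = universe.atoms
    topology: list[AtomMeta] = []
    for i, atom in enumerate(atoms):
        species = rules.classify(atom.name, atom.resname)
        topology.append(
            AtomMeta(
                atom_id=i,
                name=str(atom.name),
                residue=str(atom.resname),
                species=species,
                charge=rules.charge(atom.name, species),
                vdw_radius=rules.radius(atom.name),
                mass=float(getattr(atom, "mass", 1.0) or 1.0),
            )
        )

    coords, boxes, times = [], [], []
    for ts in universe.trajectory:
        if ts.positions.shape[0] != len(topology):
            raise FormatError(
                f"frame {ts.frame}: {ts.positions.shape[0]} atoms, topology has {len(topology)}"
            )
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise FormatError(f"frame {ts.frame}: missing or invalid box dimensions")
        coords.append(np.array(ts.positions, dtype=float))
        boxes.append(np.array(ts.dimensions[:3], dtype=float))
        times.append(float(ts.time))

    times_arr = np.asarray(times)
    if frame_interval is None:
        if len(times) > 1 and np.all(np.diff(times_arr) > 0):
            frame_interval = float(times_arr[1] - times_arr[0])
        else:
            raise ValidationError(
                "frame times are not usable; pass frame_interval explicitly"
            )
    else:
        # an explicit frame interval overrides file times, which many DCD
        # writers fill with dummy values
        times_arr = np.arange(len(times)) * frame_interval

    return Trajectory(
        topology=topology,
        coords=np.stack(coords),
        boxes=np.stack(boxes),
        times=times_arr,
        frame_interval=float(frame_interval),
    )


# ---------------------------------------------------------------------------
# selections


def _coerce_species(s: Species | str) -> Species:
    if isinstance(s, Species):
        return s
    try:
        return Species[str(s).upper()]
    except KeyError as exc:
        raise ValidationError(f"unknown species {s!r}") from exc


def select(trajectory: Trajectory, species_set: Iterable[Species | str]) -> list[int]:
    """Sorted indices of atoms whose species is in ``species_set``."""
    wanted = {_coerce_species(s) for s in species_set}
    if not wanted:
        raise ValidationError("species_set must be non-empty")
    return [a.atom_id for a in trajectory.topology if a.species in wanted]
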