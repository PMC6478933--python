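"""Amino-acid property tables, replica statistics and correlations.

This layer turns per-replica clogging / blockage numbers into the summary
quantities of the analysis: replica means with standard errors, Pearson
correlation and least-squares regression (clogging vs. blockage, clogging vs.
amino-acid volume), hydropathy-class contrasts (Welch's t-test), the
ion/water ratio inside the narrow pore region, the peptide radius of
gyration and its relaxation time, and the steered-MD displacement
arithmetic Δ = v·t.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, LookupTableError, ValidationError
from .trajio import Species, Trajectory, select
from .units import PS_PER_NS


class HydropathyClass(enum.Enum):
    HYDROPHOBIC = "HYDROPHOBIC"
    POLAR = "POLAR"
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class AminoAcidRecord:
    code: str
    name: str
    vdw_volume: float        # Å³, side-chain-inclusive VdW volume
    apparent_volume: float   # Å³, mean residue volume in folded proteins
    asa: float               # Å², accessible surface area in Gly-X-Gly
    hclass: HydropathyClass


_TABLE_CACHE: dict[str, pd.DataFrame] = {}


def aa_table(his_class: str | HydropathyClass = HydropathyClass.POLAR) -> pd.DataFrame:
    """The packaged 20-residue property table as a DataFrame (indexed by
    one-letter code). Histidine's class is configurable: it protonates near
    physiological pH and is assigned POLAR by default."""
    his = HydropathyClass(his_class.value if isinstance(his_class, HydropathyClass) else str(his_class).upper())
    key = his.value
    if key not in _TABLE_CACHE:
        with resources.files("poreclog.data").joinpath("amino_acids.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#").set_index("code")
        df.loc["H", "hclass"] = his.value
        _TABLE_CACHE[key] = df
    return _TABLE_CACHE[key].copy()


def aa_lookup(code: str, his_class: str | HydropathyClass = HydropathyClass.POLAR) -> AminoAcidRecord:
    """Record for a one-letter residue code (e.g. 'A' → Ala, 88.6 Å³)."""
    table = aa_table(his_class)
    code_u = str(code).upper()
    if code_u not in table.index:
        raise LookupTableError(f"unknown amino-acid code {code!r}")
    row = table.loc[code_u]
    return AminoAcidRecord(
        code=code_u,
        name=str(row["name"]),
        vdw_volume=float(row["vdw_volume"]),
        apparent_volume=float(row["apparent_volume"]),
        asa=float(row["asa"]),
        hclass=HydropathyClass(row["hclass"]),
    )


# ---------------------------------------------------------------------------
# replica aggregation


@dataclass
class ReplicaSet:
    """Per-replica scalars for one system, with mean and SEM = sd/√n.

    Independent replicas are treated as independent measurements; a single
    replica yields SEM 0 with ``single_replica`` flagged.
    """

    label: str
    values: np.ndarray
    mean: float = field(init=False)
    sem: float = field(init=False)
    single_replica: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("replica values must be a non-empty 1D sequence")
        self.mean = float(self.values.mean())
        self.single_replica = self.values.size == 1
        self.sem = 0.0 if self.single_replica else float(
            self.values.std(ddof=1) / np.sqrt(self.values.size)
        )
        if self.single_replica:
            warnings.warn(f"replica set {self.label!r} has n=1; SEM set to 0", stacklevel=2)

    @property
    def n(self) -> int:
        return int(self.values.size)


def replica_stats(values: Sequence[float], label: str = "") -> ReplicaSet:
    return ReplicaSet(label=label, values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# correlation / regression


@dataclass
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    n: int


def pearson_and_fit(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r plus least-squares slope/intercept (scipy.stats.linregress)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValidationError("at least 3 points are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant x or y: correlation undefined")
    fit = sps.linregress(x, y)
    return CorrelationResult(r=float(fit.rvalue), slope=float(fit.slope),
                             intercept=float(fit.intercept), n=int(x.size))


@dataclass
class ClassContrast:
    class_means: dict[str, float]
    class_a: str
    class_b: str
    mean_difference: float
    t_statistic: float
    p_value: float
    excluded: list[str]


def class_contrast(
    values_by_class: Mapping[str | HydropathyClass, Sequence[float]],
    class_a: str | HydropathyClass = HydropathyClass.HYDROPHOBIC,
    class_b: str | HydropathyClass = HydropathyClass.POLAR,
) -> ClassContrast:
    """Per-class means plus Welch's t-test between two chosen classes.

    Classes with fewer than two members are excluded (with a warning); the
    two contrasted classes must survive exclusion.
    """
    def _key(c):
        return c.value if isinstance(c, HydropathyClass) else str(c).upper()

    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for cls, vals in values_by_class.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            excluded.append(_key(cls))
            warnings.warn(f"class {_key(cls)} has < 2 members; excluded from contrast",
                          stacklevel=2)
            continue
        groups[_key(cls)] = arr
    ka, kb = _key(class_a), _key(class_b)
    if ka not in groups or kb not in groups:
        raise ValidationError(
            f"contrast requires classes {ka} and {kb} with >= 2 members each"
        )
    if len(groups) < 2:
        raise ValidationError("at least two classes with >= 2 members are required")
    welch = sps.ttest_ind(groups[ka], groups[kb], equal_var=False)
    return ClassContrast(
        class_means={k: float(v.mean()) for k, v in groups.items()},
        class_a=ka,
        class_b=kb,
        mean_difference=float(groups[ka].mean() - groups[kb].mean()),
        t_statistic=float(welch.statistic),
        p_value=float(welch.pvalue),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# trajectory-derived summaries


def ion_water_ratio(
    trajectory: Trajectory,
    z_range: tuple[float, float],
    axis_center: tuple[float, float] | None = None,
    lateral_radius: float | None = None,
) -> float:
    """Time-averaged (K + Cl count)/(water-molecule count) inside the narrow
    pore region: a z interval with an optional lateral disk about the axis.

    Waters are counted by oxygen atoms (one per molecule); the ratio is the
    ratio of the time-averaged counts.
    """
    z_lo, z_hi = z_range
    if not z_lo < z_hi:
        raise ValidationError(f"empty z_range {z_range}")
    if np.all((trajectory.boxes[:, 2] < z_lo) | (z_hi < 0)):
        raise ValidationError("pore region lies outside the box")
    ion_idx = np.asarray(select(trajectory, {Species.ION_K, Species.ION_CL}), dtype=int)
    water_idx = np.asarray(
        [a.atom_id for a in trajectory.topology
         if a.species is Species.WATER and a.name.upper().startswith("O")],
        dtype=int,
    )
    if water_idx.size == 0:  # single-bead synthetic waters may not be O-named
        water_idx = np.asarray(select(trajectory, {Species.WATER}), dtype=int)

    def _mean_count(idx: np.ndarray) -> float:
        if idx.size == 0:
            return 0.0
        pos = trajectory.coords[:, idx, :]
        inside = (pos[:, :, 2] >= z_lo) & (pos[:, :, 2] < z_hi)
        if lateral_radius is not None:
            cx, cy = axis_center if axis_center is not None else (0.0, 0.0)
            inside &= (pos[:, :, 0] - cx) ** 2 + (pos[:, :, 1] - cy) ** 2 <= lateral_radius**2
        return float(inside.sum(axis=1).mean())

    waters = _mean_count(water_idx)
    if waters == 0:
        raise DegenerateInputError("no water molecules inside the region in any frame")
    return _mean_count(ion_idx) / waters


def radius_of_gyration(
    trajectory: Trajectory, atom_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted radius of gyration per frame: (times ps, Rg Å)."""
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size < 1:
        raise ValidationError("at least one atom is required")
    masses = np.array([trajectory.topology[i].mass for i in idx], dtype=float)
    pos = trajectory.coords[:, idx, :]
    com = (masses[None, :, None] * pos).sum(axis=1) / masses.sum()
    d2 = ((pos - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt((masses[None, :] * d2).sum(axis=1) / masses.sum())
    return trajectory.times.copy(), rg


def relaxation_time(
    times: np.ndarray,
    series: np.ndarray,
    band: float = 0.05,
    tail_fraction: float = 0.25,
) -> float:
    """First time after which the series stays within ±``band`` (relative) of
    its tail mean — a pragmatic equilibration estimate for Rg traces."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times.shape != series.shape or times.size < 2:
        raise ValidationError("times and series must be equal-length with >= 2 samples")
    n_tail = max(2, int(round(times.size * tail_fraction)))
    tail_mean = float(series[-n_tail:].mean())
    if tail_mean == 0:
        raise DegenerateInputError("tail mean is zero; relative band undefined")
    inside = np.abs(series - tail_mean) <= band * abs(tail_mean)
    # last index that is outside the band; relaxation is the next sample
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return float(times[0])
    if outside[-1] == times.size - 1:
        raise DegenerateInputError("series never settles inside the band")
    return float(times[outside[-1] + 1])


def smd_displacement(v_smd: float, t_smd_ns: float) -> float:
    """Pulled-atom displacement Δ = v·t for constant-velocity steering,
    with v in Å/ps and t in ns; returns Å."""
    if not (v_smd > 0 and t_smd_ns > 0):
        raise ValidationError("v_smd and t_smd must be > 0")
    return v_smd * t_smd_ns * PS_PER_NS
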