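"""Quasi-1D pore resistance and the pore-clogging estimator.

In a quasi-1D continuum picture the resistance of a pore spanning z in
[0, L] is R = ∫ ρ(z)/A(z) dz, with ρ the electrolyte resistivity and A(z)
the cross-section available to the electrolyte (access resistance neglected).
On a grid the available area per slice is A_z = Σ_{x,y} M̃_{x,y,z} Δx Δy —
fractional occupancies contribute fractionally — and the resistance becomes
the slice sum R̃ = Σ ρ Δz / A_z. The clogging estimator

    b = 1 − R̃₀ / R̃

compares the obstructed pore (R̃) with the empty one (R̃₀): b = 0 when
nothing changed, b → 1 when a slice is completely blocked. b is independent
of ρ, so ρ defaults to 1 (arbitrary units); supply the electrolyte's actual
resistivity only if absolute resistances are wanted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .channel import ChannelMap
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AreaProfile:
    """Available cross-section per z slice: centers ``z`` (Å), areas (Å²)
    and the slice width ``dz`` (Å). Slice i covers [z_i − dz/2, z_i + dz/2)."""

    z: np.ndarray
    area: np.ndarray
    dz: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.z.shape != self.area.shape or self.z.ndim != 1 or self.z.size == 0:
            raise ValidationError("z and area must be equal-length non-empty 1D arrays")
        if np.any(self.area < 0):
            raise ValidationError("areas must be >= 0")
        if not self.dz > 0:
            raise ValidationError("dz must be > 0")
        if self.z.size > 1 and not np.allclose(np.diff(self.z), self.dz, rtol=1e-6, atol=1e-9):
            raise ValidationError("slices must be contiguous with spacing dz")

    def restrict(self, z_range: tuple[float, float]) -> "AreaProfile":
        z_lo, z_hi = z_range
        if not z_lo < z_hi:
            raise ValidationError(f"empty z_range {z_range}")
        keep = (self.z >= z_lo) & (self.z < z_hi)
        if not keep.any():
            raise ValidationError(f"z_range {z_range} selects no slices")
        return AreaProfile(z=self.z[keep], area=self.area[keep], dz=self.dz)


@dataclass(frozen=True)
class ResistanceModel:
    """ρ (resistivity, arbitrary units by default) and the summation window."""

    rho: float = 1.0
    z_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValidationError("rho must be > 0")
        if self.z_range is not None and not self.z_range[0] < self.z_range[1]:
            raise ValidationError(f"invalid z_range {self.z_range}")


@dataclass
class CloggingResult:
    R_tilde: float
    R0_tilde: float
    b: float
    blocked: bool = False
    anomalous: bool = False


def area_profile(channel_map: ChannelMap, z_range: tuple[float, float] | None = None) -> AreaProfile:
    """A_z = Σ_{x,y} M̃ Δx Δy per slice, optionally restricted to z_range."""
    grid = channel_map.grid
    areas = channel_map.values.sum(axis=(0, 1)) * grid.cell[0] * grid.cell[1]
    profile = AreaProfile(z=grid.z_centers, area=areas, dz=grid.cell[2])
    return profile if z_range is None else profile.restrict(z_range)


def quasi1d_resistance(profile: AreaProfile, model: ResistanceModel = ResistanceModel()) -> float:
    """R̃ = Σ ρ Δz / A_z; +inf (BLOCKED) when any slice has zero area."""
    prof = profile if model.z_range is None else profile.restrict(model.z_range)
    if np.any(prof.area == 0):
        logger.info("pore BLOCKED: %d slice(s) with zero available area", int((prof.area == 0).sum()))
        return math.inf
    return float(np.sum(model.rho * prof.dz / prof.area))


def clogging_estimator(R_clogged: float, R_empty: float) -> CloggingResult:
    """b = 1 − R̃₀/R̃; a BLOCKED (infinite) clogged resistance gives b = 1."""
    if not (R_empty > 0 and R_clogged > 0):
        raise ValidationError("resistances must be positive")
    if math.isinf(R_clogged):
        return CloggingResult(R_tilde=R_clogged, R0_tilde=R_empty, b=1.0, blocked=True)
    b = 1.0 - R_empty / R_clogged
    anomalous = b < 0
    if anomalous:
        logger.warning("anomalous clogging b=%.4g < 0 (empty pore resists more)", b)
    return CloggingResult(R_tilde=R_clogged, R0_tilde=R_empty, b=b, anomalous=anomalous)


def clogging_from_profiles(
    profile_clogged: AreaProfile,
    profile_empty: AreaProfile,
    model: ResistanceModel = ResistanceModel(),
) -> CloggingResult:
    return clogging_estimator(
        quasi1d_resistance(profile_clogged, model), quasi1d_resistance(profile_empty, model)
    )


def truncated_clogging(
    profile_clogged: AreaProfile,
    profile_empty: AreaProfile,
    model: ResistanceModel = ResistanceModel(),
    z_cut_offset: float = 20.0,
) -> CloggingResult:
    """Clogging of a trans-truncated pore: both resistances are re-summed
    starting ``z_cut_offset`` Å (default 20) above the trans entrance, which
    drops the barrel section below the cut (secondary-constriction removal)."""
    if z_cut_offset < 0:
        raise ValidationError("z_cut_offset must be >= 0")
    z_lo, z_hi = model.z_range if model.z_range is not None else (
        float(profile_empty.z[0] - profile_empty.dz / 2),
        float(profile_empty.z[-1] + profile_empty.dz / 2),
    )
    if not z_lo + z_cut_offset < z_hi:
        raise ValidationError(
            f"z_cut_offset {z_cut_offset} Å leaves no pore in [{z_lo}, {z_hi}] Å"
        )
    cut_model = ResistanceModel(rho=model.rho, z_range=(z_lo + z_cut_offset, z_hi))
    return clogging_from_profiles(profile_clogged, profile_empty, cut_model)
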