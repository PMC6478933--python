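"""Displacement-based ionic current, mean current and blockage.

The average current in a window [t, t+Δt] is estimated from charge
displacement along the pore axis,

    I(t) = 1/(Δt L_z) Σ_i q_i [z_i(t+Δt) − z_i(t)],

summed over the selected atoms, with q_i in elementary charges, z in Å, Δt in
ps and L_z the box height. Δz is minimum-image unwrapped by default — at
typical frame spacings an ion crossing the periodic boundary would otherwise
register a spurious ~L_z displacement. Output is in nA.

Window currents are autocorrelated, so the standard error of the mean current
uses block averaging (default 8 ns blocks); a transient can be discarded
before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .trajio import Species, Trajectory, select
from .units import E_PER_PS_TO_NA


@dataclass
class CurrentTrace:
    """Per-window current: window start times (ps), I (nA), window Δt (ps),
    per-window L_z (Å) and a species label."""

    times: np.ndarray
    current: np.ndarray
    window: float
    Lz: np.ndarray
    species: str = "TOTAL"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.Lz = np.asarray(self.Lz, dtype=float)
        if not self.window > 0:
            raise ValidationError("window must be > 0")
        if self.times.shape != self.current.shape or self.times.shape != self.Lz.shape:
            raise ValidationError("times, current and Lz must have identical shapes")

    @property
    def duration(self) -> float:
        return float(self.times.size * self.window)


@dataclass
class MeanCurrent:
    mean: float
    se: float
    n_windows: int
    n_blocks: int


@dataclass
class BlockageResult:
    I_mean: float
    I0_mean: float
    blockage: float


def displacement_current(
    trajectory: Trajectory,
    atom_indices: Sequence[int],
    unwrap: bool = True,
    species_label: str = "TOTAL",
    use_mean_box: bool = False,
) -> CurrentTrace:
    """Windowed displacement current over consecutive frame pairs.

    L_z is taken per pair from the first frame's box (NPT boxes fluctuate);
    ``use_mean_box`` switches to the trajectory-mean box height.
    """
    if trajectory.n_frames < 2:
        raise ValidationError("at least two frames are required")
    idx = np.asarray(atom_indices, dtype=int)
    dt = trajectory.frame_interval
    times = trajectory.times[:-1]
    if use_mean_box:
        lz = np.full(times.shape, trajectory.boxes[:, 2].mean())
    else:
        lz = trajectory.boxes[:-1, 2]

    if idx.size == 0:
        return CurrentTrace(times=times, current=np.zeros_like(times), window=dt, Lz=lz,
                            species=species_label)

    q = trajectory.charges(idx)
    if not np.all(np.isfinite(q)):
        raise ValidationError("selected atoms carry non-finite charges")
    z = trajectory.coords[:, idx, 2]
    dz = np.diff(z, axis=0)                       # (F-1, n)
    if unwrap:
        dz = dz - lz[:, None] * np.round(dz / lz[:, None])
    current = (dz @ q) / (dt * lz) * E_PER_PS_TO_NA
    return CurrentTrace(times=times, current=current, window=dt, Lz=lz, species=species_label)


def species_current(
    trajectory: Trajectory, species: Species | str, unwrap: bool = True
) -> CurrentTrace:
    """Displacement current restricted to one species (e.g. K or Cl)."""
    name = species.name if isinstance(species, Species) else str(species).upper()
    idx = select(trajectory, {name})
    label = {"ION_K": "K", "ION_CL": "CL"}.get(name, name)
    return displacement_current(trajectory, idx, unwrap=unwrap, species_label=label)


def mean_current(trace: CurrentTrace, discard: float = 0.0, block: float = 8000.0) -> MeanCurrent:
    """Time-average of I(t) over windows starting at t ≥ ``discard`` (ps),
    with a block-averaged standard error (block length in ps)."""
    keep = trace.times >= trace.times[0] + discard if trace.times.size else np.array([], bool)
    values = trace.current[keep]
    if values.size == 0:
        raise ValidationError(
            f"discard {discard} ps leaves no windows (duration {trace.duration} ps)"
        )
    mean = float(values.mean())
    if values.size == 1:
        return MeanCurrent(mean=mean, se=0.0, n_windows=1, n_blocks=1)
    per_block = max(1, int(round(block / trace.window)))
    n_blocks = values.size // per_block
    if n_blocks >= 2:
        block_means = values[: n_blocks * per_block].reshape(n_blocks, per_block).mean(axis=1)
        se = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    else:
        # fewer than two blocks: fall back to the naive (correlation-blind) SE
        n_blocks = values.size
        se = float(values.std(ddof=1) / np.sqrt(values.size))
    return MeanCurrent(mean=mean, se=se, n_windows=int(values.size), n_blocks=int(n_blocks))


def blockage(I_mean: float, I0_mean: float) -> BlockageResult:
    """ΔI/I₀ = (I₀ − I)/I₀ relative to the empty-pore current I₀."""
    if I0_mean == 0:
        raise DegenerateInputError("reference current I0 is zero")
    return BlockageResult(I_mean=float(I_mean), I0_mean=float(I0_mean),
                          blockage=float((I0_mean - I_mean) / I0_mean))
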