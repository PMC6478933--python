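"""HDF5 serialization of occupancy maps, masks and channel maps, plus TSV
export of profiles and current traces."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .channel import AccessibilityMask, ChannelMap, Direction
from .conductance import AreaProfile
from .current import CurrentTrace
from .errors import FormatError
from .occupancy import GridSpec, OccupancyMap, Stage


def _write_grid(group: h5py.Group, grid: GridSpec) -> None:
    group.attrs["origin"] = grid.origin
    group.attrs["cell"] = grid.cell
    group.attrs["dims"] = grid.dims


def _read_grid(group: h5py.Group) -> GridSpec:
    try:
        return GridSpec(
            origin=tuple(group.attrs["origin"]),
            cell=tuple(group.attrs["cell"]),
            dims=tuple(int(d) for d in group.attrs["dims"]),
        )
    except KeyError as exc:
        raise FormatError(f"missing grid metadata in HDF5 file: {exc}") from exc


def save_map(path: str | Path, occupancy_map: OccupancyMap, bulk_value: float | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=occupancy_map.values, compression="gzip")
        fh.attrs["stage"] = occupancy_map.stage.value
        if bulk_value is not None:
            fh.attrs["bulk_value"] = float(bulk_value)
        _write_grid(fh, occupancy_map.grid)


def load_map(path: str | Path) -> OccupancyMap:
    with h5py.File(path, "r") as fh:
        return OccupancyMap(
            grid=_read_grid(fh),
            values=np.array(fh["values"]),
            stage=Stage(fh.attrs["stage"]),
        )


def save_channel(path: str | Path, channel_map: ChannelMap,
                 masks: dict[str, AccessibilityMask] | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=channel_map.values, compression="gzip")
        _write_grid(fh, channel_map.grid)
        for name, mask in (masks or {}).items():
            ds = fh.create_dataset(f"mask_{name}", data=mask.mask, compression="gzip")
            ds.attrs["direction"] = mask.direction.value


def load_channel(path: str | Path) -> ChannelMap:
    with h5py.File(path, "r") as fh:
        return ChannelMap(grid=_read_grid(fh), values=np.array(fh["values"]))


def load_channel_masks(path: str | Path) -> dict[str, AccessibilityMask]:
    masks = {}
    with h5py.File(path, "r") as fh:
        grid = _read_grid(fh)
        for key in fh:
            if key.startswith("mask_"):
                masks[key[5:]] = AccessibilityMask(
                    grid=grid,
                    mask=np.array(fh[key], dtype=bool),
                    direction=Direction(fh[key].attrs["direction"]),
                )
    return masks


def profile_to_tsv(path: str | Path, profile: AreaProfile) -> None:
    """TSV columns: z (Å), A_z (Å²), inv_A (Å⁻², inf on blocked slices)."""
    with np.errstate(divide="ignore"):
        inv = np.where(profile.area > 0, 1.0 / np.where(profile.area > 0, profile.area, 1.0), np.inf)
    pd.DataFrame({"z": profile.z, "A_z": profile.area, "inv_A": inv}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def traces_to_tsv(path: str | Path, traces: list[CurrentTrace]) -> None:
    """TSV of window start times plus one I column (nA) per trace species."""
    data = {"t": traces[0].times}
    for tr in traces:
        data[f"I_{tr.species}"] = tr.current
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.8g")
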