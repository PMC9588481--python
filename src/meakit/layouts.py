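"""Plate/electrode layouts for the supported MEA formats.

Four presets are supported: the single-well 60- and 120-channel layouts and
the 12- and 24-well multiwell plates with 12 electrodes per well.  Channel
labels follow the vendor conventions loosely: single-well electrodes are
named by their column-row grid position ("12" ... "87"), multiwell electrodes
as "<well>-<electrode>" (e.g. "A1-07").
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChannelLayout:
    """Immutable description of an electrode layout.

    Attributes
    ----------
    name : preset name.
    wells : number of wells (1 for single-well arrays).
    channels_per_well : electrodes per well.
    channel_ids : all channel labels, in a stable order.
    well_of_channel : label -> well index (0-based).
    well_names : well labels ("well0" for single-well, "A1".. for plates).
    electrode_xy : label -> (col, row) grid coordinates within its well.
    """

    name: str
    wells: int
    channels_per_well: int
    channel_ids: tuple[str, ...]
    well_of_channel: dict[str, int] = field(repr=False)
    well_names: tuple[str, ...] = ()
    electrode_xy: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.wells < 1:
            raise ValueError("layout needs at least one well")
        if self.wells * self.channels_per_well != len(self.channel_ids):
            raise ValueError(
                "wells x channels_per_well must equal the total channel count"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def channels_of_well(self, well: int) -> list[str]:
        return [c for c in self.channel_ids if self.well_of_channel[c] == well]


def _single_well_grid(name: str, side_cols: int, side_rows: int, skip_corners: bool):
    """Square grid, column-row labels, corners optionally absent (MCS style)."""
    ids, xy = [], {}
    corners = {
        (1, 1),
        (1, side_rows),
        (side_cols, 1),
        (side_cols, side_rows),
    }
    for col in range(1, side_cols + 1):
        for row in range(1, side_rows + 1):
            if skip_corners and (col, row) in corners:
                continue
            label = f"{col}{row}" if side_cols < 10 else f"E{col:02d}{row:02d}"
            ids.append(label)
            xy[label] = (col - 1, row - 1)
    return ChannelLayout(
        name=name,
        wells=1,
        channels_per_well=len(ids),
        channel_ids=tuple(ids),
        well_of_channel={c: 0 for c in ids},
        well_names=("well0",),
        electrode_xy=xy,
    )


def _multiwell(name: str, well_rows: int, well_cols: int):
    """Multiwell plate, 12 electrodes per well on a 4x3 grid."""
    ids: list[str] = []
    well_of: dict[str, int] = {}
    xy: dict[str, tuple[int, int]] = {}
    wells: list[str] = []
    widx = 0
    for r in range(well_rows):
        for c in range(well_cols):
            well = f"{string.ascii_uppercase[r]}{c + 1}"
            wells.append(well)
            for e in range(12):
                label = f"{well}-{e + 1:02d}"
                ids.append(label)
                well_of[label] = widx
                xy[label] = (e % 3, e // 3)
            widx += 1
    return ChannelLayout(
        name=name,
        wells=well_rows * well_cols,
        channels_per_well=12,
        channel_ids=tuple(ids),
        well_of_channel=well_of,
        well_names=tuple(wells),
        electrode_xy=xy,
    )


_PRESETS = {
    "single-60": lambda: _single_well_grid("single-60", 8, 8, skip_corners=True),
    "single-120": lambda: _single_well_grid("single-120", 12, 10, skip_corners=False),
    "multiwell-12x12": lambda: _multiwell("multiwell-12x12", 3, 4),
    "multiwell-24x12": lambda: _multiwell("multiwell-24x12", 4, 6),
}


def get_layout(name: str) -> ChannelLayout:
    """Return a preset layout by name.

    Supported presets: ``single-60``, ``single-120``, ``multiwell-12x12``,
    ``multiwell-24x12`` (the last has 288 electrodes in 24 wells).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown layout {name!r}; supported: {sorted(_PRESETS)}"
        ) from None
    return factory()


def layout_names() -> list[str]:
    return sorted(_PRESETS)
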