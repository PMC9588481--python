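"""File input/output: recording HDF5, timestamp CSV, tabular exports.

HDF5 schema (converter-shaped, documented here and written by
:mod:`meakit.synth`):

* ``/meta/sample_rate_hz`` — scalar dataset (Hz)
* ``/meta/layout``         — string dataset, a layout preset name
* ``/wells/<well>/channels/<label>/voltage_uv`` — 1-D float trace (uV)

Timestamp CSV dialects:

* generic long format — header ``well,channel,time_s``; optional
  ``# duration_s=<float>`` comment line before the header
* Axion-style — header starting ``Time (s),Electrode``; electrode labels
  like ``A1_11`` are mapped to ``A1-11``
"""

from __future__ import annotations

import os
from collections import defaultdict

import h5py
import numpy as np
import pandas as pd

from meakit.containers import Recording, SpikeTrain, SpikeTrainSet
from meakit.layouts import ChannelLayout, get_layout


class FormatError(ValueError):
    """Raised when an input file does not conform to a documented layout."""


def read_recording_hdf5(path: str | os.PathLike) -> Recording:
    """Read a recording from the documented HDF5 layout.

    Channels missing from the file are simply absent from ``traces``.
    Raises :class:`FormatError` naming the missing dataset path when a
    required group or dataset is absent.
    """
    with h5py.File(path, "r") as f:
        for req in ("/meta/sample_rate_hz", "/meta/layout", "/wells"):
            if req not in f:
                raise FormatError(f"{path}: missing required HDF5 path {req}")
        sample_rate = float(f["/meta/sample_rate_hz"][()])
        if sample_rate <= 0:
            raise ValueError(f"{path}: sample_rate must be positive, got {sample_rate}")
        layout_name = f["/meta/layout"][()]
        if isinstance(layout_name, bytes):
            layout_name = layout_name.decode()
        layout = get_layout(str(layout_name))
        traces: dict[str, np.ndarray] = {}
        n = None
        for well in f["/wells"]:
            chans = f[f"/wells/{well}/channels"]
            for label in chans:
                if label not in layout.channel_ids:
                    raise FormatError(
                        f"{path}: channel {label!r} not in layout {layout.name}"
                    )
                tr = np.asarray(chans[f"{label}/voltage_uv"], dtype=float)
                if n is None:
                    n = len(tr)
                elif len(tr) != n:
                    raise FormatError(f"{path}: unequal trace lengths")
                traces[label] = tr
    if n is None:
        raise FormatError(f"{path}: no channel traces found under /wells")
    duration = n / sample_rate
    return Recording(
        layout=layout,
        sample_rate=sample_rate,
        duration=duration,
        traces=traces,
        source_path=str(path),
    )


def _axion_to_label(electrode: str) -> str:
    return electrode.strip().replace("_", "-")


def read_spike_csv(path: str | os.PathLike, layout: ChannelLayout) -> SpikeTrainSet:
    """Read pre-detected spike timestamps from either documented CSV dialect.

    Duration is taken from a ``# duration_s=`` header when present, otherwise
    the maximum time rounded up to the next whole second.  Times within a
    channel are returned sorted.
    """
    duration_hint = None
    header_line = None
    data_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.startswith("duration_s="):
                duration_hint = float(body.split("=", 1)[1])
            continue
        header_line = s
        data_start = i + 1
        break
    if header_line is None:
        return SpikeTrainSet(layout=layout, duration=duration_hint or 0.0)

    cols = [c.strip().lower() for c in header_line.split(",")]
    per_channel: dict[str, list[float]] = defaultdict(list)

    if cols[:3] == ["well", "channel", "time_s"]:
        seen_header = 1
        for line in lines[data_start:]:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = [p.strip() for p in s.split(",")]
            if [p.lower() for p in parts[:3]] == ["well", "channel", "time_s"]:
                seen_header += 1
                if seen_header > 1:
                    raise FormatError(f"{path}: duplicate header row")
            if len(parts) < 3:
                raise FormatError(f"{path}: malformed row {s!r}")
            _, channel, t = parts[0], parts[1], float(parts[2])
            per_channel[channel].append(t)
    elif cols[0].startswith("time") and any(c.startswith("electrode") for c in cols):
        elec_idx = next(i for i, c in enumerate(cols) if c.startswith("electrode"))
        for line in lines[data_start:]:
            s = line.strip()
            if not s:
                continue
            parts = [p.strip() for p in s.split(",")]
            t = float(parts[0])
            channel = _axion_to_label(parts[elec_idx])
            per_channel[channel].append(t)
    else:
        raise FormatError(
            f"{path}: unrecognized CSV header {header_line!r}; expected "
            "'well,channel,time_s' or an Axion-style 'Time (s),Electrode' header"
        )

    unknown = sorted(set(per_channel) - set(layout.channel_ids))
    if unknown:
        raise ValueError(f"{path}: unknown channel labels {unknown}")

    max_t = max((max(v) for v in per_channel.values()), default=0.0)
    duration = duration_hint if duration_hint is not None else float(np.ceil(max_t))
    trains = {
        ch: SpikeTrain(channel_id=ch, times=np.unique(np.asarray(ts, dtype=float)))
        for ch, ts in per_channel.items()
    }
    return SpikeTrainSet(layout=layout, duration=duration, trains=trains)


def write_spike_csv(tset: SpikeTrainSet, path: str | os.PathLike) -> None:
    """Write a train set in the generic long CSV dialect (with duration header)."""
    rows = []
    for ch in tset.layout.channel_ids:
        if ch not in tset.trains:
            continue
        well = tset.layout.well_names[tset.layout.well_of_channel[ch]]
        for t in tset.trains[ch].times:
            rows.append((well, ch, t))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# duration_s={float(tset.duration)!r}\n")
        fh.write("well,channel,time_s\n")
        for well, ch, t in rows:
            fh.write(f"{well},{ch},{float(t)!r}\n")


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a rectangular table as UTF-8 CSV with a header row.

    Numeric cells are written at full precision ('.' decimal separator);
    missing values render as empty cells.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    table.to_csv(path, index=False, float_format=None, encoding="utf-8")
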