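"""HDF5 session containers and CSV cue export.

One file per recording session: ``/emg`` (channels x samples), ``/glove``
(18 x samples), ``/cues`` (label, onset, offset, block), ``/latencies``
and sleeve-layout metadata, so a simulated session round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simdata import (
    CueEvent,
    CueSchedule,
    EMGRecording,
    GloveTrack,
    SleeveLayout,
    TrialLatencies,
)


def save_session(
    path: str | Path,
    rec: EMGRecording,
    glove: GloveTrack,
    schedule: CueSchedule,
    latencies: TrialLatencies | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("emg", data=rec.signal, compression="gzip")
        d.attrs["fs_hz"] = rec.fs_hz
        d.attrs["t0"] = rec.t0
        g = f.create_dataset("glove", data=glove.sensors, compression="gzip")
        g.attrs["fs_hz"] = glove.fs_hz
        grp = f.create_group("cues")
        grp.attrs["paradigm"] = schedule.paradigm
        grp.create_dataset(
            "label", data=np.array([e.label for e in schedule.events], dtype="S64")
        )
        grp.create_dataset("onset_s", data=[e.onset_s for e in schedule.events])
        grp.create_dataset("offset_s", data=[e.offset_s for e in schedule.events])
        grp.create_dataset("block", data=np.asarray(schedule.block_ids))
        lay = f.create_group("layout")
        lay.attrs["size_tag"] = rec.layout.size_tag
        lay.attrs["n_channels"] = rec.layout.n_channels
        lay.create_dataset("grid_coords", data=rec.layout.grid_coords)
        if latencies is not None:
            lg = f.create_group("latencies")
            lg.create_dataset("event_indices", data=latencies.event_indices)
            lg.create_dataset("onset_delay_ms", data=latencies.onset_delay_ms)
            lg.create_dataset("offset_delay_ms", data=latencies.offset_delay_ms)


def load_session(
    path: str | Path,
) -> tuple[EMGRecording, GloveTrack, CueSchedule, TrialLatencies | None]:
    with h5py.File(path, "r") as f:
        lay = SleeveLayout(
            size_tag=f["layout"].attrs["size_tag"],
            n_channels=int(f["layout"].attrs["n_channels"]),
            grid_coords=f["layout/grid_coords"][...],
        )
        rec = EMGRecording(
            signal=f["emg"][...],
            fs_hz=float(f["emg"].attrs["fs_hz"]),
            layout=lay,
            t0=float(f["emg"].attrs["t0"]),
        )
        glove = GloveTrack(sensors=f["glove"][...], fs_hz=float(f["glove"].attrs["fs_hz"]))
        labels = [s.decode() for s in f["cues/label"][...]]
        events = [
            CueEvent(lab, float(on), float(off))
            for lab, on, off in zip(labels, f["cues/onset_s"][...], f["cues/offset_s"][...])
        ]
        schedule = CueSchedule(
            events=events,
            paradigm=f["cues"].attrs["paradigm"],
            block_ids=[int(b) for b in f["cues/block"][...]],
        )
        lat = None
        if "latencies" in f:
            lat = TrialLatencies(
                event_indices=f["latencies/event_indices"][...],
                onset_delay_ms=f["latencies/onset_delay_ms"][...],
                offset_delay_ms=f["latencies/offset_delay_ms"][...],
            )
    return rec, glove, schedule, lat


def export_cues_csv(path: str | Path, schedule: CueSchedule) -> None:
    pd.DataFrame(
        {
            "label": [e.label for e in schedule.events],
            "onset_s": [e.onset_s for e in schedule.events],
            "offset_s": [e.offset_s for e in schedule.events],
            "block": schedule.block_ids,
            "paradigm": schedule.paradigm,
        }
    ).to_csv(path, index=False)
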