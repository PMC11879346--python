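"""Disk round-trip for recordings and derived tables.

Recordings are stored as a float32 ``.npy`` signal array plus a JSON
sidecar (sampling rate, montage, block boundaries) and a BIDS-style
events TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .design import read_events_tsv, write_events_tsv
from .simulate import Montage, Recording


def save_recording(recording: Recording, prefix) -> list[Path]:
    """Write ``<prefix>_signal.npy``, ``<prefix>.json``,
    ``<prefix>_events.tsv``; returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig_path = prefix.with_name(prefix.name + "_signal.npy")
    np.save(sig_path, recording.signal.astype(np.float32))
    sidecar = {
        "subject_id": recording.subject_id,
        "srate": recording.srate,
        "block_bounds": [list(b) for b in recording.block_bounds],
        "montage": {
            "positions": {k: list(v)
                          for k, v in recording.montage.positions.items()},
            "cluster": list(recording.montage.cluster),
            "mastoids": list(recording.montage.mastoids),
        },
    }
    json_path = prefix.with_name(prefix.name + ".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    ev_path = prefix.with_name(prefix.name + "_events.tsv")
    write_events_tsv(recording.events, ev_path)
    return [sig_path, json_path, ev_path]


def load_recording(prefix) -> Recording:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_name(prefix.name + ".json").read_text())
    montage = Montage(
        positions={k: tuple(v)
                   for k, v in sidecar["montage"]["positions"].items()},
        cluster=tuple(sidecar["montage"]["cluster"]),
        mastoids=tuple(sidecar["montage"]["mastoids"]),
    )
    signal = np.load(prefix.with_name(prefix.name + "_signal.npy"))
    events = read_events_tsv(prefix.with_name(prefix.name + "_events.tsv"))
    return Recording(signal=signal.astype(np.float64), srate=sidecar["srate"],
                     montage=montage, events=events,
                     block_bounds=[tuple(b) for b in sidecar["block_bounds"]],
                     subject_id=sidecar["subject_id"])
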