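"""File I/O: EDF sessions, events tables, ERD/ERS map archives, model JSON.

Sessions persist as EDF (16-bit, one signal per electrode, physical
dimension microvolt) with a sidecar tab-separated events table; maps and
power arrays go to HDF5; models and statistics to JSON.  Writing EDF uses
a minimal single-purpose encoder (header + int16 data records per the EDF
specification); reading goes through :mod:`mne`, which independently
validates what the encoder produced.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erds import ERDSMap
from .montage import Montage, DEFAULT_MONTAGE
from .protocol import SessionSchedule, TrialTimeline, events_table, read_events
from .synth import EEGRecord

_EDF_DATE = "01.01.00"
_EDF_TIME = "00.00.00"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r}")
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _pad(s, width)


def write_edf(path, data_uv: np.ndarray, fs: float, labels: list[str],
              record_seconds: float = 1.0) -> None:
    """Write channels x samples microvolt data as a 16-bit EDF file.

    The signal is zero-padded to a whole number of data records.  Physical
    ranges are set per channel from the data extrema (symmetric), mapped
    onto the full digital range.
    """
    data_uv = np.asarray(data_uv, float)
    ns = len(labels)
    if data_uv.shape[0] != ns:
        raise ValueError("row count must match labels")
    spr = int(round(fs * record_seconds))
    n_rec = int(np.ceil(data_uv.shape[1] / spr))
    padded = np.zeros((ns, n_rec * spr))
    padded[:, : data_uv.shape[1]] = data_uv

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_max = 32767
    scaled = np.round(padded / phys_max[:, None] * dig_max).astype("<i2")

    header_bytes = 256 + 256 * ns
    head = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad(_EDF_DATE, 8),
        _pad(_EDF_TIME, 8),
        _num(header_bytes, 8),
        _pad("", 44),
        _num(n_rec, 8),
        _num(record_seconds, 8),
        _num(ns, 4),
    ])
    fields = [
        ("".join(_pad(lb, 16).decode() for lb in labels)),
        ("".join(_pad("AgAgCl electrode", 80).decode() for _ in labels)),
        ("".join(_pad("uV", 8).decode() for _ in labels)),
        ("".join(_num(-pm, 8).decode() for pm in phys_max)),
        ("".join(_num(pm, 8).decode() for pm in phys_max)),
        ("".join(_num(-dig_max, 8).decode() for _ in labels)),
        ("".join(_num(dig_max, 8).decode() for _ in labels)),
        ("".join(_pad("", 80).decode() for _ in labels)),
        ("".join(_num(spr, 8).decode() for _ in labels)),
        ("".join(_pad("", 32).decode() for _ in labels)),
    ]
    with open(path, "wb") as fh:
        fh.write(head)
        for f in fields:
            fh.write(f.encode("ascii"))
        # data records: per record, all samples of signal 1, then signal 2, ...
        for r in range(n_rec):
            block = scaled[:, r * spr : (r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf(path, montage: Montage = DEFAULT_MONTAGE) -> tuple[np.ndarray, float]:
    """Read an EDF file; returns (channels x samples microvolts, fs) with
    channels reordered to the canonical montage order."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [lb for lb in montage.labels if lb not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    raw.reorder_channels(list(montage.labels))
    return raw.get_data() * 1e6, float(raw.info["sfreq"])


def write_session(records: list[EEGRecord], edf_path, events_path,
                  schedule: SessionSchedule | None = None) -> None:
    """Persist a trial list as one continuous EDF plus an events TSV.

    Trials are laid back to back; the events table (derived from the trial
    timelines) carries the onsets needed to slice them out again.
    """
    if not records:
        raise ValueError("no records to write")
    fs = records[0].fs
    labels = list(records[0].labels)
    data = np.concatenate([r.data for r in records], axis=1)
    write_edf(edf_path, data, fs, labels)
    if schedule is not None:
        table = events_table(schedule)
    else:
        rows, t0 = [], 0.0
        for i, r in enumerate(records):
            tl = r.timeline or TrialTimeline()
            idx = r.trial_index if r.trial_index is not None else i
            rows += [
                (t0, tl.mi_onset, "rest", idx),
                (t0 + tl.beep_at, 0.0, "beep", idx),
                (t0 + tl.mi_onset, tl.arrow_duration, "cue", idx),
                (t0 + tl.mi_onset, tl.mi_end - tl.mi_onset, "mi", idx),
                (t0 + tl.actuation_resolution_at, tl.stop_screen_duration,
                 "stop", idx),
                (t0 + tl.relax_onset, tl.relax_duration, "relax", idx),
            ]
            t0 += tl.duration
        table = pd.DataFrame(rows, columns=["onset", "duration", "label",
                                            "trial_index"])
    table.to_csv(events_path, sep="\t", index=False)


def read_session(edf_path, events_path,
                 montage: Montage = DEFAULT_MONTAGE) -> list[EEGRecord]:
    """Load a session written by :func:`write_session` back into trials."""
    data, fs = read_edf(edf_path, montage)
    events = read_events(events_path)
    records = []
    for idx, g in events.groupby("trial_index", sort=True):
        rest = g[g.label == "rest"]
        relax = g[g.label == "relax"]
        if rest.empty or relax.empty:
            raise ValueError(f"trial {idx}: missing rest or relax event")
        onset = float(rest.onset.iloc[0])
        end = float(relax.onset.iloc[0] + relax.duration.iloc[0])
        i0, i1 = int(round(onset * fs)), int(round(end * fs))
        if i1 > data.shape[1]:
            raise ValueError(f"trial {idx} extends past the recording")
        tl = TrialTimeline(relax_duration=float(relax.duration.iloc[0]))
        records.append(
            EEGRecord(data[:, i0:i1], fs, montage.labels, tl,
                      trial_index=int(idx))
        )
    return records


def save_maps(path, stacks: dict[str, list[ERDSMap]], attrs: dict | None = None) -> None:
    """Save per-condition lists of participant maps into one HDF5 file."""
    with h5py.File(path, "w") as f:
        for cond, maps in stacks.items():
            g = f.create_group(cond)
            g.create_dataset("values", data=np.stack([m.values for m in maps]))
            g.create_dataset("freqs", data=maps[0].freqs)
            g.create_dataset("times", data=maps[0].times)
            g.attrs["labels"] = list(maps[0].labels)
            g.attrs["baseline"] = list(maps[0].baseline)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_maps(path) -> dict[str, list[ERDSMap]]:
    out: dict[str, list[ERDSMap]] = {}
    with h5py.File(path, "r") as f:
        for cond in f:
            g = f[cond]
            labels = tuple(str(x) for x in g.attrs["labels"])
            baseline = tuple(float(x) for x in g.attrs["baseline"])
            out[cond] = [
                ERDSMap(v, g["freqs"][...], g["times"][...], labels, baseline)
                for v in g["values"][...]
            ]
    return out


def file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
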