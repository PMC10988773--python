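"""Readers and writers: fixture container, TSV tables, plan sidecars, EDF/BDF.

The fixture container stores one recording as a raw little-endian float32
matrix (``<stem>.f32``, channels x samples, C order) plus a JSON sidecar
(``<stem>.json``) holding the sampling rate, channel names, markers and —
for synthetic data — the ground-truth injected responses.  Real EDF/BDF
files are read through MNE, with markers taken from annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusItem, StimulusSet, SequencePlan, TaskEvent
from .errors import ValidationError
from .spectral import AmplitudeSpectrum
from .synth import Recording

_FLOAT_FMT = "%.6g"


# -- fixture container -------------------------------------------------------

def write_recording(stem: str | Path, recording: Recording) -> Path:
    """Write a recording as <stem>.f32 + <stem>.json; returns the sidecar path."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(recording.data, dtype="<f4")
    data.tofile(stem.with_suffix(".f32"))
    sidecar = {
        "fs_hz": recording.fs_hz,
        "channel_names": recording.channel_names,
        "n_channels": recording.data.shape[0],
        "n_samples": recording.data.shape[1],
        "markers": [[int(s), lbl] for s, lbl in recording.markers],
        "ground_truth": recording.ground_truth,
    }
    path = stem.with_suffix(".json")
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_recording(stem: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    shape = (sidecar["n_channels"], sidecar["n_samples"])
    data = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").reshape(shape)
    return Recording(
        data=data.astype(float),
        fs_hz=float(sidecar["fs_hz"]),
        channel_names=list(sidecar["channel_names"]),
        markers=[(int(s), str(lbl)) for s, lbl in sidecar["markers"]],
        ground_truth=sidecar.get("ground_truth"),
    )


def read_raw_eeg(path: str | Path) -> Recording:
    """Read an EDF/BDF recording (markers from annotations) or a fixture stem."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_edf if suffix == ".edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        markers = [
            (int(round(onset * raw.info["sfreq"])), str(desc))
            for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        ]
        return Recording(data=data, fs_hz=float(raw.info["sfreq"]),
                         channel_names=list(raw.ch_names), markers=markers)
    return read_recording(path.with_suffix(""))


# -- stimulus lists ----------------------------------------------------------

def write_stimulus_set(path: str | Path, stimulus_set: StimulusSet) -> None:
    """Write a stimulus set as UTF-8 TSV (label, category, n_letters, attrs...)."""
    rows = []
    for it in stimulus_set:
        row = {"label": it.label, "category": it.category, "n_letters": it.n_letters}
        row.update(it.attributes or {})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_stimulus_set(path: str | Path, set_id: str | None = None) -> StimulusSet:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "category", "n_letters"):
        if col not in df.columns:
            raise ValidationError(f"stimulus TSV missing column {col!r}")
    attr_cols = [c for c in df.columns if c not in ("label", "category", "n_letters")]
    items = [
        StimulusItem(
            label=str(r["label"]), category=str(r["category"]),
            n_letters=int(r["n_letters"]),
            attributes={c: float(r[c]) for c in attr_cols} or None,
        )
        for _, r in df.iterrows()
    ]
    return StimulusSet(items, set_id=set_id or Path(path).stem)


# -- sequence plans ----------------------------------------------------------

def write_plan(path: str | Path, plan: SequencePlan) -> None:
    """Serialize a sequence plan (stream, events and all parameters) to JSON."""
    doc = {
        "base_rate_hz": plan.base_rate_hz,
        "oddball_every": plan.oddball_every,
        "duration_s": plan.duration_s,
        "fade_in_s": plan.fade_in_s,
        "fade_out_s": plan.fade_out_s,
        "control_type": plan.control_type,
        "discrimination": plan.discrimination,
        "task": plan.task,
        "seed": plan.seed,
        "meta": plan.meta,
        "stream": [
            {"onset_s": t, "label": it.label, "category": it.category,
             "n_letters": it.n_letters, "is_deviant": dev}
            for t, it, dev in plan.stream
        ],
        "events": [
            {"onset_s": e.onset_s, "duration_s": e.duration_s,
             "kind": e.kind, "is_go": e.is_go}
            for e in plan.events
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_plan(path: str | Path) -> SequencePlan:
    doc = json.loads(Path(path).read_text())
    stream = [
        (float(p["onset_s"]),
         StimulusItem(p["label"], p["category"], int(p["n_letters"])),
         bool(p["is_deviant"]))
        for p in doc["stream"]
    ]
    events = [
        TaskEvent(float(e["onset_s"]), float(e["duration_s"]),
                  str(e["kind"]), bool(e["is_go"]))
        for e in doc["events"]
    ]
    return SequencePlan(
        base_rate_hz=float(doc["base_rate_hz"]),
        oddball_every=int(doc["oddball_every"]),
        duration_s=float(doc["duration_s"]),
        fade_in_s=float(doc["fade_in_s"]),
        fade_out_s=float(doc["fade_out_s"]),
        control_type=str(doc["control_type"]),
        discrimination=str(doc["discrimination"]),
        stream=stream,
        task=str(doc["task"]),
        events=events,
        seed=int(doc["seed"]),
        meta=dict(doc.get("meta", {})),
    )


def write_events_tsv(path: str | Path, events: list[TaskEvent]) -> None:
    """BIDS-events-style table: onset, duration, kind."""
    pd.DataFrame(
        [{"onset": e.onset_s, "duration": e.duration_s, "kind": e.kind}
         for e in events]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events_tsv(path: str | Path) -> list[TaskEvent]:
    df = pd.read_csv(path, sep="\t")
    go_kinds = {"cross_change", "bars_both"}
    return [
        TaskEvent(float(r["onset"]), float(r["duration"]), str(r["kind"]),
                  str(r["kind"]) in go_kinds)
        for _, r in df.iterrows()
    ]


# -- spectra and result tables -----------------------------------------------

def spectrum_to_frame(spectrum: AmplitudeSpectrum) -> pd.DataFrame:
    """Long-format (channel, freq, amp) view of a spectrum."""
    n_ch, n_bins = spectrum.amps.shape
    return pd.DataFrame({
        "channel": np.repeat(spectrum.channel_names, n_bins),
        "freq": np.tile(spectrum.freqs, n_ch),
        "amp": spectrum.amps.ravel(),
    })


def write_spectrum_tsv(path: str | Path, spectrum: AmplitudeSpectrum) -> None:
    spectrum_to_frame(spectrum).to_csv(path, sep="\t", index=False,
                                       float_format=_FLOAT_FMT)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Tidy TSV export with stable float formatting (byte-reproducible)."""
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
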