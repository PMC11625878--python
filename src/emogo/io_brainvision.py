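"""BrainVision (.vhdr/.vmrk/.eeg) read and write, plus tidy-table I/O.

Reading goes through MNE's BrainVision reader; writing (needed for
synthetic fixtures) produces the standard triplet directly: an INI-style
header, a marker file, and IEEE float32 multiplexed binary data at 1 µV
resolution.

Marker coding (package convention, documented here because the original
recordings' scheme is not public): each stimulus marker is
``Stimulus / S<code>`` with

    code = 1000 * is_practice + 100 * condition + 10 * emotion + identity

where condition is 1 (Go) or 2 (NoGo), emotion is 1 (angry), 2 (neutral)
or 3 (happy), and identity indexes the face model list 1..8
(f1..f4, m1..m4).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from emogo.core import ChannelLayout, EventMarker, RawRecording, Span

_COND_CODE = {"Go": 1, "NoGo": 2}
_EMO_CODE = {"angry": 1, "neutral": 2, "happy": 3}
_IDENTITIES = ("f1", "f2", "f3", "f4", "m1", "m2", "m3", "m4")


def encode_marker(ev: EventMarker) -> int:
    try:
        ident = _IDENTITIES.index(ev.identity) + 1
    except ValueError:
        raise ValueError(f"unknown identity {ev.identity!r}") from None
    return (1000 if ev.is_practice else 0) + 100 * _COND_CODE[ev.condition] \
        + 10 * _EMO_CODE[ev.emotion] + ident


def decode_marker(code: int, sample: int, trial_id: int) -> EventMarker:
    is_practice = code >= 1000
    code %= 1000
    cond = {v: k for k, v in _COND_CODE.items()}.get(code // 100)
    emo = {v: k for k, v in _EMO_CODE.items()}.get((code // 10) % 10)
    ident_idx = code % 10
    if cond is None or emo is None or not 1 <= ident_idx <= len(_IDENTITIES):
        raise ValueError(f"undecodable stimulus code {code}")
    return EventMarker(sample=sample, trial_id=trial_id, condition=cond,
                       emotion=emo, identity=_IDENTITIES[ident_idx - 1],
                       is_practice=is_practice)


def write_brainvision(raw: RawRecording, path_base: str | Path) -> tuple[Path, Path, Path]:
    """Write ``<base>.vhdr/.vmrk/.eeg``; returns the three paths.

    Data are stored as IEEE float32, multiplexed, resolution 1 µV.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    names = raw.layout.retained

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Synthetic session written by emogo",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.rate:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(names)]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20240101120000000000",
    ]
    for k, ev in enumerate(sorted(raw.events, key=lambda e: e.sample)):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{k + 2}=Stimulus,S{encode_marker(ev):>3d},{ev.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    raw.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def read_brainvision(path: str | Path, layout: ChannelLayout | None = None) -> RawRecording:
    """Read a BrainVision triplet into a RawRecording (µV).

    Channels listed in ``layout.excluded`` are dropped if present.  Raises
    FileNotFoundError naming any missing companion file, and ValueError if
    a stimulus marker lies beyond the recording.
    """
    import mne

    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("expected a .vhdr header path")
    if not vhdr.exists():
        raise FileNotFoundError(f"missing header file: {vhdr}")
    header = vhdr.read_text(encoding="utf-8", errors="replace")
    for key in ("DataFile", "MarkerFile"):
        for line in header.splitlines():
            if line.startswith(key + "="):
                companion = vhdr.parent / line.split("=", 1)[1].strip()
                if not companion.exists():
                    raise FileNotFoundError(f"missing companion file: {companion}")

    mraw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")

    # MNE silently drops annotations beyond the data; validate positions here
    marker_path = None
    for line in header.splitlines():
        if line.startswith("MarkerFile="):
            marker_path = vhdr.parent / line.split("=", 1)[1].strip()
    if marker_path is not None:
        n_total = mraw.n_times
        for line in marker_path.read_text(encoding="utf-8", errors="replace").splitlines():
            if line.startswith("Mk") and "=Stimulus," in line:
                pos = int(line.split("=", 1)[1].split(",")[2])
                if pos - 1 >= n_total:   # positions are 1-based
                    raise ValueError(
                        f"stimulus marker at sample {pos - 1} beyond recording end {n_total}")
    layout = layout or ChannelLayout()
    drop = [ch for ch in mraw.ch_names if ch in layout.excluded]
    if drop:
        mraw.drop_channels(drop)
    order = [ch for ch in layout.retained if ch in mraw.ch_names]
    if list(mraw.ch_names) != order and set(order) == set(mraw.ch_names):
        mraw.reorder_channels(order)
    if set(mraw.ch_names) != set(layout.retained):
        layout = ChannelLayout(names=tuple(mraw.ch_names), excluded=frozenset(),
                               reference=layout.reference, ground=layout.ground)

    data_uv = mraw.get_data() * 1e6
    n = data_uv.shape[1]
    events: list[EventMarker] = []
    trial_id = 0
    for ann in mraw.annotations:
        desc = ann["description"]
        if not desc.startswith("Stimulus"):
            continue
        code = int(desc.split("S")[-1].strip())
        sample = int(round(ann["onset"] * mraw.info["sfreq"]))
        if sample >= n:
            raise ValueError(f"stimulus marker at sample {sample} beyond recording end {n}")
        events.append(decode_marker(code, sample, trial_id))
        trial_id += 1
    return RawRecording(data=data_uv, rate=float(mraw.info["sfreq"]),
                        layout=layout, events=events)


# ---------------------------------------------------------------------------
# tidy tables


def write_subject_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-subject table as CSV with a stable column order.

    Missing values are written as empty fields; duplicate subject ids are
    an error.
    """
    path = Path(path)
    if "subject_id" in rows.columns and rows["subject_id"].duplicated().any():
        dupes = rows.loc[rows["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False)
    return path


def read_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
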