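"""Readers and writers: delimited epoch tables, EDF+ epochs, matrices, sidecars.

The delimited format is a long table with columns
``subject, group, condition, epoch, channel, time_ms, value_uV`` — the
language-neutral fixture format.  EDF support is a minimal self-contained
16-bit EDF+ implementation (one data record per epoch, condition labels
carried in the annotation channel).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CouplingSpec
from .epochs import EpochSet
from .montage import Montage
from .phasesync import PSIMatrix
from .simulate import GroundTruth

__all__ = [
    "write_epochs_csv",
    "read_epochs_csv",
    "write_epochs_edf",
    "read_epochs_edf",
    "read_epochs",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_ground_truth",
    "read_ground_truth",
    "edf_resolution",
]

LONG_COLUMNS = ["subject", "group", "condition", "epoch", "channel", "time_ms", "value_uV"]


# -- delimited long format ---------------------------------------------------


def write_epochs_csv(epochs: EpochSet, path: str | Path) -> None:
    n_e, n_c, n_s = epochs.data.shape
    frame = pd.DataFrame(
        {
            "subject": epochs.subject,
            "group": epochs.group if epochs.group is not None else "",
            "condition": np.repeat(epochs.conditions, n_c * n_s),
            "epoch": np.repeat(np.arange(n_e), n_c * n_s),
            "channel": np.tile(np.repeat(epochs.channels, n_s), n_e),
            "time_ms": np.tile(epochs.times, n_e * n_c),
            "value_uV": epochs.data.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_epochs_csv(path: str | Path, montage: Montage | None = None) -> EpochSet:
    frame = pd.read_csv(path, dtype={"group": str}, keep_default_na=False)
    missing_cols = set(LONG_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"missing columns in epoch table: {sorted(missing_cols)}")
    channels = list(dict.fromkeys(frame["channel"]))
    _check_montage_channels(channels, montage)
    epochs_ids = sorted(frame["epoch"].unique())
    times = np.sort(frame["time_ms"].unique())
    n_e, n_c, n_s = len(epochs_ids), len(channels), len(times)
    if len(frame) != n_e * n_c * n_s:
        raise ValueError("epoch table is not a complete epochs x channels x times grid")
    frame = frame.sort_values(["epoch", "channel", "time_ms"], kind="stable")
    data = frame["value_uV"].to_numpy(dtype=float).reshape(n_e, n_c, n_s)
    # the sort put the channel axis in alphabetical order; restore file order
    sorted_channels = sorted(channels)
    data = data[:, [sorted_channels.index(ch) for ch in channels]]
    cond = (
        frame.drop_duplicates("epoch").sort_values("epoch")["condition"].to_numpy()
    )
    subject = str(frame["subject"].iloc[0])
    group = str(frame["group"].iloc[0]) or None
    dt = np.diff(times)
    sfreq = 1000.0 / dt[0] if n_s > 1 else 1000.0
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        channels=channels,
        conditions=np.asarray(cond, dtype=object),
        subject=subject,
        group=group,
    )


def _check_montage_channels(channels: list[str], montage: Montage | None) -> None:
    if montage is None:
        return
    have = set(channels)
    for expected in (list(montage.channels), montage.analysis_channels()):
        if have == set(expected):
            return
    analysis = set(montage.analysis_channels())
    missing = sorted(analysis - have)
    unknown = sorted(have - set(montage.channels))
    raise ValueError(
        f"channel mismatch with montage: missing={missing}, unknown={unknown}"
    )


# -- minimal EDF+ ------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def edf_resolution(phys_min: float, phys_max: float) -> float:
    """Physical value of one digital step of the stored 16-bit signal."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_epochs_edf(epochs: EpochSet, path: str | Path) -> None:
    """One data record per epoch; condition labels in the annotation channel."""
    n_e, n_c, n_s = epochs.data.shape
    duration = n_s / epochs.sfreq
    ann_bytes = 64  # per-record annotation payload (32 two-byte samples)
    ns = n_c + 1

    phys_min = epochs.data.min(axis=(0, 2))
    phys_max = epochs.data.max(axis=(0, 2))
    flat = phys_max - phys_min < 1e-12
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = bytearray()
    header += _ascii(0, 8)
    patient = f"{epochs.subject} {epochs.group or 'X'}"
    header += _ascii(patient, 80)
    header += _ascii(f"Startdate 01-JAN-2000 t0={epochs.times[0]:g}ms", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (ns + 1), 8)
    header += _ascii("EDF+D", 44)
    header += _ascii(n_e, 8)
    header += _ascii(f"{duration:.6g}", 8)
    header += _ascii(ns, 4)

    labels = list(epochs.channels) + ["EDF Annotations"]
    header += b"".join(_ascii(lb, 16) for lb in labels)
    header += b"".join(_ascii("", 80) for _ in labels)
    header += b"".join(_ascii("uV", 8) for _ in epochs.channels) + _ascii("", 8)
    header += b"".join(
        _ascii(f"{v:.6g}"[:8], 8) for v in phys_min
    ) + _ascii(-1, 8)
    header += b"".join(
        _ascii(f"{v:.6g}"[:8], 8) for v in phys_max
    ) + _ascii(1, 8)
    header += b"".join(_ascii(_DIG_MIN, 8) for _ in labels)
    header += b"".join(_ascii(_DIG_MAX, 8) for _ in labels)
    header += b"".join(_ascii("", 80) for _ in labels)
    header += b"".join(_ascii(n_s, 8) for _ in epochs.channels)
    header += _ascii(ann_bytes // 2, 8)
    header += b"".join(_ascii("", 32) for _ in labels)

    # re-read the rounded physical extrema so scaling matches the header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for ep in range(n_e):
            for c in range(n_c):
                dig = np.round(
                    (epochs.data[ep, c] - pmin[c]) / scale[c] + _DIG_MIN
                ).astype("<i2")
                fh.write(dig.tobytes())
            onset = ep * duration
            tal = f"+{onset:.6g}\x14\x14\x00+{onset:.6g}\x14{epochs.conditions[ep]}\x14\x00"
            payload = tal.encode("ascii").ljust(ann_bytes, b"\x00")[:ann_bytes]
            fh.write(payload)


def read_epochs_edf(path: str | Path, montage: Montage | None = None) -> EpochSet:
    with open(path, "rb") as fh:
        raw = fh.read()
    header = raw[:256].decode("ascii", errors="replace")
    patient = header[8:88].strip()
    recording = header[88:168].strip()
    n_records = int(header[236:244].strip())
    duration = float(header[244:252].strip())
    ns = int(header[252:256].strip())

    sig = raw[256 : 256 * (ns + 1)].decode("ascii", errors="replace")

    def field(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [sig[base + i * width : base + (i + 1) * width].strip()
                for i in range(ns)]

    labels = field(0, 16)
    # byte offsets of the per-signal arrays inside the signal header block
    pos = 0
    parsed: dict[str, list[str]] = {}
    for name, width in [
        ("label", 16), ("transducer", 80), ("dim", 8), ("phys_min", 8),
        ("phys_max", 8), ("dig_min", 8), ("dig_max", 8), ("prefilter", 80),
        ("n_samples", 8), ("reserved", 32),
    ]:
        parsed[name] = [
            sig[pos + i * width : pos + (i + 1) * width].strip() for i in range(ns)
        ]
        pos += width * ns
    labels = parsed["label"]
    n_samp = [int(v) for v in parsed["n_samples"]]
    phys_min = np.array([float(v) for v in parsed["phys_min"]])
    phys_max = np.array([float(v) for v in parsed["phys_max"]])
    dig_min = np.array([float(v) for v in parsed["dig_min"]])
    dig_max = np.array([float(v) for v in parsed["dig_max"]])

    ann_idx = [i for i, lb in enumerate(labels) if lb == "EDF Annotations"]
    eeg_idx = [i for i in range(ns) if i not in ann_idx]
    channels = [labels[i] for i in eeg_idx]
    _check_montage_channels(channels, montage)
    if len({n_samp[i] for i in eeg_idx}) != 1:
        raise ValueError("inconsistent per-record sample counts across channels")
    n_s = n_samp[eeg_idx[0]]
    sfreq = n_s / duration

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    record_len = sum(n_samp)
    body = np.frombuffer(raw[256 * (ns + 1):], dtype="<i2")
    if body.size < n_records * record_len:
        raise ValueError("EDF body shorter than header promises")
    body = body[: n_records * record_len].reshape(n_records, record_len)

    offsets = np.concatenate([[0], np.cumsum(n_samp)])
    data = np.zeros((n_records, len(eeg_idx), n_s))
    for row, i in enumerate(eeg_idx):
        seg = body[:, offsets[i] : offsets[i + 1]].astype(float)
        data[:, row] = (seg - dig_min[i]) * scale[i] + phys_min[i]

    conditions = []
    for rec in range(n_records):
        label = ""
        if ann_idx:
            i = ann_idx[0]
            chunk = body[rec, offsets[i] : offsets[i + 1]].tobytes()
            tals = [t for t in chunk.split(b"\x00") if t]
            for tal in tals:
                parts = tal.split(b"\x14")
                notes = [p for p in parts[1:] if p]
                if notes:
                    label = notes[0].decode("ascii", errors="replace")
                    break
        if not label:
            raise ValueError(f"record {rec} carries no condition annotation")
        conditions.append(label)

    t0 = 0.0
    for token in recording.split():
        if token.startswith("t0=") and token.endswith("ms"):
            t0 = float(token[3:-2])
    times = t0 + 1000.0 / sfreq * np.arange(n_s)
    tokens = patient.split()
    subject = tokens[0] if tokens else "S01"
    group = tokens[1] if len(tokens) > 1 and tokens[1] != "X" else None
    return EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        channels=channels,
        conditions=np.asarray(conditions, dtype=object),
        subject=subject,
        group=group,
    )


def read_epochs(path: str | Path, montage: Montage | None = None) -> EpochSet:
    """Dispatch on extension: ``.edf`` or delimited ``.csv``."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_epochs_edf(path, montage)
    return read_epochs_csv(path, montage)


# -- matrices and sidecars ---------------------------------------------------


def write_matrix_csv(matrix: PSIMatrix | np.ndarray, path: str | Path,
                     labels: list[str] | None = None) -> None:
    if isinstance(matrix, PSIMatrix):
        values, labels = matrix.values, matrix.channels
    else:
        values = np.asarray(matrix)
        if labels is None:
            labels = [f"N{i}" for i in range(values.shape[0])]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("matrix row and column labels differ")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "coupling": [
            {
                "condition": spec.condition,
                "band": spec.band,
                "channel_set": list(spec.channel_set),
                "kappa": spec.kappa,
            }
            for spec in truth.coupling
        ],
        "evoked": {cond: wave.tolist() for cond, wave in truth.evoked.items()},
        "artifact_flags": (
            truth.artifact_flags.astype(int).tolist()
            if truth.artifact_flags is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    truth = GroundTruth()
    for entry in doc.get("coupling", []):
        truth.coupling.append(
            CouplingSpec(
                condition=entry["condition"],
                band=entry["band"],
                channel_set=tuple(entry["channel_set"]),
                kappa=float(entry["kappa"]),
            )
        )
    truth.evoked = {
        cond: np.asarray(wave, dtype=float)
        for cond, wave in doc.get("evoked", {}).items()
    }
    flags = doc.get("artifact_flags")
    truth.artifact_flags = (
        np.asarray(flags, dtype=bool) if flags is not None else None
    )
    return truth
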