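"""Plain-text container formats and EDF reading.

A session is stored as a delimited signal matrix (channels x samples,
one channel per row) plus a key-value sidecar (``<prefix>.meta``)
carrying sampling rate, channel labels, event samples and block bounds;
the ground-truth coupling graph is a delimited edge list
(source, target, strength, block).  European Data Format files are read
through MNE when available; no EDF writer ships with this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Recording
from .mvar_pdc import ConnectivityMatrix
from .synth import CouplingSpec, SessionRecording

__all__ = [
    "write_session",
    "read_session",
    "write_truth_edges",
    "write_connectivity",
    "read_connectivity",
    "read_edf",
]


def write_session(session: SessionRecording, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.signal.tsv`` and ``<prefix>.meta`` (JSON sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig_path = prefix.with_suffix(".signal.tsv")
    np.savetxt(sig_path, session.signal, fmt="%.6g", delimiter="\t")
    meta = {
        "fs": session.fs,
        "channel_labels": list(session.channel_labels),
        "events": session.events.tolist(),
        "block_bounds": [list(b) for b in session.block_bounds],
        "units": "uV",
    }
    meta_path = prefix.with_suffix(".meta")
    meta_path.write_text(json.dumps(meta, indent=1))
    return sig_path, meta_path


def read_session(prefix) -> SessionRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta").read_text())
    signal = np.loadtxt(prefix.with_suffix(".signal.tsv"), delimiter="\t", ndmin=2)
    return SessionRecording(
        signal=signal,
        fs=meta["fs"],
        channel_labels=meta["channel_labels"],
        events=np.asarray(meta["events"], dtype=int),
        block_bounds=tuple(tuple(b) for b in meta["block_bounds"]),
    )


def write_truth_edges(spec: CouplingSpec, path) -> Path:
    """Ground-truth edge list: source, target, strength per block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["source\ttarget\tstrength\tblock"]
    for block, scale in enumerate(spec.block_scale, start=1):
        for src, tgt, s in spec.edges:
            lines.append(f"{src}\t{tgt}\t{scale * s:.6g}\t{block}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_connectivity(cm: ConnectivityMatrix, path) -> Path:
    """Delimited connectivity matrix with a self-describing header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = cm.channel_labels or [f"ch{i:02d}" for i in range(cm.n_channels)]
    header = (
        "orientation: row=receiver, column=sender\n"
        f"band_hz: {cm.band[0]} {cm.band[1]}\n"
        f"n_epochs_averaged: {cm.n_epochs_averaged}\n"
        f"threshold_applied: {cm.threshold_applied}\n"
        f"channels: {' '.join(labels)}"
    )
    np.savetxt(path, cm.W, fmt="%.8g", delimiter="\t", header=header)
    return path


def read_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    band, n_epochs, labels, threshold = (0.5, 30.0), 1, None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").rstrip("\n").partition(":")
            val = val.strip()
            if key == "band_hz":
                band = tuple(float(v) for v in val.split())
            elif key == "n_epochs_averaged":
                n_epochs = int(val)
            elif key == "channels":
                labels = val.split()
            elif key == "threshold_applied" and val not in ("None", ""):
                threshold = val
    W = np.loadtxt(path, delimiter="\t", ndmin=2)
    return ConnectivityMatrix(
        W=W,
        band=band,  # type: ignore[arg-type]
        n_epochs_averaged=n_epochs,
        threshold_applied=threshold,
        channel_labels=labels,
    )


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Read a European Data Format recording into a :class:`Recording`.

    Requires the optional ``mne`` dependency.  Signal is converted from
    volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    return Recording(
        signal=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )
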