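"""Hemispheric information flow (HIF) and laterality index.

The 62-channel scalp montage (standard 10-20 64-electrode layout minus
the mastoids M1/M2) splits into 27 left-hemisphere, 27 right-hemisphere
and 8 midline electrodes (Fpz, Fz, FCz, Cz, CPz, Pz, POz, Oz).  Midline
electrodes are dropped and the remaining 54 x 54 connectivity is
partitioned into four 27 x 27 sub-networks — LH->LH, LH->RH, RH->RH,
RH->LH — whose per-sender outflow totals summarize within- and
between-hemisphere information transfer.  The laterality index
(LH - RH) / (LH + RH) contrasts any left/right pair of such quantities.

Note: odd-numbered 10-20 labels are left hemisphere, even-numbered are
right.  A "PT8" electrode mentioned in some montage listings is mapped
to the standard TP8 label here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_MONTAGE",
    "MIDLINE_CHANNELS",
    "default_channel_labels",
    "hemisphere_of",
    "split_hemispheres",
    "hif",
    "laterality_index",
    "load_montage",
]

MIDLINE_CHANNELS = ("Fpz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz")

_LEFT = (
    "Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1",
    "FT7", "FC5", "FC3", "FC1", "T7", "C5", "C3", "C1",
    "TP7", "CP5", "CP3", "CP1", "P7", "P5", "P3", "P1",
    "PO7", "PO5", "PO3", "O1",
)
_RIGHT = (
    "Fp2", "AF8", "AF4", "F8", "F6", "F4", "F2",
    "FT8", "FC6", "FC4", "FC2", "T8", "C6", "C4", "C2",
    "TP8", "CP6", "CP4", "CP2", "P8", "P6", "P4", "P2",
    "PO8", "PO6", "PO4", "O2",
)

#: channel name -> hemisphere label ("left", "right", "midline")
DEFAULT_MONTAGE: dict[str, str] = (
    {ch: "left" for ch in _LEFT}
    | {ch: "right" for ch in _RIGHT}
    | {ch: "midline" for ch in MIDLINE_CHANNELS}
)


def default_channel_labels() -> list[str]:
    """The 62 default channel names in a fixed anterior-to-posterior order."""
    order = (
        "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
        "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
        "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
        "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
        "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
        "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
        "O1", "Oz", "O2",
    )
    assert len(order) == 62 and set(order) == set(DEFAULT_MONTAGE)
    return list(order)


def paired_channel_labels(n_channels: int) -> list[str]:
    """Left/right-paired channel names for reduced desk-scale montages.

    For an even ``n_channels`` up to 54, picks n/2 homologous electrode
    pairs spread across the lateral arrays, interleaved left, right.
    62 returns the full default montage order.  Odd counts fall back to
    generic unlabelled names.
    """
    if n_channels == 62:
        return default_channel_labels()
    if n_channels % 2 or n_channels > 54:
        return [f"ch{i:02d}" for i in range(n_channels)]
    k = n_channels // 2
    idx = np.unique(np.linspace(0, len(_LEFT) - 1, k).astype(int))
    labels: list[str] = []
    for i in idx:
        labels += [_LEFT[i], _RIGHT[i]]
    return labels


def hemisphere_of(channel: str, montage: dict[str, str] | None = None) -> str:
    montage = montage or DEFAULT_MONTAGE
    name = "TP8" if channel == "PT8" else channel  # nonstandard alias
    try:
        return montage[name]
    except KeyError:
        raise KeyError(f"channel {channel!r} not in montage") from None


def split_hemispheres(
    W: np.ndarray,
    channel_labels: list[str],
    montage: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Partition W into the four lateralized sub-networks.

    Midline rows/columns are dropped.  With the row = receiver
    convention, the "X->Y" block holds entries whose sender is in
    hemisphere X and receiver in hemisphere Y, arranged as
    (receivers in Y) x (senders in X).  Keys: "LH->LH", "LH->RH",
    "RH->RH", "RH->LH"; the hemisphere channel name lists are returned
    under "left_channels" / "right_channels".
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1] or W.shape[0] != len(channel_labels):
        raise ValueError("W shape and channel_labels length disagree")
    montage = montage or DEFAULT_MONTAGE
    sides = [hemisphere_of(ch, montage) for ch in channel_labels]
    left = np.array([s == "left" for s in sides])
    right = np.array([s == "right" for s in sides])
    blocks = {
        # receiver rows indexed first (row = receiver, column = sender)
        "LH->LH": W[np.ix_(left, left)],
        "LH->RH": W[np.ix_(right, left)],
        "RH->RH": W[np.ix_(right, right)],
        "RH->LH": W[np.ix_(left, right)],
    }
    blocks["left_channels"] = [c for c, s in zip(channel_labels, sides) if s == "left"]
    blocks["right_channels"] = [c for c, s in zip(channel_labels, sides) if s == "right"]
    return blocks


def hif(sub: np.ndarray, direction: str = "outflow") -> np.ndarray:
    """Per-node information flow of one sub-network block.

    ``outflow`` (default): total flow each *sender* emits = sum over
    receivers, i.e. the sum along the receiver axis (axis 0 of the
    (receivers x senders) block).  ``inflow``: total each receiver
    collects (sum along axis 1).
    """
    sub = np.asarray(sub, dtype=float)
    if sub.ndim != 2:
        raise ValueError("sub-network block must be 2-D")
    if direction == "outflow":
        return sub.sum(axis=0)
    if direction == "inflow":
        return sub.sum(axis=1)
    raise ValueError("direction must be 'outflow' or 'inflow'")


def laterality_index(lh_value: float, rh_value: float) -> float:
    """(LH - RH) / (LH + RH), in [-1, 1] for nonnegative inputs."""
    total = lh_value + rh_value
    if total == 0:
        raise ZeroDivisionError("laterality index undefined: LH + RH = 0")
    return float((lh_value - rh_value) / total)


def load_montage(path) -> dict[str, str]:
    """Read a delimited montage file: one ``channel<sep>hemisphere`` per line.

    Separator may be comma, tab or whitespace; hemisphere labels are
    normalized to lower case and must be left/right/midline.
    """
    montage: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            if len(parts) != 2:
                raise ValueError(f"bad montage line: {line!r}")
            ch, side = parts[0], parts[1].lower()
            if side not in ("left", "right", "midline"):
                raise ValueError(f"unknown hemisphere label {side!r} for {ch}")
            montage[ch] = side
    return montage
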