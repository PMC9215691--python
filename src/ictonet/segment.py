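"""Core container for multichannel EEG segments and the 10-20 montage used throughout.

The pipeline operates on 20-channel scalp EEG in the standard 10-20 montage.
Channel order is fixed alphabetically and every stage validates against it, so
that weight matrices, node-ictogenicity vectors and report columns always line
up.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Canonical 20-channel 10-20 montage, alphabetical order.
CHANNELS_1020: tuple[str, ...] = (
    "C3", "C4", "CZ", "F3", "F4", "F7", "F8", "FP1", "FP2", "FPZ",
    "FZ", "O1", "O2", "P3", "P4", "PZ", "T3", "T4", "T5", "T6",
)

#: Approximate 2-D head-surface coordinates (x: left-right, y: back-front),
#: unit head radius; montage metadata for plotting or distance queries.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "FPZ": (0.00, 0.95), "FP1": (-0.31, 0.90), "FP2": (0.31, 0.90),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.48), "FZ": (0.00, 0.48),
    "F4": (0.55, 0.48), "F8": (0.81, 0.59),
    "T3": (-0.95, 0.00), "C3": (-0.48, 0.00), "CZ": (0.00, 0.00),
    "C4": (0.48, 0.00), "T4": (0.95, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.55, -0.48), "PZ": (0.00, -0.48),
    "P4": (0.55, -0.48), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.90), "O2": (0.31, -0.90),
}

OCCIPITAL_CHANNELS: tuple[str, str] = ("O1", "O2")

#: Coarse lobe grouping of the montage, used by the synthetic generator's
#: regional rhythm sources.
CHANNEL_REGIONS: dict[str, str] = {
    "FP1": "frontal", "FP2": "frontal", "FPZ": "frontal", "F3": "frontal",
    "F4": "frontal", "F7": "frontal", "F8": "frontal", "FZ": "frontal",
    "C3": "central", "C4": "central", "CZ": "central", "T3": "central",
    "T4": "central",
    "P3": "posterior", "P4": "posterior", "PZ": "posterior",
    "T5": "posterior", "T6": "posterior", "O1": "posterior", "O2": "posterior",
}


@dataclass
class EEGSegment:
    """One artifact-free multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in arbitrary units (the analysis is phase based and
        amplitude-scale invariant).
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered channel names; must match ``data`` row count.
    subject_id, segment_id : str
        Provenance identifiers carried through the pipeline.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGSegment":
        """Copy of this segment with new samples (and optionally a new rate)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)

    # ------------------------------------------------------------------
    # plain-text serialization (one CSV per segment, metadata in a header
    # comment line) -- shared by the synthetic fixtures and the CLI
    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# fs={self.fs!r} subject_id={self.subject_id} "
                f"segment_id={self.segment_id}\n"
            )
            df = pd.DataFrame(self.data.T, columns=list(self.channel_labels))
            df.to_csv(fh, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path) -> "EEGSegment":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header line")
            meta = dict(
                item.split("=", 1) for item in header[1:].split() if "=" in item
            )
            df = pd.read_csv(fh)
        return cls(
            data=df.to_numpy().T,
            fs=float(meta.get("fs", "nan")),
            channel_labels=tuple(df.columns),
            subject_id=meta.get("subject_id", ""),
            segment_id=meta.get("segment_id", ""),
        )
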