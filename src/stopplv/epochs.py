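"""Epoched multichannel EEG container.

An :class:`EpochSet` holds a ``(n_trials, n_channels, n_samples)`` tensor of
amplitudes in microvolts together with the channel montage, sampling rate, the
epoch time axis in milliseconds and a per-trial label table.  Time 0 is the
stimulus (stop-signal) onset; the default epoch window is the half-open
interval [-200, 1300) ms, i.e. 750 samples at 500 Hz.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: 32-channel subset of the international 10-20/10-10 montage used throughout.
MONTAGE_32 = [
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FCZ", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CPZ", "CP4", "TP8",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2", "PO3", "PO4",
]


def condition_label(hand: str, outcome: str) -> str:
    """Join a hand (LHR/RHR) and stop outcome (SS/FS) into e.g. ``"LHR-SS"``."""
    return f"{hand}-{outcome}"


@dataclass
class EpochSet:
    """Labelled trials x channels x samples tensor.

    Parameters
    ----------
    data:
        Amplitudes in microvolts, shape ``(n_trials, n_channels, n_samples)``.
    channel_names:
        Unique channel labels, one per channel row.
    fs:
        Sampling rate in Hz.
    tmin_ms:
        Time of the first sample relative to stimulus onset, in ms.
    trials:
        One row per trial.  Expected columns (when available): ``subject``,
        ``hand`` (LHR/RHR), ``outcome`` (SS/FS/go_correct/go_error), ``ssd``.
    """

    data: np.ndarray
    channel_names: list[str]
    fs: float
    tmin_ms: float
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel labels must be unique")
        if len(self.trials) == 0:
            self.trials = pd.DataFrame(index=range(self.n_trials))
        if len(self.trials) != self.n_trials:
            raise ValueError("trial table length does not match data")
        self.trials = self.trials.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in milliseconds."""
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def get_channel(self, name: str) -> np.ndarray:
        """Return (n_trials, n_samples) for one channel."""
        return self.data[:, self.channel_index(name), :]

    def time_mask(self, lo_ms: float, hi_ms: float, half_open: bool = False) -> np.ndarray:
        """Boolean sample mask for ``lo <= t <= hi`` (or ``< hi`` if half-open)."""
        t = self.times
        hi_ok = (t < hi_ms) if half_open else (t <= hi_ms + 1e-9)
        return (t >= lo_ms - 1e-9) & hi_ok

    # -- selection ------------------------------------------------------
    def select(
        self,
        hand: str | None = None,
        outcome: str | None = None,
        condition: str | None = None,
        mask: np.ndarray | None = None,
    ) -> "EpochSet":
        """Subset trials by hand/outcome, a ``"LHR-SS"`` style condition, or a mask."""
        if condition is not None:
            hand, outcome = condition.split("-")
        keep = np.ones(self.n_trials, dtype=bool)
        if hand is not None:
            keep &= (self.trials["hand"] == hand).to_numpy()
        if outcome is not None:
            keep &= (self.trials["outcome"] == outcome).to_numpy()
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool)
        return EpochSet(
            self.data[keep],
            list(self.channel_names),
            self.fs,
            self.tmin_ms,
            self.trials.loc[keep].reset_index(drop=True),
        )

    @property
    def conditions(self) -> pd.Series:
        """Per-trial ``hand-outcome`` labels."""
        return self.trials["hand"].astype(str) + "-" + self.trials["outcome"].astype(str)

    @classmethod
    def concat(cls, parts: Sequence["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.channel_names != first.channel_names or p.fs != first.fs:
                raise ValueError("incompatible EpochSets")
        return cls(
            np.concatenate([p.data for p in parts], axis=0),
            list(first.channel_names),
            first.fs,
            first.tmin_ms,
            pd.concat([p.trials for p in parts], ignore_index=True),
        )

    # -- I/O -------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialise to a ``.npz`` container (array + metadata + trial CSV)."""
        buf = io.StringIO()
        self.trials.to_csv(buf, index=False)
        meta = {"channel_names": self.channel_names, "fs": self.fs, "tmin_ms": self.tmin_ms}
        np.savez_compressed(
            path,
            data=self.data,
            meta=np.array(json.dumps(meta)),
            trials_csv=np.array(buf.getvalue()),
        )

    @classmethod
    def load(cls, path: str) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            trials = pd.read_csv(io.StringIO(str(z["trials_csv"])))
            return cls(z["data"], meta["channel_names"], meta["fs"], meta["tmin_ms"], trials)


def read_edf_continuous(path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording via MNE.

    Returns ``(data_uV, fs, channel_names)`` with data shaped
    ``(n_channels, n_samples)``.  Requires the optional ``mne`` dependency.
    """
    import mne  # local import: EDF support is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def read_delimited_continuous(path: str, delimiter: str = ",") -> np.ndarray:
    """Read a channels x samples plain-text matrix (one channel per row)."""
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))
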