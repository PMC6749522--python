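"""Phase-locking value (PLV) features.

The PLV between two signals is the modulus of the time-averaged unit phasor
of their instantaneous phase difference,

    PLV = | (1/N) sum_k exp(i (phi1(k) - phi2(k))) |,

which lies in [0, 1]: 0 means no consistent phase relationship, 1 a constant
phase lag.  Instantaneous phase is the argument of the analytic signal
(Hilbert transform), wrapped to (-pi, pi].

Per trial and electrode pair, the signal is band-filtered, the phase
extracted, and the PLV computed over the post-stimulus window (default
1-300 ms, N = 150 samples at 500 Hz).  The default band set is the single
1-50 Hz pass-band of the preprocessing stage; a canonical five-sub-band set
is available for finer spectral resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .epochs import EpochSet
from .preprocess import FilterSpec, bandpass_filter
from .synth import ROI_PAIRS

#: Default single wide band (matches the 1-50 Hz preprocessing pass-band).
WIDEBAND = ((1.0, 50.0),)

#: Canonical delta/theta/alpha/beta/gamma sub-bands, all inside 1-50 Hz.
CANONICAL_BANDS = ((1.0, 4.0), (4.0, 7.0), (8.0, 12.0), (13.0, 30.0), (30.0, 50.0))


def analytic_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous phase of the analytic signal, wrapped to (-pi, pi].

    The input should already be band-limited; the analytic signal is built by
    zeroing the negative-frequency half of the spectrum.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 4:
        raise ValueError("need at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if np.all(x == 0):
        raise ValueError("phase of the all-zero signal is undefined")
    phi = np.angle(hilbert(x, axis=axis))
    # np.angle returns [-pi, pi]; fold the single boundary point.
    phi = np.where(phi == -np.pi, np.pi, phi)
    return phi


def plv(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """Phase-locking value of two equal-length phase series."""
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ValueError("phase series must have equal length")
    if phi1.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phi1 - phi2)))))


def pair_column(pair, band) -> str:
    a, b = (pair.split("-") if isinstance(pair, str) else pair)
    return f"{a}-{b}|{band[0]:g}-{band[1]:g}Hz"


@dataclass
class FeatureTable:
    """Per-trial connectivity features with class labels.

    ``X`` rows align with the source EpochSet's trial order; columns are
    ``"F3-F4|1-50Hz"`` style (pair, band) identifiers.  Values are raw PLVs
    in [0, 1], or z-scores after baseline normalisation.
    """

    X: pd.DataFrame
    labels: pd.Series
    window_ms: tuple[float, float] = (1.0, 300.0)
    bands: tuple = WIDEBAND
    normalized: bool = False
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.X.loc[mask].reset_index(drop=True),
            self.labels.loc[mask].reset_index(drop=True),
            self.window_ms,
            self.bands,
            self.normalized,
            self.trials.loc[mask].reset_index(drop=True) if len(self.trials) else self.trials,
        )

    def columns_for_pair(self, pair) -> list[str]:
        key = pair if isinstance(pair, str) else "-".join(pair)
        return [c for c in self.X.columns if c.split("|")[0] == key]

    def to_csv(self, path: str) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.labels.values)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str, **kwargs) -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(df.drop(columns=["label"]), df["label"], **kwargs)


def plv_features(
    epochs: EpochSet,
    pairs=ROI_PAIRS,
    window_ms: tuple[float, float] = (1.0, 300.0),
    bands: tuple = WIDEBAND,
    filter_order: int = 4,
) -> FeatureTable:
    """PLV of every (electrode pair, band) per trial over the analysis window.

    Both channels of a pair are band-filtered over the whole epoch (so filter
    transients stay outside the window), Hilbert phases extracted, and the
    PLV computed over the window samples.  Deterministic given the EpochSet.
    """
    pair_keys = [p if isinstance(p, str) else "-".join(p) for p in pairs]
    if len(set(pair_keys)) != len(pair_keys):
        raise ValueError("duplicate electrode pairs")
    idx_pairs = []
    for key in pair_keys:
        a, b = key.split("-")
        idx_pairs.append((epochs.channel_index(a), epochs.channel_index(b)))

    mask = epochs.time_mask(*window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")

    cols: dict[str, np.ndarray] = {}
    for band in bands:
        spec = FilterSpec(band_hz=tuple(band), order=filter_order)
        if epochs.n_trials:
            filt = bandpass_filter(epochs.data, spec, epochs.fs, axis=-1)
            phase = np.angle(hilbert(filt, axis=-1))
        else:
            phase = epochs.data
        for key, (ia, ib) in zip(pair_keys, idx_pairs):
            dphi = phase[:, ia, :][:, mask] - phase[:, ib, :][:, mask]
            vals = (
                np.abs(np.mean(np.exp(1j * dphi), axis=1))
                if epochs.n_trials
                else np.empty(0)
            )
            cols[pair_column(key, band)] = vals

    X = pd.DataFrame(cols)
    labels = (
        epochs.conditions
        if {"hand", "outcome"} <= set(epochs.trials.columns)
        else pd.Series(["?"] * epochs.n_trials)
    )
    return FeatureTable(X, labels.reset_index(drop=True), tuple(window_ms), tuple(map(tuple, bands)),
                        False, epochs.trials.copy())


def znormalize_features(features: FeatureTable, baseline: FeatureTable) -> FeatureTable:
    """Z-transform features against a baseline-window feature distribution.

    Per column: z = (x - baseline mean) / baseline SD.  Columns with zero
    baseline SD map to zero with a warning.
    """
    if list(features.X.columns) != list(baseline.X.columns):
        raise ValueError("feature and baseline tables must share columns")
    mu = baseline.X.mean(axis=0)
    sd = baseline.X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} column(s) have zero baseline SD; z set to 0"
        )
    sd = sd.where(~degenerate, np.inf)
    Z = (features.X - mu) / sd
    return FeatureTable(Z, features.labels.copy(), features.window_ms, features.bands,
                        True, features.trials.copy())
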