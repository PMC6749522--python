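"""Continuous-EEG preprocessing: band-pass filtering, down-sampling, epoching,
baseline correction and automatic independent-component artifact rejection.

The filter is a 4th-order Butterworth band-pass (default 1-50 Hz) applied
forward-backward, i.e. zero-phase: phase distortion would bias downstream
phase-locking estimates.  Sample windows are 0-based and half-open with time
0 at stimulus onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet


@dataclass(frozen=True)
class FilterSpec:
    band_hz: tuple[float, float] = (1.0, 50.0)
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.band_hz
        if not 0.0 < lo < hi < fs / 2.0:
            raise ValueError(f"band {self.band_hz} must satisfy 0 < low < high < fs/2 ({fs / 2})")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return sps.butter(self.order, self.band_hz, btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    x: np.ndarray, spec: FilterSpec = FilterSpec(), fs: float = 500.0, axis: int = -1
) -> np.ndarray:
    """Band-pass an amplitude series (any shape, filtered along ``axis``)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    sos = spec.sos(fs)
    if x.shape[axis] <= 3 * spec.order:
        raise ValueError("input shorter than 3x filter order")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=axis)
    return sps.sosfilt(sos, x, axis=axis)


def filter_response(spec: FilterSpec, fs: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Magnitude response of the designed filter at the given frequencies.

    For the zero-phase (forward-backward) realisation the effective magnitude
    is the squared single-pass magnitude.
    """
    _, h = sps.sosfreqz(spec.sos(fs), worN=2.0 * np.pi * np.asarray(freqs_hz) / fs)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def downsample(x: np.ndarray, fs_in: float, fs_out: float, axis: int = -1) -> np.ndarray:
    """Anti-aliased integer-factor decimation (e.g. 1000 Hz -> 500 Hz).

    Length follows the keep-every-q-th-sample-from-0 convention:
    ``ceil(n / q)`` output samples.
    """
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError(f"fs_in must be an integer multiple of fs_out (got ratio {q})")
    q = int(round(q))
    if q == 1:
        return np.asarray(x, dtype=float).copy()
    return sps.decimate(np.asarray(x, dtype=float), q, ftype="fir", zero_phase=True, axis=axis)


def epoch_extract(
    continuous: np.ndarray,
    events: np.ndarray,
    fs: float,
    window_ms: tuple[float, float] = (-200.0, 1300.0),
    channel_names: list[str] | None = None,
    trial_info: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs out of a channels x samples recording.

    ``events`` are 0-based stimulus-onset sample indices.  The window is
    half-open: at 500 Hz, [-200, 1300) ms gives exactly 750 samples starting
    ``round(-0.2 * fs)`` samples before the event.  Events whose window would
    overrun the recording are skipped with a warning.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_ch, n_total = continuous.shape
    if channel_names is None:
        channel_names = [f"CH{i}" for i in range(n_ch)]
    lo_ms, hi_ms = window_ms
    start_off = round(lo_ms / 1000.0 * fs)
    n_samp = round((hi_ms - lo_ms) / 1000.0 * fs)

    kept, data = [], []
    for j, ev in enumerate(np.asarray(events, dtype=int)):
        a = ev + start_off
        b = a + n_samp
        if a < 0 or b > n_total:
            continue
        kept.append(j)
        data.append(continuous[:, a:b])
    n_skipped = len(np.atleast_1d(events)) - len(kept)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} event(s) too close to the recording edges")
    arr = np.asarray(data) if data else np.empty((0, n_ch, n_samp))
    if trial_info is not None and len(kept):
        trials = trial_info.iloc[kept].reset_index(drop=True)
    elif trial_info is not None:
        trials = trial_info.iloc[:0]
    else:
        trials = pd.DataFrame(index=range(len(kept)))
    return EpochSet(arr, channel_names, fs, lo_ms, trials)


def baseline_correct(epochs: EpochSet, baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus baseline window."""
    mask = epochs.time_mask(*baseline_ms, half_open=True)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        epochs.data - mean, list(epochs.channel_names), epochs.fs, epochs.tmin_ms,
        epochs.trials.copy(),
    )


@dataclass(frozen=True)
class ComponentRejectionSpec:
    """Automatic IC rejection criteria.

    Components whose kurtosis or log-variance z-score (across components)
    exceeds the thresholds are zeroed before back-projection.  ``method
    = "none"`` is the identity and the default for synthetic data.
    """

    method: str = "none"            # "none" | "automatic"
    kurtosis_z: float = 3.0
    variance_z: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in ("none", "automatic"):
            raise ValueError("method must be 'none' or 'automatic'")
        if self.kurtosis_z <= 0 or self.variance_z <= 0:
            raise ValueError("rejection thresholds must be positive")


def reject_components(
    epochs: EpochSet, spec: ComponentRejectionSpec = ComponentRejectionSpec(), seed: int = 0
) -> EpochSet:
    """ICA-based artifact removal on concatenated epochs.

    Decomposes the concatenated trials into independent components (FastICA),
    zeroes components flagged by the kurtosis/variance criteria and
    back-projects the rest.  On decomposition failure the input is passed
    through unchanged with a warning.
    """
    if spec.method == "none" or epochs.n_trials == 0:
        return epochs
    from scipy.stats import kurtosis as _kurtosis
    from sklearn.decomposition import FastICA

    n_tr, n_ch, n_sp = epochs.data.shape
    X = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_sp)  # channels x time
    if X.shape[1] < n_ch:
        raise ValueError("automatic rejection needs at least n_channels samples")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=n_ch, whiten="unit-variance", random_state=seed, max_iter=500)
            S = ica.fit_transform(X.T).T              # components x time
        kurt = _kurtosis(S, axis=1, fisher=True)
        logvar = np.log(np.var(S, axis=1) + 1e-300)

        def _z(v):
            sd = v.std()
            return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

        bad = (np.abs(_z(kurt)) > spec.kurtosis_z) | (np.abs(_z(logvar)) > spec.variance_z)
        S_clean = S.copy()
        S_clean[bad] = 0.0
        X_clean = (ica.mixing_ @ S_clean) + ica.mean_[:, None]
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"ICA decomposition failed ({exc}); passing data through")
        return epochs
    data = X_clean.reshape(n_ch, n_tr, n_sp).transpose(1, 0, 2)
    return EpochSet(data, list(epochs.channel_names), epochs.fs, epochs.tmin_ms, epochs.trials.copy())
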