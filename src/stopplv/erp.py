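"""Event-related potentials, the P300 measure and pointwise paired testing.

The P300 here is the positive stimulus-locked deflection ~300 ms after the
stop signal, averaged per subject and then grand-averaged.  Condition
contrasts (successful vs failed stops) are tested per time sample with the
two-sided Wilcoxon signed-rank test at alpha = 0.05, with no multiplicity
correction -- an anti-conservative convention, flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochSet


@dataclass
class ERPWaveform:
    channel: str
    times_ms: np.ndarray
    per_subject: np.ndarray      # (n_subjects, n_samples), µV
    subjects: list[str]

    @property
    def grand_average(self) -> np.ndarray:
        return self.per_subject.mean(axis=0)

    @property
    def n_subjects(self) -> int:
        return self.per_subject.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times_ms, "grand_average": self.grand_average})
        for i, s in enumerate(self.subjects):
            df[s] = self.per_subject[i]
        return df


def condition_erp(
    epochs: EpochSet,
    channel: str = "FZ",
    hand: str | None = None,
    outcome: str | None = None,
    condition: str | None = None,
) -> ERPWaveform:
    """Per-subject average then grand average for one channel and condition."""
    sub = epochs.select(hand=hand, outcome=outcome, condition=condition)
    if sub.n_trials == 0:
        raise ValueError("no trials match the requested condition")
    x = sub.get_channel(channel)
    if "subject" in sub.trials.columns:
        subjects = list(pd.unique(sub.trials["subject"]))
        per_subject = np.stack(
            [x[(sub.trials["subject"] == s).to_numpy()].mean(axis=0) for s in subjects]
        )
    else:
        subjects = ["pooled"]
        per_subject = x.mean(axis=0, keepdims=True)
    return ERPWaveform(channel, sub.times, per_subject, subjects)


def p300_amplitude(
    erp: ERPWaveform, window_ms: tuple[float, float] = (250.0, 400.0), mode: str = "mean"
) -> np.ndarray:
    """Per-subject P300 amplitude: window mean (default) or window peak, in µV."""
    lo, hi = window_ms
    t = erp.times_ms
    if lo < t[0] or hi > t[-1]:
        raise ValueError(f"window {window_ms} outside the epoch time axis")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    seg = erp.per_subject[:, mask]
    if mode == "mean":
        return seg.mean(axis=1)
    if mode == "peak":
        return seg.max(axis=1)
    raise ValueError("mode must be 'mean' or 'peak'")


@dataclass
class SignificanceMask:
    alpha: float
    times_ms: np.ndarray
    statistic: np.ndarray
    p: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times_ms, "statistic": self.statistic, "p": self.p,
             "significant": self.mask}
        )


def pointwise_wilcoxon(
    erp_a: ERPWaveform | np.ndarray,
    erp_b: ERPWaveform | np.ndarray,
    alpha: float = 0.05,
    times_ms: np.ndarray | None = None,
) -> SignificanceMask:
    """Two-sided Wilcoxon signed-rank test at every time sample.

    Accepts either two ERPWaveforms or two (n_subjects, n_samples) stacks of
    paired per-subject values.  Uses the exact null distribution for small n
    (scipy switches to it automatically when there are no ties); a sample
    where every paired difference is zero gets p = 1 by convention.  Requires
    at least 5 paired subjects.
    """
    a = erp_a.per_subject if isinstance(erp_a, ERPWaveform) else np.asarray(erp_a, float)
    b = erp_b.per_subject if isinstance(erp_b, ERPWaveform) else np.asarray(erp_b, float)
    if times_ms is None:
        times_ms = erp_a.times_ms if isinstance(erp_a, ERPWaveform) else np.arange(a.shape[1])
    if a.shape != b.shape:
        raise ValueError("paired stacks must have identical shape")
    if a.shape[0] < 5:
        raise ValueError("signed-rank testing needs at least 5 paired subjects")
    n_samp = a.shape[1]
    stat = np.empty(n_samp)
    p = np.empty(n_samp)
    for k in range(n_samp):
        d = a[:, k] - b[:, k]
        if np.all(d == 0):
            stat[k], p[k] = 0.0, 1.0
            continue
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="auto")
        stat[k], p[k] = float(res.statistic), float(res.pvalue)
    return SignificanceMask(alpha, np.asarray(times_ms), stat, p)
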