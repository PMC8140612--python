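"""Epoch-averaging analysis: cut, detrend, reject, average, summarise.

The block-average estimate of the evoked response: μM recordings are cut
into [-3, 14] s epochs around each stimulus onset, linearly detrended,
screened with a 100 μM peak-to-peak rejection rule, averaged per
condition and channel, pooled into ROI waveforms per subject, and
summarised at group level with a subject-resampling bootstrap band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import signal as sp_signal

from .core import Recording, Unit
from .montage import Montage


@dataclass
class Epochs:
    """Stimulus-locked data segments: (n_epochs, rows, samples) in μM."""

    data: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    sfreq: float
    montage: Montage
    row_chroma: list[str]
    rejection_log: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return self.data.shape[0]


def epoch(
    rec: Recording,
    window: tuple[float, float] = (-3.0, 14.0),
    detrend: bool = True,
    baseline: bool = False,
) -> Epochs:
    """Cut one epoch per event; optionally detrend and baseline-correct.

    ``detrend`` removes the per-channel least-squares line from each epoch.
    ``baseline`` additionally subtracts the mean of the pre-stimulus
    interval (off by default).  Epochs running past either end of the
    recording are dropped with a warning.
    """
    rec.require_unit(Unit.MOLAR, "epoch")
    if len(rec.events) == 0:
        warnings.warn("no events: returning empty Epochs", stacklevel=2)
        return Epochs(
            data=np.empty((0, rec.data.shape[0], 0)),
            times=np.empty(0),
            conditions=np.empty(0, dtype=object),
            sfreq=rec.sfreq,
            montage=rec.montage,
            row_chroma=list(rec.row_chroma),
        )
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must satisfy start < end")
    n_times = int(round((w1 - w0) * rec.sfreq)) + 1
    times = w0 + np.arange(n_times) / rec.sfreq

    segs, conds, dropped = [], [], []
    for onset, cond in zip(rec.events.onsets, rec.events.conditions):
        i0 = int(round((onset + w0) * rec.sfreq))
        if i0 < 0 or i0 + n_times > rec.n_samples:
            dropped.append(onset)
            continue
        segs.append(rec.data[:, i0:i0 + n_times])
        conds.append(cond)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} epoch(s) extending past the recording "
            f"(onsets {np.round(dropped, 2).tolist()})",
            stacklevel=2,
        )
    data = np.array(segs) if segs else np.empty((0, rec.data.shape[0], n_times))
    if detrend and len(data):
        data = sp_signal.detrend(data, axis=-1, type="linear")
    if baseline and len(data):
        pre = times < 0
        if pre.any():
            data = data - data[:, :, pre].mean(axis=-1, keepdims=True)
    return Epochs(
        data=data,
        times=times,
        conditions=np.array(conds, dtype=object),
        sfreq=rec.sfreq,
        montage=rec.montage,
        row_chroma=list(rec.row_chroma),
    )


def reject_epochs(ep: Epochs, pp_limit: float = 100.0) -> Epochs:
    """Drop epochs whose peak-to-peak range exceeds ``pp_limit`` μM in any channel."""
    if len(ep) == 0:
        return ep
    pp = ep.data.max(axis=-1) - ep.data.min(axis=-1)  # (epochs, rows)
    worst = pp.max(axis=1)
    keep = worst <= pp_limit
    log = list(ep.rejection_log)
    for i in np.where(~keep)[0]:
        row = int(np.argmax(pp[i]))
        log.append(
            {
                "epoch": int(i),
                "condition": ep.conditions[i],
                "channel": row // 2,
                "chroma": ep.row_chroma[row],
                "peak_to_peak": float(pp[i, row]),
            }
        )
    return Epochs(
        data=ep.data[keep],
        times=ep.times,
        conditions=ep.conditions[keep],
        sfreq=ep.sfreq,
        montage=ep.montage,
        row_chroma=list(ep.row_chroma),
        rejection_log=log,
    )


@dataclass
class EpochAverage:
    """Per-condition mean waveforms of one subject, (rows, samples) in μM."""

    means: dict[str, np.ndarray]
    n_epochs: dict[str, int]
    times: np.ndarray
    sfreq: float
    montage: Montage
    row_chroma: list[str]
    missing: list[str] = field(default_factory=list)

    def roi_waveform(self, roi: str, chroma: str, condition: str) -> np.ndarray:
        """Unweighted mean over the ROI's channels for one chromophore."""
        if condition not in self.means:
            raise KeyError(f"condition {condition!r} has no retained epochs")
        channels = self.montage.roi_channels(roi)
        rows = [
            2 * ch + k
            for ch in channels
            for k in (0, 1)
            if self.row_chroma[2 * ch + k] == chroma
        ]
        if not rows:
            raise ValueError(f"no rows for ROI {roi!r} / chroma {chroma!r}")
        return self.means[condition][rows].mean(axis=0)


def average(ep: Epochs) -> EpochAverage:
    """Sample-wise mean per condition over retained epochs."""
    conditions = []
    for c in ep.conditions:
        if c not in conditions:
            conditions.append(c)
    means, counts, missing = {}, {}, []
    for cond in conditions:
        mask = ep.conditions == cond
        if not mask.any():
            missing.append(cond)
            continue
        means[cond] = ep.data[mask].mean(axis=0)
        counts[cond] = int(mask.sum())
    return EpochAverage(
        means=means,
        n_epochs=counts,
        times=ep.times,
        sfreq=ep.sfreq,
        montage=ep.montage,
        row_chroma=list(ep.row_chroma),
        missing=missing,
    )


def amplitude_window(
    avg: EpochAverage,
    roi: str,
    condition: str,
    chroma: str,
    window: tuple[float, float] = (5.0, 7.0),
) -> float:
    """Time-mean of the subject's ROI waveform over ``window`` seconds.

    The default 5-7 s window sits on the response peak for ~5 s auditory
    blocks; the window mean under-reads the true peak slightly, which is
    the accepted cost of avoiding fragile peak picking.
    """
    if window[0] < avg.times[0] or window[1] > avg.times[-1]:
        raise ValueError(f"window {window} outside epoch span "
                         f"[{avg.times[0]:g}, {avg.times[-1]:g}] s")
    wf = avg.roi_waveform(roi, chroma, condition)
    mask = (avg.times >= window[0]) & (avg.times <= window[1])
    return float(wf[mask].mean())


@dataclass
class RoiWaveform:
    """Group-level ROI waveform with a bootstrap confidence band (μM)."""

    roi: str
    condition: str
    chroma: str
    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_subjects: int

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.mean, label=f"{self.condition} {self.chroma}", **kwargs)
        ax.fill_between(self.times, self.lower, self.upper, alpha=0.3)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("ΔHb (μM)")
        return ax


def group_band(
    waveforms: np.ndarray,
    times: np.ndarray,
    roi: str = "",
    condition: str = "",
    chroma: str = "",
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 95.0,
) -> RoiWaveform:
    """Across-subject mean with a subject-resampling bootstrap percentile band.

    ``waveforms`` is (n_subjects, n_samples); subjects are resampled with
    replacement and the band is the 2.5/97.5 percentile of resampled means
    (for the default 95% level), clipped to bracket the observed mean.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n_subj = waveforms.shape[0]
    if n_subj < 2:
        raise ValueError("bootstrap band needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    mean = waveforms.mean(axis=0)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boots = waveforms[idx].mean(axis=1)  # (n_boot, n_samples)
    alpha = (100.0 - ci) / 2.0
    lower = np.percentile(boots, alpha, axis=0)
    upper = np.percentile(boots, 100.0 - alpha, axis=0)
    return RoiWaveform(
        roi=roi,
        condition=condition,
        chroma=chroma,
        times=np.asarray(times, dtype=float),
        mean=mean,
        lower=np.minimum(lower, mean),
        upper=np.maximum(upper, mean),
        n_subjects=n_subj,
    )
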