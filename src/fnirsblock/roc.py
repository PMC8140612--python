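"""ROC-based detection evaluation of the canonical GLM pipeline.

A "detection" is a small GLM p-value for a condition regressor.  Silence
rows are the negative class (any detected silence response is a false
positive); speech and noise rows are positives.  Sweeping the p-value
threshold traces the ROC; the summary metrics are the AUC and the
true-positive rate at a 5% false-positive rate.

``run_canonical_analysis`` is the §-style driver: resample, optical
density, Beer-Lambert, distance pruning, STG channel selection, canonical
design with drifts and a chosen short-channel nuisance block, AR(4)
prewhitened GLM, and a tidy p-value table at channel and ROI level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Recording
from .design import NuisanceSpec, design_for_recording
from .glm import HemodynamicGLM
from .hrf import HrfParams
from .montage import STG_ROIS
from .preprocess import beer_lambert, prune_channels, resample, to_optical_density

POSITIVE_CONDITIONS = ("speech", "noise")
NEGATIVE_CONDITION = "silence"


@dataclass
class RocResult:
    """ROC curve plus summary metrics."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def tpr_at(self, fpr: float = 0.05, method: str = "interp") -> float:
        """TPR at the given FPR: linear interpolation or step convention."""
        if method == "interp":
            return float(np.interp(fpr, self.fpr, self.tpr))
        if method == "step":
            idx = np.searchsorted(self.fpr, fpr, side="right") - 1
            return float(self.tpr[max(idx, 0)])
        raise ValueError("method must be 'interp' or 'step'")

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=label or f"AUC={self.auc:.2f}")
        ax.plot([0, 1], [0, 1], "k:", lw=0.5)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend()
        return ax


def roc(table: pd.DataFrame) -> RocResult:
    """ROC over all distinct p-value thresholds of a detection table.

    ``table`` needs columns ``condition`` and ``p``; rows with silence are
    negatives, speech/noise rows positives.  FPR(θ) and TPR(θ) are the
    class fractions with p < θ; AUC is the trapezoid area (equal to the
    tie-corrected Mann-Whitney statistic).
    """
    labels = table["condition"].isin(POSITIVE_CONDITIONS).to_numpy()
    p = table["p"].to_numpy(dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("detection table needs both positive and negative rows")
    thresholds = np.concatenate([[0.0], np.unique(p), [np.inf]])
    fpr = np.array([(p[~labels] < th).mean() for th in thresholds])
    tpr = np.array([(p[labels] < th).mean() for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, n_pos=n_pos, n_neg=n_neg
    )


# --------------------------------------------------------------------------
# canonical detection pipeline
# --------------------------------------------------------------------------

def run_canonical_analysis(
    recordings: list[Recording],
    rate: float = 0.6,
    boxcar_dur: float | None = 3.0,
    nuisance: NuisanceSpec = NuisanceSpec("short_pca", None),
    rois: tuple[str, ...] = STG_ROIS,
    ar_order: int = 4,
    drift_hf: float = 0.01,
    hrf: HrfParams = HrfParams(),
    side: str = "two-sided",
    ppf: float = 0.1,
) -> pd.DataFrame:
    """Canonical-HRF GLM detection table for a cohort of raw recordings.

    Per subject: resample -> optical density -> Beer-Lambert -> distance
    pruning -> canonical GLM (boxcar ⊛ HRF, cosine drifts, chosen
    short-channel nuisance, AR prewhitening) on the ROI's long channels.
    Returns one row per (subject, unit, condition, chroma) with the GLM
    p-value; ``unit`` is "channel" (individual channels) or "roi"
    (inverse-SE pooled).
    """
    rows = []
    for subject, rec in enumerate(recordings):
        r = resample(rec, rate) if rate < rec.sfreq else rec
        hb = beer_lambert(to_optical_density(r), ppf=ppf)
        hb = prune_channels(hb)
        target = sorted(
            {c for roi in rois for c in hb.montage.roi_map.get(roi, [])}
        )
        target = [c for c in target if c in hb.montage.long_indices]
        design = design_for_recording(
            hb, basis="canonical", boxcar_dur=boxcar_dur,
            drift_hf=drift_hf, hrf=hrf, nuisance=nuisance,
        )
        fit = HemodynamicGLM(hb, design, channels=target).fit(ar_order=ar_order)
        ct = fit.condition_table(side=side)
        for _, row in ct.iterrows():
            rows.append(
                (subject, "channel", int(row.channel),
                 hb.montage.roi_of(int(row.channel)),
                 row.condition, row.chroma, row.beta, row.se, row.p)
            )
        for roi in rois:
            pooled = fit.pool_roi(roi)
            for _, row in pooled.iterrows():
                rows.append(
                    (subject, "roi", -1, roi, row.condition, row.chroma,
                     row.beta, row.se, row.p)
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "unit", "channel", "roi",
                 "condition", "chroma", "beta", "se", "p"],
    )


def detection_subset(
    table: pd.DataFrame, unit: str = "channel", chroma: str = "hbo"
) -> pd.DataFrame:
    """Rows of one analysis level and chromophore (the panel the ROC pools)."""
    return table.query("unit == @unit and chroma == @chroma").reset_index(drop=True)


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

DEFAULT_NUISANCE_SWEEP: tuple[NuisanceSpec, ...] = (
    NuisanceSpec("none"),
    NuisanceSpec("short_pca", 1),
    NuisanceSpec("short_pca", 2),
    NuisanceSpec("short_pca", 4),
    NuisanceSpec("short_pca", None),
    NuisanceSpec("short_individual"),
    NuisanceSpec("short_mean"),
)


def sweep_nuisance(
    recordings: list[Recording],
    methods: tuple[NuisanceSpec, ...] = DEFAULT_NUISANCE_SWEEP,
    unit: str = "channel",
    chroma: str = "hbo",
    **kwargs,
) -> dict[str, RocResult]:
    """One ROC per short-channel correction method (STG channels only)."""
    out = {}
    for spec in methods:
        table = run_canonical_analysis(recordings, nuisance=spec, **kwargs)
        out[spec.label] = roc(detection_subset(table, unit, chroma))
    return out


def sweep_rate(
    recordings: list[Recording],
    rates: tuple[float, ...] = (0.2, 0.6, 1.0, 2.0),
    unit: str = "channel",
    chroma: str = "hbo",
    **kwargs,
) -> dict[float, RocResult]:
    """One ROC per analysis sample rate (resampling precedes fitting)."""
    out = {}
    for rate in rates:
        table = run_canonical_analysis(recordings, rate=rate, **kwargs)
        out[rate] = roc(detection_subset(table, unit, chroma))
    return out


def sweep_boxcar(
    recordings: list[Recording],
    durations: tuple[float, ...] = (0.5, 1.0, 3.0, 5.0),
    unit: str = "channel",
    chroma: str = "hbo",
    **kwargs,
) -> dict[float, RocResult]:
    """One ROC per boxcar duration used in the canonical design."""
    out = {}
    for dur in durations:
        table = run_canonical_analysis(recordings, boxcar_dur=dur, **kwargs)
        out[dur] = roc(detection_subset(table, unit, chroma))
    return out
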