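"""GLM design matrices: condition regressors, drifts, short-channel nuisance.

Condition regressors come in two bases:

* ``canonical`` — a boxcar per stimulus (height 1, duration the stimulus
  duration unless overridden) convolved with the canonical double-gamma
  HRF.  Columns are scaled so an isolated event's response peaks at 1,
  which puts the fitted beta on the same μM scale as the simulator's and
  averaging pipeline's "amplitude".
* ``fir`` — one stick regressor per condition and integer-second delay
  (0..n-1 s), each stick a one-second boxcar at the analysis rate; the
  fitted weights trace the deconvolved response.

Slow drifts are modelled with a cosine (DCT-II) basis up to a cutoff
frequency, plus a constant.  Systemic nuisance variants project out
short-channel information: their per-chromophore mean, every short
channel individually, or principal components of the centred
short-channel matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventSchedule, Recording
from .hrf import HrfParams, canonical_hrf


@dataclass(frozen=True)
class NuisanceSpec:
    """Short-channel nuisance choice for the GLM.

    method: one of ``none``, ``short_mean``, ``short_individual``,
    ``short_pca``.  For ``short_pca``, ``n_components=None`` keeps all
    components.
    """

    method: str = "none"
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.method not in {"none", "short_mean", "short_individual", "short_pca"}:
            raise ValueError(f"unknown nuisance method {self.method!r}")

    @property
    def label(self) -> str:
        if self.method == "short_pca":
            k = "all" if self.n_components is None else str(self.n_components)
            return f"short_pca_{k}"
        return self.method


@dataclass
class DesignMatrix:
    """Named regressor columns aligned to samples."""

    frame: pd.DataFrame
    basis: str
    sfreq: float
    condition_columns: dict[str, list[str]]
    fir_delays: np.ndarray | None = None

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("design column names must be unique")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_regressors(self) -> int:
        return self.frame.shape[1]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.frame.to_numpy(), aspect="auto", interpolation="nearest")
        ax.set_xticks(range(self.n_regressors))
        ax.set_xticklabels(self.frame.columns, rotation=90, fontsize=6)
        ax.set_ylabel("sample")
        return ax


def cosine_drift_basis(n_samples: int, sfreq: float, high_freq: float = 0.01) -> np.ndarray:
    """DCT-II cosine columns with frequencies k/(2T) up to ``high_freq`` Hz."""
    T = n_samples / sfreq
    k_max = int(np.floor(2.0 * T * high_freq))
    n = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_samples)) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


def _boxcar(
    schedule: EventSchedule, condition: str, n_samples: int, sfreq: float,
    duration: float | None,
) -> np.ndarray:
    sub = schedule.for_condition(condition)
    u = np.zeros(n_samples)
    for onset, dur in zip(sub.onsets, sub.durations):
        d = duration if duration is not None else dur
        i0 = int(round(onset * sfreq))
        i1 = max(i0 + 1, int(round((onset + d) * sfreq)))
        u[i0:min(i1, n_samples)] = 1.0
    return u


def nuisance_columns(
    spec: NuisanceSpec,
    short_data: np.ndarray | None,
    short_chroma: list[str] | None = None,
) -> pd.DataFrame:
    """Build the short-channel nuisance block (samples x columns)."""
    if spec.method == "none":
        return pd.DataFrame()
    if short_data is None or short_data.size == 0:
        raise ValueError(f"nuisance method {spec.label!r} needs short-channel data")
    short_data = np.atleast_2d(short_data)
    n_rows = short_data.shape[0]
    if short_chroma is None:
        short_chroma = [f"c{i}" for i in range(n_rows)]

    if spec.method == "short_mean":
        cols = {}
        for tag in dict.fromkeys(short_chroma):
            rows = [i for i, t in enumerate(short_chroma) if t == tag]
            cols[f"short_mean_{tag}"] = short_data[rows].mean(axis=0)
        return pd.DataFrame(cols)

    if spec.method == "short_individual":
        return pd.DataFrame(
            {f"short{i}_{short_chroma[i]}": short_data[i] for i in range(n_rows)}
        )

    # short_pca: left singular vectors of the centred (samples x rows) matrix
    k = spec.n_components if spec.n_components is not None else n_rows
    if k > n_rows:
        raise ValueError(f"requested {k} PCs but only {n_rows} short-channel rows")
    centred = short_data.T - short_data.mean(axis=1)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    return pd.DataFrame({f"short_pc{i + 1}": u[:, i] * s[i] for i in range(k)})


def build_design(
    schedule: EventSchedule,
    n_samples: int,
    sfreq: float,
    basis: str = "canonical",
    boxcar_dur: float | None = None,
    fir_n: int = 14,
    drift_hf: float = 0.01,
    hrf: HrfParams = HrfParams(),
    nuisance: NuisanceSpec = NuisanceSpec(),
    short_data: np.ndarray | None = None,
    short_chroma: list[str] | None = None,
) -> DesignMatrix:
    """Assemble the full design matrix for one recording.

    ``boxcar_dur`` overrides the stimulus duration of every condition
    (canonical basis only); all three conditions — including silence, whose
    beta is the false-positive probe — get a column.
    """
    if len(schedule) == 0:
        raise ValueError("cannot build a design from an empty schedule")
    if basis not in {"canonical", "fir"}:
        raise ValueError(f"unknown basis {basis!r}")
    if basis == "fir" and boxcar_dur is not None:
        raise ValueError("boxcar_dur does not apply to the FIR basis")
    if boxcar_dur is not None and boxcar_dur <= 0:
        raise ValueError("boxcar_dur must be positive")

    cols: dict[str, np.ndarray] = {}
    condition_columns: dict[str, list[str]] = {}
    fir_delays = None

    if basis == "canonical":
        kernel = canonical_hrf(hrf, sfreq)
        for cond in schedule.condition_set:
            u = _boxcar(schedule, cond, n_samples, sfreq, boxcar_dur)
            reg = np.convolve(u, kernel)[:n_samples]
            # scale so one isolated event peaks at 1 (beta is then in μM)
            dur = boxcar_dur if boxcar_dur is not None else float(
                schedule.for_condition(cond).durations[0]
            )
            single = np.convolve(np.ones(max(1, int(round(dur * sfreq)))), kernel)
            reg = reg / single.max()
            cols[cond] = reg
            condition_columns[cond] = [cond]
    else:
        fir_delays = np.arange(fir_n)
        for cond in schedule.condition_set:
            sub = schedule.for_condition(cond)
            names = []
            for d in fir_delays:
                col = np.zeros(n_samples)
                for onset in sub.onsets:
                    i0 = int(round((onset + d) * sfreq))
                    i1 = max(i0 + 1, int(round((onset + d + 1.0) * sfreq)))
                    if i0 < n_samples:
                        col[i0:min(i1, n_samples)] = 1.0
                name = f"{cond}_delay{d}"
                cols[name] = col
                names.append(name)
            condition_columns[cond] = names

    for cond, names in condition_columns.items():
        if len(schedule.for_condition(cond)) and all(
            not cols[n].any() for n in names
        ):
            raise ValueError(f"condition {cond!r} produced an all-zero regressor")

    drift = cosine_drift_basis(n_samples, sfreq, drift_hf)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    cols["constant"] = np.ones(n_samples)

    nui = nuisance_columns(nuisance, short_data, short_chroma)
    for name in nui.columns:
        if len(nui[name]) != n_samples:
            raise ValueError("nuisance columns must match n_samples")
        cols[name] = nui[name].to_numpy()

    return DesignMatrix(
        frame=pd.DataFrame(cols),
        basis=basis,
        sfreq=sfreq,
        condition_columns=condition_columns,
        fir_delays=fir_delays,
    )


def design_for_recording(
    rec: Recording,
    basis: str = "canonical",
    boxcar_dur: float | None = None,
    fir_n: int = 14,
    drift_hf: float = 0.01,
    hrf: HrfParams = HrfParams(),
    nuisance: NuisanceSpec = NuisanceSpec(),
) -> DesignMatrix:
    """Convenience wrapper: pulls schedule, rate and short channels from ``rec``."""
    short = rec.montage.short_indices
    short_rows = rec.channel_rows(short) if short else np.empty(0, dtype=int)
    return build_design(
        rec.events,
        rec.n_samples,
        rec.sfreq,
        basis=basis,
        boxcar_dur=boxcar_dur,
        fir_n=fir_n,
        drift_hf=drift_hf,
        hrf=hrf,
        nuisance=nuisance,
        short_data=rec.data[short_rows] if len(short_rows) else None,
        short_chroma=[rec.row_chroma[r] for r in short_rows] or None,
    )
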