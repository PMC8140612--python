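"""Signal-domain preprocessing for the averaging and GLM pipelines.

Stage order is enforced through the recording's unit tag:

    raw intensity --to_optical_density--> optical density
    (SCI / TDDR / short-channel regression on optical density)
    --beer_lambert--> μM hemoglobin
    (negative-correlation enhancement, bandpass, epoching on μM)

Resampling and channel pruning are unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import HBO, HBR, Recording, Unit
from .montage import LONG_CHANNEL_BOUNDS, Montage
from .optics import DEFAULT_PPF, extinction_matrix, od_to_concentration


# --------------------------------------------------------------------------
# optical density
# --------------------------------------------------------------------------

def to_optical_density(rec: Recording) -> Recording:
    """ΔOD(t) = -ln(I(t) / mean(I)) per row.

    The reference is each row's mean intensity, so ΔOD (and everything
    derived from it) is defined relative to the session mean.
    """
    rec.require_unit(Unit.RAW_INTENSITY, "to_optical_density")
    if np.any(rec.data <= 0):
        bad = sorted(set(np.where(rec.data <= 0)[0] // 2))
        raise ValueError(f"non-positive intensity in channels {bad}")
    od = -np.log(rec.data / rec.data.mean(axis=1, keepdims=True))
    return rec.with_data(od, unit=Unit.OPTICAL_DENSITY)


# --------------------------------------------------------------------------
# scalp-coupling index
# --------------------------------------------------------------------------

@dataclass
class SciReport:
    """Per-channel cardiac-band wavelength correlation and the kept/dropped split."""

    sci: np.ndarray
    threshold: float
    kept: list[int]
    dropped: list[int]
    band: tuple[float, float]


def scalp_coupling_index(
    rec: Recording,
    band: tuple[float, float] = (0.7, 1.45),
    threshold: float = 0.8,
) -> SciReport:
    """Cardiac-band Pearson correlation between the two wavelengths per channel.

    A well-coupled optode pair shows the cardiac pulsation coherently at both
    wavelengths; channels with SCI below ``threshold`` are flagged for
    removal.  Requires the sample rate to resolve the cardiac band, which is
    why this step is computed before any aggressive downsampling.
    """
    rec.require_unit(Unit.OPTICAL_DENSITY, "scalp_coupling_index")
    if rec.sfreq <= 2 * band[1]:
        raise ValueError(
            f"sfreq {rec.sfreq} Hz cannot resolve the cardiac band {band}; "
            "compute the SCI before downsampling"
        )
    sos = signal.butter(5, band, btype="bandpass", fs=rec.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    sci = np.empty(rec.n_channels)
    for ch in range(rec.n_channels):
        a, b = filtered[2 * ch], filtered[2 * ch + 1]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            sci[ch] = 0.0
        else:
            sci[ch] = float(np.corrcoef(a, b)[0, 1])
    kept = [c for c in range(rec.n_channels) if sci[c] >= threshold]
    dropped = [c for c in range(rec.n_channels) if sci[c] < threshold]
    return SciReport(sci=sci, threshold=threshold, kept=kept, dropped=dropped, band=band)


# --------------------------------------------------------------------------
# temporal-derivative distribution repair
# --------------------------------------------------------------------------

def _tddr_1d(x: np.ndarray, sfreq: float, tune: float = 4.685,
             max_iter: int = 50) -> np.ndarray:
    """Robust-reweighting motion repair of one trace.

    The signal is split at 0.5 Hz; the low-frequency derivative is
    iteratively reweighted with Tukey biweights (robust location / spread
    via the median / scaled MAD) until the robust mean converges, the
    weighted derivative is re-integrated, and the high-frequency part is
    added back.  The output keeps the input mean.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    centred = x - mean

    fc = 0.5 * 2.0 / sfreq
    if fc < 1:
        fb, fa = signal.butter(3, fc)
        low = signal.filtfilt(fb, fa, centred, padlen=0)
    else:
        low = centred
    high = centred - low

    deriv = np.diff(low)
    w = np.ones_like(deriv)
    mu = np.inf
    eps = np.sqrt(np.finfo(float).eps)
    for _ in range(max_iter):
        mu0 = mu
        mu = np.sum(w * deriv) / np.sum(w)
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * np.median(dev)
        if sigma == 0:
            break
        r = dev / (sigma * tune)
        w = np.where(r < 1, (1 - r ** 2) ** 2, 0.0)
        if np.isfinite(mu0) and abs(mu - mu0) < eps * max(abs(mu), abs(mu0)):
            break

    new_deriv = w * (deriv - mu)
    low_fixed = np.concatenate([[0.0], np.cumsum(new_deriv)])
    low_fixed -= low_fixed.mean()
    return low_fixed + high + mean


def tddr(rec: Recording) -> Recording:
    """Temporal-derivative distribution repair, applied per row."""
    rec.require_unit(Unit.OPTICAL_DENSITY, "tddr")
    if rec.n_samples < 3:
        raise ValueError("tddr needs at least 3 samples")
    out = np.vstack([_tddr_1d(row, rec.sfreq) for row in rec.data])
    return rec.with_data(out)


# --------------------------------------------------------------------------
# short-channel regression
# --------------------------------------------------------------------------

def nearest_short_channel(montage: Montage, ch: int) -> int:
    """Index of the short channel whose midpoint is closest to channel ``ch``.

    Ties break toward the lowest channel index.
    """
    shorts = montage.short_indices
    if not shorts:
        raise ValueError("montage has no short channels")
    mid = montage.midpoint(ch)
    dists = [float(np.linalg.norm(mid - montage.midpoint(s))) for s in shorts]
    return shorts[int(np.argmin(dists))]


def short_channel_regress(rec: Recording) -> Recording:
    """Subtract the least-squares-scaled nearest short channel per long channel.

    For long-channel trace ``y`` and (matching-chroma) short-channel trace
    ``s``, the corrected trace is ``y - α s`` with ``α = <y', s'> / <s', s'>``
    computed on mean-centred signals — the scale that minimises residual
    variance with respect to the short channel's fluctuations.
    """
    if rec.unit is Unit.RAW_INTENSITY:
        raise ValueError("short_channel_regress expects optical density (or μM) data")
    shorts = rec.montage.short_indices
    if not shorts:
        raise ValueError("no short channels available for regression")
    out = rec.data.copy()
    for ch in rec.montage.long_indices:
        s = nearest_short_channel(rec.montage, ch)
        for k in (0, 1):
            y = rec.data[2 * ch + k]
            x = rec.data[2 * s + k]
            xc = x - x.mean()
            yc = y - y.mean()
            denom = float(xc @ xc)
            alpha = float(yc @ xc) / denom if denom > 0 else 0.0
            out[2 * ch + k] = y - alpha * x
    return rec.with_data(out)


# --------------------------------------------------------------------------
# modified Beer-Lambert law
# --------------------------------------------------------------------------

def beer_lambert(
    rec: Recording,
    ppf: float = DEFAULT_PPF,
    extinctions: np.ndarray | None = None,
) -> Recording:
    """Two-wavelength ΔOD -> ΔHbO/ΔHbR in μM via the modified Beer-Lambert law.

    Per channel, ``[ΔHbO; ΔHbR] = E⁻¹ [ΔOD_λ1; ΔOD_λ2] / (d_cm · ppf)`` with
    the bundled molar extinction matrix for the montage's wavelengths unless
    ``extinctions`` overrides it.
    """
    rec.require_unit(Unit.OPTICAL_DENSITY, "beer_lambert")
    E = (
        np.asarray(extinctions, dtype=float)
        if extinctions is not None
        else extinction_matrix(rec.montage.wavelengths)
    )
    if abs(np.linalg.det(E)) < 1e-12:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    out = np.empty_like(rec.data)
    for ch in range(rec.n_channels):
        d = rec.montage.sd_distance(ch)
        rows = slice(2 * ch, 2 * ch + 2)
        out[rows] = od_to_concentration(rec.data[rows], d, E, ppf)
    chroma = [HBO, HBR] * rec.n_channels
    return rec.with_data(out, unit=Unit.MOLAR, row_chroma=chroma)


# --------------------------------------------------------------------------
# negative-correlation enhancement
# --------------------------------------------------------------------------

def negative_correlation_enhance(rec: Recording) -> Recording:
    """Enforce the canonical HbO/HbR anti-correlation per channel.

    With ``β = σ(HbO)/σ(HbR)``: ``HbO' = (HbO - β·HbR)/2`` and
    ``HbR' = -HbO'/β``, which makes corr(HbO', HbR') exactly -1 while
    averaging the (sign-corrected) information of both chromophores.
    """
    rec.require_unit(Unit.MOLAR, "negative_correlation_enhance")
    out = rec.data.copy()
    for ch in range(rec.n_channels):
        hbo = rec.data[2 * ch]
        hbr = rec.data[2 * ch + 1]
        s_hbr = hbr.std()
        if s_hbr == 0:
            raise ZeroDivisionError(f"channel {ch}: σ(HbR) = 0")
        beta = hbo.std() / s_hbr
        hbo2 = 0.5 * (hbo - beta * hbr)
        out[2 * ch] = hbo2
        out[2 * ch + 1] = -hbo2 / beta
    return rec.with_data(out)


# --------------------------------------------------------------------------
# bandpass filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR bandpass: edges and transition widths in Hz."""

    l_freq: float = 0.01
    h_freq: float = 0.7
    l_trans: float = 0.005
    h_trans: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.l_freq < self.h_freq:
            raise ValueError("need 0 < l_freq < h_freq")
        if self.l_trans <= 0 or self.h_trans <= 0:
            raise ValueError("transition widths must be positive")


def _edge_taps(cutoff: float, trans: float, sfreq: float, pass_zero: bool) -> np.ndarray:
    """Hamming-window FIR low/high-pass with -6 dB point at ``cutoff``."""
    numtaps = int(np.ceil(3.3 * sfreq / trans))
    numtaps += 1 - numtaps % 2  # odd length, exactly linear phase
    return signal.firwin(numtaps, cutoff, window="hamming", pass_zero=pass_zero, fs=sfreq)


def design_bandpass(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Bandpass taps: cascade of a high-pass and a low-pass edge filter.

    Each edge gets its own Hamming-window design sized by its transition
    width (-6 dB at the band edge ± half the transition), so the overall
    length is governed by the narrower transition.  Taps are symmetric;
    application compensates the group delay, giving zero phase.
    """
    nyq = sfreq / 2.0
    hi_cut = spec.h_freq + spec.h_trans / 2.0
    lo_cut = max(spec.l_freq - spec.l_trans / 2.0, 1e-6)
    if hi_cut >= nyq:
        raise ValueError(
            f"band edge {hi_cut:g} Hz infeasible at sfreq {sfreq:g} Hz"
        )
    hp = _edge_taps(lo_cut, spec.l_trans, sfreq, pass_zero=False)
    lp = _edge_taps(hi_cut, spec.h_trans, sfreq, pass_zero=True)
    return np.convolve(hp, lp)


def apply_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase application of symmetric FIR taps with reflect padding."""
    delay = (len(taps) - 1) // 2
    n = data.shape[-1]
    if n <= 2:
        raise ValueError("signal too short to filter")
    pad = min(delay, n - 1)
    padded = np.pad(np.atleast_2d(data), [(0, 0), (pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=-1)
    out = out[:, pad:pad + n]
    return out if data.ndim > 1 else out[0]


def bandpass(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase FIR bandpass of every row."""
    if rec.sfreq <= 2 * spec.h_freq:
        raise ValueError(
            f"sfreq {rec.sfreq:g} Hz cannot support a {spec.h_freq:g} Hz passband edge"
        )
    taps = design_bandpass(spec, rec.sfreq)
    return rec.with_data(apply_fir(rec.data, taps))


# --------------------------------------------------------------------------
# resampling and pruning
# --------------------------------------------------------------------------

def resample(rec: Recording, target_sfreq: float) -> Recording:
    """Anti-aliased polyphase resampling; event times stay in seconds."""
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be positive")
    if target_sfreq > rec.sfreq:
        raise ValueError("upsampling is not supported")
    ratio = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    if up == down:
        return rec.copy()
    data = signal.resample_poly(rec.data, up, down, axis=-1, padtype="line")
    return Recording(
        data=data,
        sfreq=rec.sfreq * up / down,
        unit=rec.unit,
        montage=rec.montage,
        events=rec.events,
        row_chroma=list(rec.row_chroma),
    )


def prune_channels(
    rec: Recording,
    sci_report: SciReport | None = None,
    dist_bounds: tuple[float, float] = LONG_CHANNEL_BOUNDS,
) -> Recording:
    """Drop long channels failing the separation bounds or the SCI threshold.

    Short channels are always retained (they feed the nuisance regressors);
    fitting stages select long channels explicitly.
    """
    keep: list[int] = []
    for ch in range(rec.n_channels):
        d = rec.montage.sd_distance(ch)
        if ch in rec.montage.short_indices:
            keep.append(ch)
            continue
        if not dist_bounds[0] <= d <= dist_bounds[1]:
            continue
        if sci_report is not None and ch in sci_report.dropped:
            continue
        keep.append(ch)
    if not any(c not in rec.montage.short_indices for c in keep):
        raise ValueError("pruning removed every long channel")
    return rec.pick_channels(keep)
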