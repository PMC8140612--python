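"""Forward generator for block-design auditory fNIRS sessions.

Emulates the study design the package analyses: 17 subjects, 24 long +
8 short channels, 5.2 Hz raw sampling, three conditions (speech 5.25 s,
noise 5 s, silence 5 s) with 20 trials each and inter-stimulus intervals
uniform on [10, 20] s.  Neural responses are placed only in channels whose
ROI has a configured amplitude (by default the two STG regions); systemic
physiology (Mayer wave, cardiac pulsation, random-walk drift) is shared
across channels — including the short channels, which carry no neural
signal — with per-channel gains.  Concentrations are mapped through the
modified Beer-Lambert forward model to two-wavelength raw intensity, so
the generated recordings enter the pipelines exactly where real data
would.

Ground truth (noise-free traces, true amplitudes, the systemic trace) is
returned alongside each recording so parameter recovery is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventSchedule, Recording, Unit
from .hrf import HrfParams, event_response
from .montage import Montage, build_paper_montage, LEFT_STG, RIGHT_STG
from .optics import DEFAULT_PPF, concentration_to_od, extinction_matrix


def _default_durations() -> dict[str, float]:
    return {"speech": 5.25, "noise": 5.0, "silence": 5.0}


def _default_amplitudes() -> dict[tuple[str, str], float]:
    # peak ΔHbO in μM per (condition, ROI); silence carries no response
    return {
        ("speech", LEFT_STG): 2.0,
        ("speech", RIGHT_STG): 2.0,
        ("noise", LEFT_STG): 1.0,
        ("noise", RIGHT_STG): 1.0,
    }


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the forward generator.

    Amplitudes are peaks of the noise-free single-event ΔHbO response in
    μM; ΔHbR is ``hbr_ratio`` times ΔHbO.  Systemic amplitudes are μM.
    ``seed`` fixes the complete draw; subject ``i`` uses child seed
    ``seed + i``.
    """

    n_subjects: int = 17
    sfreq: float = 5.2
    trials_per_condition: int = 20
    isi_bounds: tuple[float, float] = (10.0, 20.0)
    durations: dict[str, float] = field(default_factory=_default_durations)
    amplitudes: dict[tuple[str, str], float] = field(default_factory=_default_amplitudes)
    hbr_ratio: float = -1.0 / 3.0
    # systemic HbR co-varies in phase with HbO (volume change), smaller
    systemic_hbr_ratio: float = 0.2
    hrf: HrfParams = field(default_factory=HrfParams)
    # systemic physiology
    mayer_freq: float = 0.1
    mayer_amp: float = 2.0
    cardiac_freq: float = 1.1
    cardiac_amp: float = 0.5
    drift_scale: float = 0.1  # random-walk step sd, μM per sample
    systemic_gain_bounds: tuple[float, float] = (0.5, 1.5)
    # noise
    noise_sigma: float = 1.0  # stationary sd of AR(1) concentration noise, μM
    noise_ar1: float = 0.5
    od_noise_sigma: float = 2e-5  # per-wavelength instrument noise, OD units
    subject_gain_sd: float = 0.2  # inter-subject neural amplitude spread
    # optics
    ppf: float = DEFAULT_PPF
    wavelengths: tuple[float, float] = (760.0, 850.0)
    # session padding
    lead_in: float = 15.0
    tail: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isi_bounds[0] >= self.isi_bounds[1]:
            raise ValueError("isi_bounds must satisfy lower < upper")
        for v in list(self.amplitudes.values()) + [self.mayer_amp, self.cardiac_amp]:
            if not np.isfinite(v):
                raise ValueError("amplitudes must be finite")
        if not 0 <= abs(self.noise_ar1) < 1:
            raise ValueError("noise_ar1 must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """Known truth of one simulated session (concentration space, μM).

    Rows follow the Recording convention: ``2*ch`` is HbO, ``2*ch+1`` HbR.
    ``neural`` and ``systemic`` are noise-free; their sum is the noise-free
    concentration signal before AR noise and instrument noise.
    ``amplitudes`` are this subject's realised single-event peaks per
    (condition, channel); ``configured_amplitudes`` the cohort-level values.
    """

    neural: np.ndarray
    systemic: np.ndarray
    amplitudes: dict[tuple[str, int], float]
    configured_amplitudes: dict[tuple[str, int], float]
    schedule: EventSchedule
    systemic_base: np.ndarray  # shared (pre-gain) HbO systemic trace
    channel_gains: np.ndarray
    subject_gain: float

    @property
    def clean(self) -> np.ndarray:
        return self.neural + self.systemic


def generate_events(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> EventSchedule:
    """Randomly interleaved trials with ISI ~ U(isi_bounds) (offset to onset)."""
    rng = rng or np.random.default_rng(cfg.seed)
    conds = [c for c in cfg.durations for _ in range(cfg.trials_per_condition)]
    if not conds:
        return EventSchedule.empty()
    order = rng.permutation(len(conds))
    conds = [conds[i] for i in order]
    onsets, durations = [], []
    t = cfg.lead_in
    for c in conds:
        onsets.append(t)
        durations.append(cfg.durations[c])
        t += cfg.durations[c] + rng.uniform(*cfg.isi_bounds)
    return EventSchedule(
        np.array(onsets), np.array(durations), np.array(conds, dtype=object)
    )


def _n_samples(cfg: SimulationConfig, schedule: EventSchedule) -> int:
    end = cfg.lead_in + cfg.tail
    if len(schedule):
        end = schedule.onsets[-1] + schedule.durations[-1] + cfg.tail
    return int(np.ceil(end * cfg.sfreq))


def generate_neural(
    cfg: SimulationConfig,
    schedule: EventSchedule,
    montage: Montage,
    subject_gain: float = 1.0,
    n_samples: int | None = None,
) -> GroundTruth:
    """Noise-free neural concentration traces for every channel.

    Each channel in an ROI with a configured amplitude receives the sum over
    that condition's events of ``amplitude x response(t - onset)``, where the
    response is the stimulus boxcar convolved with the canonical HRF and
    peak-normalised (so the configured amplitude IS the isolated-event peak).
    Short channels and ROIs without an entry stay identically zero.
    """
    n = n_samples or _n_samples(cfg, schedule)
    n_rows = 2 * montage.n_channels
    neural = np.zeros((n_rows, n))

    for (cond, roi), amp in cfg.amplitudes.items():
        if roi not in montage.roi_map:
            raise KeyError(f"amplitude table names unknown ROI {roi!r}")

    # one condition-level regressor, reused across channels
    cond_traces: dict[str, np.ndarray] = {}
    for cond, dur in cfg.durations.items():
        sub = schedule.for_condition(cond)
        trace = np.zeros(n)
        if len(sub):
            resp = event_response(dur, cfg.hrf, cfg.sfreq)
            for onset in sub.onsets:
                i0 = int(round(onset * cfg.sfreq))
                seg = resp[: max(0, n - i0)]
                trace[i0:i0 + len(seg)] += seg
        cond_traces[cond] = trace

    amplitudes: dict[tuple[str, int], float] = {}
    configured: dict[tuple[str, int], float] = {}
    for (cond, roi), amp in cfg.amplitudes.items():
        for ch in montage.roi_map[roi]:
            a = subject_gain * amp
            amplitudes[(cond, ch)] = amplitudes.get((cond, ch), 0.0) + a
            configured[(cond, ch)] = configured.get((cond, ch), 0.0) + amp
            neural[2 * ch] += a * cond_traces[cond]
            neural[2 * ch + 1] += cfg.hbr_ratio * a * cond_traces[cond]

    return GroundTruth(
        neural=neural,
        systemic=np.zeros_like(neural),
        amplitudes=amplitudes,
        configured_amplitudes=configured,
        schedule=schedule,
        systemic_base=np.zeros(n),
        channel_gains=np.ones(montage.n_channels),
        subject_gain=subject_gain,
    )


def generate_session(
    cfg: SimulationConfig,
    subject_index: int = 0,
    montage: Montage | None = None,
    schedule: EventSchedule | None = None,
) -> tuple[Recording, GroundTruth]:
    """One subject's raw-intensity recording plus its ground truth.

    Concentrations = neural + systemic + AR(1) noise; the systemic trace
    (Mayer sinusoid with random phase, cardiac sinusoid, random-walk drift)
    is shared across all channels with per-channel gains drawn from
    U(systemic_gain_bounds) and is fully present in short channels, which
    carry no neural signal.  Concentrations map to optical density through
    the extinction matrix, channel separation and partial pathlength
    factor, then to intensity ``I = exp(-OD)`` with unit baseline.
    """
    rng = np.random.default_rng(cfg.seed + subject_index)
    montage = montage or build_paper_montage(wavelengths=cfg.wavelengths)
    if schedule is None:
        schedule = generate_events(cfg, rng)
    else:
        generate_events(cfg, rng)  # keep the downstream draws seed-stable
    n = _n_samples(cfg, schedule)
    t = np.arange(n) / cfg.sfreq
    nch = montage.n_channels

    subject_gain = 1.0
    if cfg.subject_gain_sd > 0:
        subject_gain = max(0.1, 1.0 + cfg.subject_gain_sd * rng.standard_normal())

    gt = generate_neural(cfg, schedule, montage, subject_gain, n_samples=n)

    # shared systemic trace (HbO space)
    base = (
        cfg.mayer_amp * np.sin(2 * np.pi * cfg.mayer_freq * t + rng.uniform(0, 2 * np.pi))
        + cfg.cardiac_amp * np.sin(2 * np.pi * cfg.cardiac_freq * t + rng.uniform(0, 2 * np.pi))
    )
    if cfg.drift_scale > 0:
        base = base + np.cumsum(cfg.drift_scale * rng.standard_normal(n))
    gains = rng.uniform(*cfg.systemic_gain_bounds, size=nch)

    systemic = np.zeros_like(gt.neural)
    for ch in range(nch):
        systemic[2 * ch] = gains[ch] * base
        systemic[2 * ch + 1] = cfg.systemic_hbr_ratio * gains[ch] * base
    gt.systemic = systemic
    gt.systemic_base = base
    gt.channel_gains = gains

    conc = gt.neural + systemic
    if cfg.noise_sigma > 0:
        innov_sd = cfg.noise_sigma * np.sqrt(1.0 - cfg.noise_ar1 ** 2)
        eps = innov_sd * rng.standard_normal(conc.shape)
        noise = np.empty_like(eps)
        # stationary start: x0 has the stationary sd
        noise[:, 0] = cfg.noise_sigma * rng.standard_normal(conc.shape[0])
        for i in range(1, n):
            noise[:, i] = cfg.noise_ar1 * noise[:, i - 1] + eps[:, i]
        conc = conc + noise

    E = extinction_matrix(cfg.wavelengths)
    od = np.empty_like(conc)
    for ch in range(nch):
        rows = slice(2 * ch, 2 * ch + 2)
        od[rows] = concentration_to_od(conc[rows], montage.sd_distance(ch), E, cfg.ppf)
    if cfg.od_noise_sigma > 0:
        od = od + cfg.od_noise_sigma * rng.standard_normal(od.shape)

    rec = Recording(
        data=np.exp(-od),
        sfreq=cfg.sfreq,
        unit=Unit.RAW_INTENSITY,
        montage=montage,
        events=schedule,
        row_chroma=[f"{cfg.wavelengths[i % 2]:g}" for i in range(2 * nch)],
    )
    return rec, gt


def generate_cohort(
    cfg: SimulationConfig, montage: Montage | None = None
) -> list[tuple[Recording, GroundTruth]]:
    """All subjects of the configured study (deterministic child seeds)."""
    montage = montage or build_paper_montage(wavelengths=cfg.wavelengths)
    return [generate_session(cfg, i, montage) for i in range(cfg.n_subjects)]


# --------------------------------------------------------------------------
# test utilities
# --------------------------------------------------------------------------

def inject_step(data: np.ndarray, sample: int, magnitude: float) -> np.ndarray:
    """Add a level shift from ``sample`` onward (motion-artifact probe)."""
    out = np.array(data, dtype=float, copy=True)
    out[..., sample:] += magnitude
    return out


def inject_spike(data: np.ndarray, sample: int, magnitude: float, width: int = 1) -> np.ndarray:
    """Add a transient spike of the given width (motion-artifact probe)."""
    out = np.array(data, dtype=float, copy=True)
    out[..., sample:sample + width] += magnitude
    return out
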