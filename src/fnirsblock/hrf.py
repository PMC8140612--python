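"""Canonical hemodynamic response function (double-gamma, SPM form)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the canonical double-gamma HRF.

    The kernel is ``gamma.pdf(t; peak_delay/peak_dispersion, peak_dispersion)
    - undershoot_ratio * gamma.pdf(t; undershoot_delay/undershoot_dispersion,
    undershoot_dispersion)``, sampled over ``[0, time_length]`` seconds and
    peak-normalised to 1.  Defaults are the standard published constants
    (6 s / 16 s delays, unit dispersions, undershoot ratio 1/6).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    time_length: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "time_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")


def canonical_hrf(params: HrfParams = HrfParams(), sfreq: float = 1.0) -> np.ndarray:
    """Sample the canonical HRF at ``sfreq``; peak value is exactly 1."""
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    t = np.arange(0.0, params.time_length, 1.0 / sfreq)
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - params.undershoot_ratio * under
    m = kernel.max()
    if m <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / m


def event_response(
    duration: float, params: HrfParams = HrfParams(), sfreq: float = 1.0
) -> np.ndarray:
    """Boxcar of ``duration`` seconds convolved with the HRF, peak-normalised.

    This is the noise-free response shape of one isolated event; a configured
    or estimated amplitude multiplies this curve, so "amplitude" always means
    the peak of the single-event response in μM.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    kernel = canonical_hrf(params, sfreq)
    n_box = max(1, int(round(duration * sfreq)))
    resp = np.convolve(np.ones(n_box), kernel)
    return resp / resp.max()
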