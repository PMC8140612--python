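"""Modified Beer-Lambert optics shared by the simulator and preprocessing.

The linearised attenuation model for a channel of source-detector
separation ``d`` (metres) is

    ΔOD_λ(t) = ε_λ,HbO · ΔHbO(t) + ε_λ,HbR · ΔHbR(t)) · d_cm · ppf

with molar extinction coefficients ε in M⁻¹·cm⁻¹, concentrations in M,
and ``ppf`` the partial pathlength factor (default 0.1).  Inversion of the
2x2 system per channel maps two-wavelength optical density to ΔHbO/ΔHbR.
"""

from __future__ import annotations

import numpy as np

#: Molar extinction coefficients (M^-1 cm^-1), {wavelength nm: (HbO, HbR)},
#: from the standard compiled hemoglobin absorption tables.
EXTINCTION_TABLE: dict[float, tuple[float, float]] = {
    690.0: (276.0, 2051.96),
    760.0: (586.0, 1548.52),
    780.0: (710.0, 1075.44),
    808.0: (871.2, 723.52),
    830.0: (974.0, 693.04),
    850.0: (1058.0, 691.32),
}

DEFAULT_PPF = 0.1


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 matrix E with E[i] = (ε_HbO, ε_HbR) at wavelength i (M^-1 cm^-1)."""
    rows = []
    for wl in wavelengths:
        if wl not in EXTINCTION_TABLE:
            raise KeyError(
                f"no extinction coefficients for {wl} nm; "
                f"available: {sorted(EXTINCTION_TABLE)}"
            )
        rows.append(EXTINCTION_TABLE[wl])
    E = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(E)) < 1e-12:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    return E


def concentration_to_od(
    conc_um: np.ndarray, distance_m: float, E: np.ndarray, ppf: float = DEFAULT_PPF
) -> np.ndarray:
    """Forward optics: (2, n) ΔHbO/ΔHbR in μM -> (2, n) ΔOD at the two wavelengths."""
    pathlength_cm = distance_m * 100.0 * ppf
    return (E @ (conc_um * 1e-6)) * pathlength_cm


def od_to_concentration(
    od: np.ndarray, distance_m: float, E: np.ndarray, ppf: float = DEFAULT_PPF
) -> np.ndarray:
    """Inverse optics: (2, n) ΔOD -> (2, n) ΔHbO/ΔHbR in μM."""
    pathlength_cm = distance_m * 100.0 * ppf
    if pathlength_cm <= 0:
        raise ValueError("distance and ppf must be positive")
    conc_m = np.linalg.solve(E, od) / pathlength_cm
    return conc_m * 1e6
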