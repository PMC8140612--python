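"""AR-prewhitened GLM fitting and ROI pooling, statsmodels-style.

:class:`HemodynamicGLM` pairs a μM recording with a design matrix;
``fit()`` runs, per channel row: an OLS pass, Yule-Walker AR estimation
on the residuals, whitening of data and design by ``1 - Σ aᵢ z⁻ⁱ``, and
an OLS refit on the whitened system.  The returned :class:`GLMResults`
carries per-(channel, chroma, regressor) estimates with uncertainties,
inverse-SE ROI pooling, and FIR waveform reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats
from statsmodels.regression.linear_model import yule_walker

from .core import Recording, Unit
from .design import DesignMatrix
from .montage import Montage


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(len(diag)) if diag[i] < tol]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad or 'unresolved'}"
        )


def _whiten(v: np.ndarray, ar: np.ndarray) -> np.ndarray:
    """Apply the whitening filter 1 - Σ aᵢ z⁻ⁱ and drop the warm-up samples."""
    if len(ar) == 0:
        return v
    b = np.concatenate([[1.0], -ar])
    out = sp_signal.lfilter(b, [1.0], v, axis=0)
    return out[len(ar):]


class HemodynamicGLM:
    """GLM of a μM recording against a design matrix.

    Parameters
    ----------
    recording
        μM (molar) recording.
    design
        Design matrix with the same number of samples.
    channels
        ``"long"`` (default) fits long channels only, ``"all"`` every
        channel, or an explicit list of channel indices.
    """

    def __init__(
        self,
        recording: Recording,
        design: DesignMatrix,
        channels: str | list[int] = "long",
    ) -> None:
        recording.require_unit(Unit.MOLAR, "HemodynamicGLM")
        if design.frame.shape[0] != recording.n_samples:
            raise ValueError("design and recording sample counts differ")
        self.recording = recording
        self.design = design
        if channels == "long":
            self.channel_indices = recording.montage.long_indices
        elif channels == "all":
            self.channel_indices = list(range(recording.n_channels))
        else:
            self.channel_indices = list(channels)

    def fit(self, ar_order: int = 4, iterate: bool = False) -> "GLMResults":
        """Fit every selected channel row; see module docstring for the steps.

        ``iterate`` repeats the AR estimation/whitening/refit loop once more
        on the whitened residuals (off by default: a single pass).
        """
        X = self.design.values
        names = list(self.design.frame.columns)
        n, k = X.shape
        if n <= k + ar_order:
            raise ValueError("need more samples than regressors + AR order")
        _check_rank(X, names)

        rows_out = []
        ar_coefs: dict[tuple[int, str], np.ndarray] = {}
        for ch in self.channel_indices:
            for r in self.recording.rows_for_channel(ch):
                chroma = self.recording.row_chroma[r]
                y = self.recording.data[r]
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                ar = np.empty(0)
                if ar_order > 0 and resid.std() > 0:
                    n_pass = 2 if iterate else 1
                    Xw, yw = X, y
                    for _ in range(n_pass):
                        ar, _sigma = yule_walker(resid, order=ar_order, method="adjusted")
                        Xw = _whiten(X, ar)
                        yw = _whiten(y, ar)
                        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
                        resid = yw - Xw @ beta
                else:
                    Xw, yw = X, y
                dof = Xw.shape[0] - k
                rss = float(resid @ resid)
                sigma2 = rss / dof if dof > 0 else np.nan
                xtx_inv = np.linalg.inv(Xw.T @ Xw)
                se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
                p = 2.0 * stats.t.sf(np.abs(t), dof)
                p = np.clip(p, np.finfo(float).tiny, 1.0)
                ar_coefs[(ch, chroma)] = ar
                for j, name in enumerate(names):
                    rows_out.append(
                        (ch, chroma, name, beta[j], se[j], float(t[j]), float(p[j]), dof)
                    )

        table = pd.DataFrame(
            rows_out,
            columns=["channel", "chroma", "regressor", "beta", "se", "t", "p", "dof"],
        )
        return GLMResults(
            estimates=table,
            design=self.design,
            montage=self.recording.montage,
            ar_order=ar_order,
            ar_coefs=ar_coefs,
        )


@dataclass
class GLMResults:
    """Estimates of a fitted :class:`HemodynamicGLM`."""

    estimates: pd.DataFrame
    design: DesignMatrix
    montage: Montage
    ar_order: int
    ar_coefs: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    # -- access -----------------------------------------------------------

    def params(self, channel: int, chroma: str) -> pd.Series:
        sub = self.estimates.query("channel == @channel and chroma == @chroma")
        return sub.set_index("regressor")["beta"]

    def condition_table(self, side: str = "two-sided") -> pd.DataFrame:
        """Per-(channel, chroma, condition) beta/SE/p for canonical fits.

        ``side='greater'`` converts to one-sided p-values for a positive
        response (the directional detection convention).
        """
        if self.design.basis != "canonical":
            raise ValueError("condition_table requires a canonical-basis fit")
        conds = list(self.design.condition_columns)
        sub = self.estimates[self.estimates.regressor.isin(conds)].copy()
        sub = sub.rename(columns={"regressor": "condition"})
        if side == "greater":
            p_one = stats.t.sf(sub["t"], sub["dof"])
            sub["p"] = np.clip(p_one, np.finfo(float).tiny, 1.0)
        elif side != "two-sided":
            raise ValueError("side must be 'two-sided' or 'greater'")
        return sub.reset_index(drop=True)

    # -- pooling ----------------------------------------------------------

    def pool_roi(self, roi: str, weight: str = "inv_se") -> pd.DataFrame:
        """Inverse-SE weighted ROI pooling of condition (or FIR) betas.

        With weights ``wᵢ = 1/SEᵢ`` (default; ``weight='inv_var'`` uses
        1/SEᵢ²): pooled β = Σwᵢβᵢ/Σwᵢ, pooled SE = √(Σwᵢ²SEᵢ²)/Σwᵢ, and p
        from the normal approximation on pooled β / pooled SE.
        """
        channels = [
            c for c in self.montage.roi_channels(roi)
            if c in set(self.estimates.channel)
        ]
        if not channels:
            raise ValueError(f"no fitted channels in ROI {roi!r}")
        regs = [n for names in self.design.condition_columns.values() for n in names]
        sub = self.estimates[
            self.estimates.channel.isin(channels) & self.estimates.regressor.isin(regs)
        ]
        out = []
        for (chroma, reg), grp in sub.groupby(["chroma", "regressor"], sort=False):
            b, s = grp["beta"].to_numpy(), grp["se"].to_numpy()
            # floor exact-fit SEs so weights stay finite
            s = np.maximum(s, max(1e-12 * max(s.max(), 1.0), 1e-30))
            if weight == "inv_se":
                w = 1.0 / s
            elif weight == "inv_var":
                w = 1.0 / s ** 2
            else:
                raise ValueError("weight must be 'inv_se' or 'inv_var'")
            pooled_b = float(np.sum(w * b) / np.sum(w))
            pooled_se = float(np.sqrt(np.sum(w ** 2 * s ** 2)) / np.sum(w))
            z = pooled_b / pooled_se if pooled_se > 0 else np.inf * np.sign(pooled_b)
            p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
            cond = next(
                c for c, names in self.design.condition_columns.items() if reg in names
            )
            out.append((roi, cond, reg, chroma, pooled_b, pooled_se, z, p, len(b)))
        return pd.DataFrame(
            out,
            columns=["roi", "condition", "regressor", "chroma",
                     "beta", "se", "z", "p", "n_channels"],
        )

    def fir_waveform(self, roi: str, weight: str = "inv_se") -> pd.DataFrame:
        """Deconvolved response: pooled FIR betas indexed by delay (s).

        Summing each delay's weight-pooled beta traces the estimated
        response over 0..n-1 s per condition and chromophore.
        """
        if self.design.basis != "fir":
            raise ValueError("fir_waveform requires a FIR-basis fit")
        pooled = self.pool_roi(roi, weight=weight)
        delay = pooled["regressor"].str.extract(r"_delay(\d+)$")[0].astype(int)
        pooled = pooled.assign(delay_s=delay.to_numpy())
        return pooled[["roi", "condition", "chroma", "delay_s", "beta", "se", "p"]]

    # -- reporting --------------------------------------------------------

    def summary(self, max_rows: int = 40) -> str:
        lines = [
            "Hemodynamic GLM results",
            f"  basis: {self.design.basis}   regressors: {self.design.n_regressors}"
            f"   AR order: {self.ar_order}",
            f"  channels fitted: {self.estimates.channel.nunique()}",
            "",
        ]
        regs = [n for names in self.design.condition_columns.values() for n in names]
        sub = self.estimates[self.estimates.regressor.isin(regs)]
        lines.append(
            sub.head(max_rows).to_string(
                index=False, float_format=lambda v: f"{v: .4g}"
            )
        )
        if len(sub) > max_rows:
            lines.append(f"  ... ({len(sub) - max_rows} more rows)")
        return "\n".join(lines)
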