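"""Group-level (second-level) inference on subject response estimates.

The same linear mixed-effects machinery is applied to amplitudes from the
averaging pipeline and betas from the GLM pipeline:

* a no-intercept summary model with one fixed effect per
  condition x ROI x chromophore cell and a subject random intercept,
* a condition contrast (speech - noise) over the bilateral STG,
* a lateralisation contrast (left - right STG) within the speech
  condition,

each fitted per chromophore by REML with Wald tests.  When the random
intercept variance degenerates to ~0 the fit falls back to ordinary
least squares with a logged note (the two coincide in that limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .montage import LEFT_STG, RIGHT_STG, STG_ROIS

ALPHA = 0.05


@dataclass
class ContrastResult:
    """A fixed-effect contrast with its Wald test."""

    name: str
    chroma: str
    delta: float
    se: float
    p: float
    n_subjects: int
    method: str  # "mixedlm" or "ols-fallback"

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def summary(self) -> str:
        star = "*" if self.significant else ""
        return (f"{self.name} [{self.chroma}]: Δ = {self.delta:+.3f} μM "
                f"(SE {self.se:.3f}), p = {self.p:.3g}{star} "
                f"[{self.method}, n={self.n_subjects}]")


def _wald_p(delta: float, se: float) -> float:
    """Two-sided normal p; exact fits (SE = 0) give 1 for a zero effect."""
    if se == 0:
        return float(np.finfo(float).tiny) if abs(delta) > 1e-12 else 1.0
    return float(np.clip(2 * stats.norm.sf(abs(delta / se)),
                         np.finfo(float).tiny, 1.0))


def _require_columns(table: pd.DataFrame) -> None:
    need = {"subject", "roi", "condition", "chroma", "estimate"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"estimate table missing columns {sorted(missing)}")
    if not np.isfinite(table["estimate"]).all():
        raise ValueError("estimates must be finite")


def _mixed_fit(endog: np.ndarray, exog: np.ndarray, groups: np.ndarray,
               names: list[str]):
    """REML MixedLM with OLS fallback on degenerate random-effect variance."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog, groups=groups)
            res = model.fit(reml=True)
            var_re = float(np.squeeze(res.cov_re))
            if np.isfinite(var_re) and var_re > 1e-10 * max(endog.var(), 1e-12):
                return np.asarray(res.fe_params), np.asarray(res.bse_fe), "mixedlm"
        except Exception:
            pass
        res = sm.OLS(endog, exog).fit()
    warnings.warn("random-intercept variance degenerate; using OLS fallback",
                  stacklevel=3)
    return res.params[:len(names)], res.bse[:len(names)], "ols-fallback"


def summary_model(table: pd.DataFrame) -> pd.DataFrame:
    """Cell-means mixed model: one fixed effect per condition x ROI x chroma.

    Returns a tidy frame with the Wald z/p of each cell estimate against
    zero.  Cells missing from the table are reported in a warning.
    """
    _require_columns(table)
    df = table.copy()
    df["cell"] = (
        df["condition"].astype(str) + ":" + df["roi"].astype(str)
        + ":" + df["chroma"].astype(str)
    )
    expected = {
        f"{c}:{r}:{h}"
        for c in df["condition"].unique()
        for r in df["roi"].unique()
        for h in df["chroma"].unique()
    }
    missing = sorted(expected - set(df["cell"]))
    if missing:
        warnings.warn(f"unbalanced table; missing cells: {missing}", stacklevel=2)

    cells = sorted(df["cell"].unique())
    exog = pd.get_dummies(df["cell"])[cells].to_numpy(dtype=float)  # no intercept
    params, bse, method = _mixed_fit(
        df["estimate"].to_numpy(), exog, df["subject"].to_numpy(), cells
    )
    params = np.asarray(params, dtype=float)
    bse = np.asarray(bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, params / bse, np.inf * np.sign(params))
    p = np.array([_wald_p(b, s) for b, s in zip(params, bse)])
    cond, roi, chroma = zip(*(c.split(":") for c in cells))
    return pd.DataFrame(
        {
            "condition": cond, "roi": roi, "chroma": chroma,
            "estimate": np.asarray(params), "se": np.asarray(bse),
            "z": z, "p": p, "method": method,
        }
    )


def condition_contrast(
    table: pd.DataFrame, rois: tuple[str, ...] = STG_ROIS
) -> dict[str, ContrastResult]:
    """Speech - noise fixed effect over the (bilateral STG) ROI, per chroma."""
    _require_columns(table)
    sub = table[table.roi.isin(rois) & table.condition.isin(["speech", "noise"])]
    if sub.empty or set(sub.condition) != {"speech", "noise"}:
        raise ValueError("need both speech and noise rows over the requested ROIs")
    out = {}
    for chroma, grp in sub.groupby("chroma"):
        x = (grp["condition"] == "speech").to_numpy(dtype=float)
        exog = np.column_stack([np.ones(len(grp)), x])
        params, bse, method = _mixed_fit(
            grp["estimate"].to_numpy(), exog, grp["subject"].to_numpy(),
            ["intercept", "speech_minus_noise"],
        )
        delta, se = float(params[1]), float(bse[1])
        out[chroma] = ContrastResult(
            "speech - noise", chroma, delta, se, _wald_p(delta, se),
            grp["subject"].nunique(), method,
        )
    return out


def lateralization_contrast(
    table: pd.DataFrame, condition: str = "speech"
) -> dict[str, ContrastResult]:
    """Left - right STG fixed effect within one condition, per chroma."""
    _require_columns(table)
    sub = table[
        table.roi.isin([LEFT_STG, RIGHT_STG]) & (table.condition == condition)
    ]
    if sub.empty or set(sub.roi) != {LEFT_STG, RIGHT_STG}:
        raise ValueError("need both left and right STG rows for the contrast")
    out = {}
    for chroma, grp in sub.groupby("chroma"):
        x = (grp["roi"] == LEFT_STG).to_numpy(dtype=float)
        exog = np.column_stack([np.ones(len(grp)), x])
        params, bse, method = _mixed_fit(
            grp["estimate"].to_numpy(), exog, grp["subject"].to_numpy(),
            ["intercept", "left_minus_right"],
        )
        delta, se = float(params[1]), float(bse[1])
        out[chroma] = ContrastResult(
            "left - right STG", chroma, delta, se, _wald_p(delta, se),
            grp["subject"].nunique(), method,
        )
    return out


def agreement_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side contrasts from several sources with concordance flags.

    ``tables`` maps a source name (e.g. "averaging", "glm_corrected") to an
    estimate table.  For each research question and chromophore the report
    lists each source's (Δ, p) and whether all sources agree in sign and in
    significance at α = 0.05.
    """
    if len(tables) < 1:
        raise ValueError("need at least one source table")
    rows = []
    questions = {
        "speech_vs_noise": condition_contrast,
        "lateralization": lateralization_contrast,
    }
    for question, fn in questions.items():
        per_source = {src: fn(tbl) for src, tbl in tables.items()}
        chromas = sorted({c for res in per_source.values() for c in res})
        for chroma in chromas:
            results = {src: res[chroma] for src, res in per_source.items()
                       if chroma in res}
            if len(results) != len(tables):
                raise ValueError(f"sources disagree on available cells ({chroma})")
            signs = {np.sign(r.delta) for r in results.values()}
            sigs = {r.significant for r in results.values()}
            row = {"question": question, "chroma": chroma,
                   "sign_concordant": len(signs) == 1,
                   "significance_concordant": len(sigs) == 1,
                   "concordant": len(signs) == 1 and len(sigs) == 1}
            for src, r in results.items():
                row[f"{src}_delta"] = r.delta
                row[f"{src}_p"] = r.p
            rows.append(row)
    return pd.DataFrame(rows)
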