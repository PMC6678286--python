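"""Median-effect dose-response modelling and combination-index analysis.

The median-effect equation, fa/fu = (D/Dm)^m with fu = 1 - fa, linearises as

    log10(fa/(1-fa)) = m * log10(D) - m * log10(Dm)

so (m, Dm) come from an ordinary least-squares line on transformed data, with
r the Pearson correlation of the fit. Dm is the dose of median effect, i.e.
the IC50. The combination index at effect level fa for doses (d1, d2) is

    CI = d1/Dx1(fa) + d2/Dx2(fa),   Dx = Dm * (fa/(1-fa))^(1/m)

(the mutually exclusive, classic form): CI < 1 synergism, CI = 1 additivity,
CI > 1 antagonism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError

__all__ = [
    "DoseResponseSeries",
    "MedianEffectFit",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
    "classify_ci",
    "constant_ratio_analysis",
    "load_published_ci_table",
]

logger = logging.getLogger(__name__)

#: fa values of exactly 0 (no effect) or 1 (complete kill) cannot be
#: linearised; they are clipped to this band with a warning.
FA_CLIP = 1e-6


@dataclass
class DoseResponseSeries:
    """Dose / fraction-affected pairs for one drug.

    Replicates are averaged on the fa scale per dose before fitting. For
    constant-ratio combination series ``d1``/``d2`` hold the component doses
    and ``doses`` the total dose.
    """

    drug: str
    doses: np.ndarray
    fa: np.ndarray
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        if self.doses.shape != fa.shape:
            raise InputError("doses and fa must align")
        if np.any(self.doses <= 0):
            raise InputError("all doses must be positive")
        if np.any((fa < 0) | (fa > 1)):
            raise InputError("fraction affected must lie in [0, 1]")
        if np.any((fa <= FA_CLIP) | (fa >= 1 - FA_CLIP)):
            logger.warning("fa values at 0/1 clipped to (%g, %g)", FA_CLIP, 1 - FA_CLIP)
        self.fa = np.clip(fa, FA_CLIP, 1.0 - FA_CLIP)
        if np.unique(self.doses).size < 2:
            raise InputError("need at least 2 distinct doses")

    def averaged(self) -> "DoseResponseSeries":
        """Collapse replicate doses to their mean fa."""
        df = pd.DataFrame({"dose": self.doses, "fa": self.fa}).groupby("dose", as_index=False).mean()
        return DoseResponseSeries(drug=self.drug, doses=df["dose"].to_numpy(), fa=df["fa"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"drug": self.drug, "dose": self.doses, "fa": self.fa})


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: slope m, median-effect dose Dm (= IC50), and
    the Pearson r of the linearised fit."""

    drug: str
    m: float
    dm: float
    r: float

    def fa(self, dose: float | np.ndarray) -> float | np.ndarray:
        """Predicted fraction affected at a dose."""
        ratio = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        out = ratio / (1.0 + ratio)
        return float(out) if np.isscalar(dose) else out

    @property
    def ic50(self) -> float:
        return self.dm


def fit_median_effect(series: DoseResponseSeries) -> MedianEffectFit:
    """Least-squares median-effect fit on the linearised (log-log) scale."""
    avg = series.averaged()
    if np.unique(avg.fa).size < 2:
        raise InputError("fa values are all equal; the model is unidentifiable")
    x = np.log10(avg.doses)
    y = np.log10(avg.fa / (1.0 - avg.fa))
    res = stats.linregress(x, y)
    if res.slope == 0 or not math.isfinite(res.slope):
        raise DegenerateFitError(f"degenerate median-effect fit for {series.drug!r} (zero slope)")
    m = float(res.slope)
    dm = float(10.0 ** (-res.intercept / res.slope))
    return MedianEffectFit(drug=series.drug, m=m, dm=dm, r=float(res.rvalue))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose Dx producing effect level ``fa``: Dx = Dm * (fa/(1-fa))^(1/m).

    ``dose_for_effect(fit, 0.5)`` is Dm itself, the IC50.
    """
    if not 0.0 < fa < 1.0:
        raise InputError(f"effect level must lie in (0, 1), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
) -> float:
    """Chou–Talalay combination index (mutually exclusive form).

    CI = d1/Dx1 + d2/Dx2 where Dx_k is the dose of drug k alone producing the
    observed combination effect ``fa_combo``.
    """
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise InputError("component doses must be non-negative and not both zero")
    if not 0.0 < fa_combo < 1.0:
        raise InputError(f"fa_combo must lie in (0, 1), got {fa_combo}")
    ci = 0.0
    if d1 > 0:
        ci += d1 / dose_for_effect(fit1, fa_combo)
    if d2 > 0:
        ci += d2 / dose_for_effect(fit2, fa_combo)
    return float(ci)


def classify_ci(ci: float, tolerance: float = 0.0) -> str:
    """Label a combination index: CI < 1 synergism, CI = 1 additivity,
    CI > 1 antagonism; ``|CI - 1| <= tolerance`` counts as additivity."""
    if ci <= 0:
        raise InputError(f"combination index must be positive, got {ci}")
    if abs(ci - 1.0) <= tolerance:
        return "additivity"
    return "synergism" if ci < 1.0 else "antagonism"


def constant_ratio_analysis(
    series1: DoseResponseSeries,
    series2: DoseResponseSeries,
    combo: DoseResponseSeries,
    ratio: float,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """CI table for a constant-ratio (d2:d1 = ratio) combination design.

    Fits single-agent median-effect models, checks the declared ratio against
    the combination's component doses (1e-9 relative), fits the combination on
    total dose (reported as ``m_combo``/``dm_combo`` attrs), and evaluates the
    CI at each observed combination fa. Returns one row per combination point
    with columns ``d1, d2, fa, dx1, dx2, ci, classification``.
    """
    if combo.d1 is None or combo.d2 is None:
        d1 = combo.doses / (1.0 + ratio)
        d2 = combo.doses - d1
    else:
        d1, d2 = combo.d1, combo.d2
    if np.any(np.abs(d2 / d1 - ratio) > 1e-9 * ratio):
        raise InputError(f"combination doses do not respect the declared ratio {ratio}")
    fit1 = fit_median_effect(series1)
    fit2 = fit_median_effect(series2)
    fit_combo = fit_median_effect(combo)
    rows = []
    for dd1, dd2, fa in zip(d1, d2, combo.fa):
        dx1 = dose_for_effect(fit1, float(fa))
        dx2 = dose_for_effect(fit2, float(fa))
        ci = combination_index(fit1, fit2, float(dd1), float(dd2), float(fa))
        rows.append(
            {
                "d1": float(dd1),
                "d2": float(dd2),
                "fa": float(fa),
                "dx1": dx1,
                "dx2": dx2,
                "ci": ci,
                "classification": classify_ci(ci, tolerance=tolerance),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["m_combo"] = fit_combo.m
    out.attrs["dm_combo"] = fit_combo.dm
    out.attrs["fit1"] = fit1
    out.attrs["fit2"] = fit2
    return out


def load_published_ci_table() -> pd.DataFrame:
    """Published combination-index measurements for withaferin A combined with
    pemetrexed, cisplatin or gemcitabine in four NSCLC cell lines.

    Columns: cell_line, wa_um, partner_um, partner, ci_mean, ci_sd. These are
    reported experimental values shipped as package data for classification
    demonstrations; the package does not recompute them.
    """
    from importlib.resources import files

    path = files("repscreen.data").joinpath("wa_combination_ci.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)
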