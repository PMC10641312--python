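"""Dose-response fitting and Chou-Talalay combination-index analysis.

GI50 values come from least-squares fits of the log-concentration versus
normalized-response model with a standard Hill slope of -1:

    y(D) = 100 / (1 + D/GI50)

The median-effect model fa/fu = (D/Dm)^m (fu = 1 - fa) linearizes as
log(fa/fu) = m*log(D) - m*log(Dm) and is fitted by ordinary least squares
on the median-effect plot.  Combination indices at a given effect level fa
use Dx_i = Dm_i * [fa/(1-fa)]^(1/m_i) and, under the mutually nonexclusive
assumption, add the product term(s) to the exclusive sum:

    CI_2 = d1/Dx1 + d2/Dx2 + (d1*d2)/(Dx1*Dx2)

The 3-drug generalization (all singles, all pairwise products and the
triple product) follows the standard Chou construction.  The component
doses d_i at each fa derive from the combination's own median-effect fit at
the fixed mixing ratio (CompuSyn behavior), not from raw interpolation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


def response_to_fa(response) -> np.ndarray:
    """Convert percent-of-vehicle response to fraction affected fa = 1 - y/100."""
    return 1.0 - np.asarray(response, dtype=float) / 100.0


# --- GI50 -------------------------------------------------------------------

@dataclass
class GI50Fit:
    gi50: float
    ci95: tuple[float, float]
    rss: float
    flags: list[str] = field(default_factory=list)


def fit_gi50(doses, responses) -> GI50Fit:
    """Least-squares GI50 from a Hill-slope -1 normalized-response curve.

    Fits log10(GI50); the 95% CI comes from the fit covariance on the log
    scale (t distribution).  Fits landing far outside the tested dose range
    (beyond 100x either end) are flagged; a fit pinned at the upper search
    bound (no inhibition) returns an infinite GI50 sentinel.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(d).size < 4:
        raise ValueError("GI50 fit requires at least 4 dose levels")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    lo, hi = math.log10(d.min()) - 5, math.log10(d.max()) + 5

    def model(dose, log_g):
        return 100.0 / (1.0 + dose / 10.0**log_g)

    p0 = math.log10(np.sqrt(d.min() * d.max()))
    popt, pcov = optimize.curve_fit(
        model, d, y, p0=[p0], bounds=([lo], [hi]), maxfev=10000
    )
    log_g = float(popt[0])
    rss = float(np.sum((y - model(d, log_g)) ** 2))
    flags: list[str] = []
    gi50 = 10.0**log_g
    if gi50 > d.max() * 1e2:
        return GI50Fit(math.inf, (math.nan, math.nan), rss, ["no_inhibition"])
    if gi50 < d.min() * 1e-2:
        flags.append("extrapolated_low")
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    tcrit = stats.t.ppf(0.975, max(len(d) - 1, 1))
    ci = (10.0 ** (log_g - tcrit * se), 10.0 ** (log_g + tcrit * se))
    return GI50Fit(gi50, ci, rss, flags)


# --- median-effect model ----------------------------------------------------

@dataclass
class MedianEffectFit:
    dm: float   # median-effect dose (fa = 0.5)
    m: float    # sigmoidicity
    r: float    # correlation coefficient of the linearized fit
    n_points: int = 0

    def fa(self, dose) -> np.ndarray:
        """Fraction affected at a dose under the fitted model."""
        d = np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + (self.dm / d) ** self.m)

    def dose_at(self, fa: float) -> float:
        """Dose producing effect level fa: Dx = Dm * [fa/(1-fa)]^(1/m)."""
        if not 0 < fa < 1:
            raise ValueError("effect level fa must lie strictly inside (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def fit_median_effect(doses, fa, fa_bounds: tuple[float, float] = (0.01, 0.99)) -> MedianEffectFit:
    """OLS fit of the median-effect plot log(fa/fu) vs log(D).

    Points with fa outside ``fa_bounds`` (where the logit is numerically
    meaningless) are excluded with a warning.  Non-monotone data giving a
    slope m <= 0 raise.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive")
    keep = (f > fa_bounds[0]) & (f < fa_bounds[1])
    if keep.sum() < len(f):
        warnings.warn(
            f"excluding {int((~keep).sum())} point(s) with fa outside {fa_bounds}",
            stacklevel=2,
        )
    d, f = d[keep], f[keep]
    if len(d) < 3:
        raise ValueError("median-effect fit requires at least 3 usable doses")
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    m, b = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError(f"non-monotone dose-response (fitted slope m = {m:.3g} <= 0)")
    r = float(np.corrcoef(x, y)[0, 1])
    return MedianEffectFit(dm=float(10.0 ** (-b / m)), m=float(m), r=r, n_points=len(d))


# --- combination index ------------------------------------------------------

@dataclass(frozen=True)
class CombinationIndexResult:
    effect_level: float
    ci: float
    exclusive_sum: float          # sum of d_i/Dx_i without product terms
    component_doses: tuple[float, ...]
    assumption: str = "mutually_nonexclusive"
    band: str = ""


def combination_index(
    combo_fit: MedianEffectFit,
    single_fits: list[MedianEffectFit],
    ratio: list[float],
    effect_levels: list[float],
    thresholds: dict | None = None,
) -> list[CombinationIndexResult]:
    """Mutually nonexclusive Chou-Talalay CI at each requested effect level.

    ``ratio`` gives the fixed mixing proportions of the component drugs in
    the combination's total dose (any positive weights; normalized
    internally).  For each fa the combination's own median-effect fit sets
    the total dose, split into components by the ratio.
    """
    if len(single_fits) not in (2, 3):
        raise ValueError("combination index supports 2- or 3-drug combinations")
    if len(ratio) != len(single_fits):
        raise ValueError("ratio length must match the number of drugs")
    frac = np.asarray(ratio, dtype=float)
    if np.any(frac < 0) or frac.sum() <= 0:
        raise ValueError("mixing ratio must be nonnegative with positive sum")
    frac = frac / frac.sum()
    results = []
    for fa in effect_levels:
        total = combo_fit.dose_at(fa)           # validates fa in (0,1)
        d = frac * total
        dx = np.array([sf.dose_at(fa) for sf in single_fits])
        terms = d / dx
        ci = terms.sum()
        for size in range(2, len(terms) + 1):
            for idx in itertools.combinations(range(len(terms)), size):
                ci += np.prod(terms[list(idx)])
        results.append(
            CombinationIndexResult(
                effect_level=fa,
                ci=float(ci),
                exclusive_sum=float(terms.sum()),
                component_doses=tuple(float(v) for v in d),
                band=classify_synergy(float(ci), thresholds),
            )
        )
    return results


#: Coarse default bands; a finer (Chou-style) banding can be supplied as a
#: {label: (low, high)} config with inclusive-left intervals.
DEFAULT_SYNERGY_THRESHOLDS = {"additive_tolerance": 0.10}


def classify_synergy(ci: float, thresholds: dict | None = None) -> str:
    """Label a CI: < 1 synergism, ~1 additive, > 1 antagonism.

    Defaults use an additive band of width +/-0.1 around 1.  Passing a
    ``bands`` mapping {label: [low, high)} switches to fine-grained bands.
    """
    if ci <= 0 or not math.isfinite(ci):
        raise ValueError(f"CI must be finite and positive, got {ci}")
    th = thresholds or DEFAULT_SYNERGY_THRESHOLDS
    if "bands" in th:
        for label, (lo, hi) in th["bands"].items():
            if lo <= ci < hi:
                return label
        return "unclassified"
    tol = th.get("additive_tolerance", 0.10)
    if ci < 1.0 - tol:
        return "synergism"
    if ci > 1.0 + tol:
        return "antagonism"
    return "additive"


# --- series ingestion -------------------------------------------------------

def read_dose_response_tsv(path) -> pd.DataFrame:
    """Read a TSV with columns drug, dose, response[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    needed = {"drug", "dose", "response"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["dose"] <= 0).any():
        raise ValueError("doses must be strictly positive")
    return df


def median_effect_from_responses(df: pd.DataFrame) -> MedianEffectFit:
    """Fit the median-effect model from a (drug, dose, response) table,
    averaging replicates per dose and converting response to fa."""
    mean = df.groupby("dose", as_index=False)["response"].mean()
    return fit_median_effect(mean["dose"], response_to_fa(mean["response"]))
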