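"""Immunohistochemistry H-scores and KI67 positivity from per-cell DAB OD.

Inputs are per-cell measurement tables (QuPath-style exports) with the mean
DAB optical density per cell -- nuclear for KI67, cellular for p16.  p16
staining is banded on thresholds (0.2, 0.4, 0.6): negative below 0.2, then
weak / moderate / strong with inclusive-left boundaries.  The H-score is
the weighted sum of band percentages (1x weak + 2x moderate + 3x strong),
ranging 0-300.  KI67 positivity uses a single 0.2 nuclear OD threshold
(counted positive at exactly 0.2, consistent with the band convention).
Cells below the nucleus-area detection minimum (default 15 um^2 within the
usual 10-25 um^2 setting range) are excluded before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

P16_THRESHOLDS = (0.2, 0.4, 0.6)
KI67_THRESHOLD = 0.2
NUCLEUS_AREA_MIN_UM2 = 15.0

BANDS = ("negative", "weak", "moderate", "strong")


@dataclass
class HScoreResult:
    fractions: dict[str, float]   # per band, summing to 1
    h_score: float                # in [0, 300]
    n_cells: int = 0


def filter_cells(
    table: pd.DataFrame, min_nucleus_area: float = NUCLEUS_AREA_MIN_UM2
) -> pd.DataFrame:
    """Drop cells below the nucleus-area detection minimum (if area present)."""
    if "nucleus_area" not in table.columns:
        return table
    return table[table["nucleus_area"] >= min_nucleus_area]


def classify_p16_intensity(
    od: np.ndarray, thresholds: tuple[float, float, float] = P16_THRESHOLDS
) -> np.ndarray:
    """Band each cell's OD: negative < t0 <= weak < t1 <= moderate < t2 <= strong."""
    od = np.asarray(od, dtype=float)
    if np.any(od < 0) or not np.all(np.isfinite(od)):
        raise ValueError("optical densities must be finite and nonnegative")
    t0, t1, t2 = thresholds
    if not t0 < t1 < t2:
        raise ValueError("thresholds must be strictly increasing")
    idx = np.searchsorted(np.array([t0, t1, t2]), od, side="right")
    return np.array(BANDS)[idx]


def band_fractions(classes: np.ndarray) -> dict[str, float]:
    n = len(classes)
    if n == 0:
        raise ValueError("no cells to score")
    return {b: float(np.mean(classes == b)) for b in BANDS}


def h_score(fractions: dict[str, float]) -> float:
    """H = 100 * (1*weak + 2*moderate + 3*strong); bounded in [0, 300]."""
    total = sum(fractions.get(b, 0.0) for b in BANDS)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"band fractions sum to {total}, expected 1")
    return 100.0 * (
        fractions.get("weak", 0.0)
        + 2.0 * fractions.get("moderate", 0.0)
        + 3.0 * fractions.get("strong", 0.0)
    )


def p16_h_score(
    table: pd.DataFrame,
    thresholds: tuple[float, float, float] = P16_THRESHOLDS,
    min_nucleus_area: float = NUCLEUS_AREA_MIN_UM2,
) -> HScoreResult:
    """Full p16 scoring from a per-cell table with ``mean_dab_od``."""
    cells = filter_cells(table, min_nucleus_area)
    classes = classify_p16_intensity(cells["mean_dab_od"].to_numpy(), thresholds)
    fr = band_fractions(classes)
    return HScoreResult(fractions=fr, h_score=h_score(fr), n_cells=len(cells))


def ki67_positive_fraction(
    table: pd.DataFrame,
    threshold: float = KI67_THRESHOLD,
    min_nucleus_area: float = NUCLEUS_AREA_MIN_UM2,
) -> float:
    """Fraction of cells with nuclear mean DAB OD >= threshold."""
    cells = filter_cells(table, min_nucleus_area)
    od = cells["mean_dab_od"].to_numpy(dtype=float)
    if len(od) == 0:
        raise ValueError("no cells to score")
    if np.any(od < 0) or not np.all(np.isfinite(od)):
        raise ValueError("optical densities must be finite and nonnegative")
    return float(np.mean(od >= threshold))
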