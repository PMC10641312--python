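"""CDK4 modification profiles from 2D-gel spot densitometry.

CDK4 resolved by isoelectric focusing separates into up to four spots: the
native form (spot 1), a non-phospho modified form (spot 2), the activating
T172-phosphorylated form (spot 3) and a doubly modified form (spot 4).  The
spot3/spot2 volume ratio defines three modification profiles:

* ``A`` (absent phospho-CDK4): ratio < 0.02
* ``L`` (low):                 0.02 <= ratio < 0.50
* ``H`` (high):                ratio >= 0.50

Input volumes are densitometric spot volumes after linear background
correction of the immunoblot scan; a simple baseline-subtraction helper is
provided for convenience but correction is normally done upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ratio below which the phosphorylated form is called absent.
RATIO_ABSENT = 0.02
#: Ratio at or above which the phosphorylated form is called high.
RATIO_HIGH = 0.50


class SpotValidationError(ValueError):
    """Raised when spot volumes are negative or non-finite."""


@dataclass(frozen=True)
class SpotQuantification:
    """Background-corrected 2D-gel spot volumes for one sample.

    ``spot1`` (native CDK4) and ``spot4`` (doubly modified form) are
    optional and only enter the phospho-fraction computation; the profile
    call uses ``spot2`` (non-phospho modified form) and ``spot3``
    (T172-phosphorylated form) only.
    """

    sample_id: str
    spot2: float
    spot3: float
    spot1: float = 0.0
    spot4: float = 0.0

    def __post_init__(self) -> None:
        vols = (self.spot1, self.spot2, self.spot3, self.spot4)
        for v in vols:
            if not math.isfinite(v):
                raise SpotValidationError(
                    f"{self.sample_id}: non-finite spot volume {v!r}"
                )
            if v < 0:
                raise SpotValidationError(
                    f"{self.sample_id}: negative spot volume {v!r}"
                )
        if all(v == 0 for v in vols):
            raise SpotValidationError(f"{self.sample_id}: all spot volumes are zero")

    @property
    def total(self) -> float:
        return self.spot1 + self.spot2 + self.spot3 + self.spot4


@dataclass(frozen=True)
class CDK4Profile:
    """Profile call for one sample: label in {A, L, H} plus the ratio used."""

    sample_id: str
    label: str
    ratio: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def classify_ratio(ratio: float) -> str:
    """Map a spot3/spot2 ratio onto the A/L/H profile bands."""
    if ratio < RATIO_ABSENT:
        return "A"
    if ratio < RATIO_HIGH:
        return "L"
    return "H"


def classify_cdk4_profile(q: SpotQuantification) -> CDK4Profile:
    """Call the CDK4 modification profile from spot 2 and spot 3 volumes.

    Degenerate spot2 = 0 inputs never occur in practice but are handled so
    cohort runs stay robust: spot3 > 0 yields ratio +inf and label H,
    spot3 = 0 yields ratio 0 and label A; both carry a ``zero_spot2`` flag.
    """
    flags: list[str] = []
    if q.spot2 == 0:
        flags.append("zero_spot2")
        ratio = math.inf if q.spot3 > 0 else 0.0
    else:
        ratio = q.spot3 / q.spot2
    return CDK4Profile(q.sample_id, classify_ratio(ratio), ratio, tuple(flags))


def phospho_fraction(q: SpotQuantification) -> float:
    """Fraction of T172-phosphorylated CDK4 (spot 3) over all detected forms."""
    total = q.total
    if total <= 0:
        raise SpotValidationError(
            f"{q.sample_id}: total spot volume is zero, fraction undefined"
        )
    return q.spot3 / total


def subtract_linear_baseline(volumes: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Optional helper: subtract a linear baseline, clipping at zero."""
    out = np.asarray(volumes, dtype=float) - np.asarray(baseline, dtype=float)
    return np.clip(out, 0.0, None)


SATURATION_LIMIT_16BIT = 65535.0


def saturation_warnings(df: pd.DataFrame, limit: float = SATURATION_LIMIT_16BIT) -> list[str]:
    """Warning-only QC: flag samples whose raw volumes touch the scan ceiling."""
    spots = [c for c in ("spot1", "spot2", "spot3", "spot4") if c in df.columns]
    hit = df.loc[(df[spots] >= limit).any(axis=1), "sample_id"]
    return [f"{s}: saturated signal" for s in hit]


def read_spot_table(path) -> list[SpotQuantification]:
    """Read a TSV with columns sample_id, spot2, spot3 (spot1/spot4 optional)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "spot2", "spot3"}
    missing = required - set(df.columns)
    if missing:
        raise SpotValidationError(f"missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SpotQuantification(
                sample_id=str(row.sample_id),
                spot2=float(row.spot2),
                spot3=float(row.spot3),
                spot1=float(getattr(row, "spot1", 0.0) or 0.0),
                spot4=float(getattr(row, "spot4", 0.0) or 0.0),
            )
        )
    return out


def classify_spot_table(quants: list[SpotQuantification]) -> pd.DataFrame:
    """Classify a cohort and return a tidy table (one row per sample)."""
    rows = []
    for q in quants:
        p = classify_cdk4_profile(q)
        rows.append(
            {
                "sample_id": p.sample_id,
                "ratio": p.ratio,
                "profile": p.label,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "ratio", "profile", "flags"])
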