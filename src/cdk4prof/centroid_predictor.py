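"""Nearest-centroid prediction of the CDK4 modification profile.

A sample's CP20M expression over an 11-gene panel (which includes CDKN2A)
is compared by Spearman rank correlation to three reference centroids --
the mean expression of prototype tumors with A, H or L CDK4 profiles.  The
predicted profile is the centroid with the highest correlation; the binary
clinical read-out collapses H and L into "non-A" (drug-target present).

Because the raw CDKN2A locus signal conflates p16 and p14ARF transcription,
the CDKN2A feature can optionally be replaced by the p16-specific
exon-1alpha expression, after scaling the whole cohort by a single factor
chosen so that the mean exon-1alpha expression of known profile-A samples
equals the reference centroid's CDKN2A value.

References are data, never constants: they ship as JSON/TSV config with an
``is_cdkn2a`` flag marking the feature the exon-1alpha substitution targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("A", "H", "L")  # tie-break priority: a tie involving A surfaces as A


class PredictionError(ValueError):
    """Raised when a sample vector cannot be correlated with the centroids."""


@dataclass
class CentroidReference:
    """11-gene mean expression vectors for profiles A, H and L."""

    genes: list[str]
    centroid_A: np.ndarray
    centroid_H: np.ndarray
    centroid_L: np.ndarray
    cdkn2a_gene: str = "CDKN2A"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.centroid_A = np.asarray(self.centroid_A, dtype=float)
        self.centroid_H = np.asarray(self.centroid_H, dtype=float)
        self.centroid_L = np.asarray(self.centroid_L, dtype=float)
        n = len(self.genes)
        for c in (self.centroid_A, self.centroid_H, self.centroid_L):
            if c.shape != (n,):
                raise ValueError("centroid length does not match gene list")
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError("centroid values must be finite and nonnegative")
        if len(set(self.genes)) != n:
            raise ValueError("duplicate genes in reference")
        if self.cdkn2a_gene not in self.genes:
            raise ValueError(f"CDKN2A feature {self.cdkn2a_gene!r} not in gene list")

    def centroid(self, label: str) -> np.ndarray:
        return {"A": self.centroid_A, "H": self.centroid_H, "L": self.centroid_L}[label]

    @property
    def cdkn2a_index(self) -> int:
        return self.genes.index(self.cdkn2a_gene)

    @property
    def reference_A_cdkn2a(self) -> float:
        return float(self.centroid_A[self.cdkn2a_index])

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "centroid_A": self.centroid_A.tolist(),
            "centroid_H": self.centroid_H.tolist(),
            "centroid_L": self.centroid_L.tolist(),
            "cdkn2a_gene": self.cdkn2a_gene,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CentroidReference":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class ProfilePrediction:
    sample_id: str
    rho_A: float
    rho_H: float
    rho_L: float
    predicted_label: str
    binary_label: str  # "A" or "nonA"
    tie_flag: bool = False

    @property
    def correlations(self) -> dict[str, float]:
        return {"A": self.rho_A, "H": self.rho_H, "L": self.rho_L}


def scale_exon1a_to_reference(
    exon1a_values: pd.Series,
    known_a_sample_ids: list[str],
    reference_A_cdkn2a_value: float,
) -> tuple[float, pd.Series]:
    """Scale cohort exon-1alpha expression onto the reference scale.

    One common factor is applied to every sample, chosen so the mean
    exon-1alpha expression of the known profile-A samples equals the
    reference centroid's CDKN2A value.  Returns (factor, scaled values).
    """
    known = [s for s in known_a_sample_ids if s in exon1a_values.index]
    if not known:
        raise ValueError("no known profile-A samples available for scaling")
    mean_a = float(exon1a_values.loc[known].mean())
    if mean_a <= 0:
        raise ValueError("mean exon-1alpha expression of known-A samples is zero")
    factor = reference_A_cdkn2a_value / mean_a
    return factor, exon1a_values * factor


def predict_cdk4_profile(
    sample_id: str,
    values: np.ndarray,
    ref: CentroidReference,
) -> ProfilePrediction:
    """Spearman-correlate an 11-gene vector with each centroid and call A/H/L.

    Ties in the maximal correlation are resolved with priority A > H > L
    and flagged.  The binary label is "A" only when rho_A is strictly
    greatest, so a tie involving A surfaces as potentially resistant in the
    three-class call but the binary call stays consistent with the strict
    rule (a flagged tie at the top involving A is reported as A in both).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(ref.genes),):
        raise PredictionError(
            f"{sample_id}: expected {len(ref.genes)} values, got {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise PredictionError(f"{sample_id}: non-finite expression values")
    if np.all(values == values[0]):
        raise PredictionError(
            f"{sample_id}: constant expression vector, Spearman correlation undefined"
        )
    rho = {}
    for label in LABELS:
        r = stats.spearmanr(values, ref.centroid(label)).statistic
        if not np.isfinite(r):
            raise PredictionError(f"{sample_id}: undefined correlation with centroid {label}")
        rho[label] = float(r)
    best = max(rho.values())
    winners = [lab for lab in LABELS if rho[lab] == best]
    predicted = winners[0]  # LABELS order encodes the A > H > L priority
    binary = "A" if rho["A"] > max(rho["H"], rho["L"]) else "nonA"
    if predicted == "A" and len(winners) > 1:
        binary = "A"  # keep the flagged tie consistent across modes
    return ProfilePrediction(
        sample_id, rho["A"], rho["H"], rho["L"], predicted, binary,
        tie_flag=len(winners) > 1,
    )


def predict_cohort(
    expression: pd.DataFrame,
    ref: CentroidReference,
    exon1a: pd.Series | None = None,
    known_a_sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Predict every sample of a genes x samples CP20M matrix.

    With ``exon1a`` given (exon-1alpha expression per sample) the CDKN2A
    feature is replaced by the cohort-scaled exon-1alpha values
    (``known_a_sample_ids`` required); otherwise the raw locus value is
    used.  Returns a tidy table with correlations and both call modes.
    """
    missing = [g for g in ref.genes if g not in expression.index]
    if missing:
        raise PredictionError(f"genes missing from expression matrix: {missing}")
    feats = expression.loc[ref.genes].copy()
    mode = "raw_locus"
    if exon1a is not None:
        if known_a_sample_ids is None:
            raise PredictionError("known-A sample ids required for exon-1alpha scaling")
        _, scaled = scale_exon1a_to_reference(
            exon1a.reindex(feats.columns), known_a_sample_ids, ref.reference_A_cdkn2a
        )
        feats.loc[ref.cdkn2a_gene] = scaled
        mode = "exon1a_corrected"
    rows = []
    for sample in feats.columns:
        p = predict_cdk4_profile(sample, feats[sample].to_numpy(), ref)
        rows.append(
            {
                "sample_id": sample,
                "rho_A": p.rho_A,
                "rho_H": p.rho_H,
                "rho_L": p.rho_L,
                "predicted": p.predicted_label,
                "binary": p.binary_label,
                "tie_flag": p.tie_flag,
                "cdkn2a_mode": mode,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PredictionEvaluation:
    confusion: pd.DataFrame
    accuracy: float
    n: int = 0
    mode: str = "three_class"


def evaluate_predictions(
    truth: list[str], predicted: list[str], mode: str = "three_class"
) -> PredictionEvaluation:
    """Confusion matrix and accuracy; binary mode collapses H/L into nonA."""
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lists differ in length")
    if mode == "binary":
        collapse = lambda lab: "A" if lab == "A" else "nonA"  # noqa: E731
        truth = [collapse(t) for t in truth]
        predicted = [collapse(p) for p in predicted]
        order = ["A", "nonA"]
    elif mode == "three_class":
        order = list(LABELS)
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    t = pd.Categorical(truth, categories=order)
    p = pd.Categorical(predicted, categories=order)
    confusion = pd.crosstab(
        pd.Series(t, name="truth"), pd.Series(p, name="predicted"), dropna=False
    ).reindex(index=order, columns=order, fill_value=0)
    n = len(truth)
    accuracy = float(np.trace(confusion.to_numpy()) / n) if n else float("nan")
    return PredictionEvaluation(confusion, accuracy, n, mode)
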