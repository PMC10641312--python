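"""Seeded generators emulating the inputs each analysis stage consumes.

Every generator takes an integer seed, draws from an isolated
``numpy.random.Generator``, and returns the simulated data together with
the ground truth used to produce it, so recovery tests consume only the
data and compare against truth.  Identical seeds and parameters give
bit-identical output.

The expression-cohort generator builds a synthetic placeholder centroid
reference (the study's actual 11-gene breast-cohort reference is external
config): three centroids over an 11-gene panel whose value ladder and rank
structure mirror the described biology -- profile A tumors rank CDKN2A
(p16) at the top of a proliferative expression pattern, profile H shares
the proliferative pattern with low CDKN2A, and profile L is quiescent-like.
Optional "p14 confounder" samples reproduce the documented failure mode of
the raw-locus predictor: a high CDKN2A locus signal driven almost entirely
by exon 1beta (p14), with near-zero exon-1alpha fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centroid_predictor import CentroidReference
from .cdkn2a_exon_usage import CoverageTrack, LocusAnnotation, LocusInterval
from .copy_number import Segment, SegmentSet, ratio_from_copy

# --- 11-gene cohort ---------------------------------------------------------

PANEL_GENES = [
    "CDKN2A", "CCNE1", "E2F1", "MYBL2", "CCND1", "CDK6",
    "RB1", "PCNA", "FOXM1", "ESR1", "MKI67",
]

#: Rank (0 = lowest expression, 10 = highest) of each panel gene per class.
#: A and H share a proliferative pattern and differ mainly in CDKN2A; L is
#: quiescent-like (high RB1/ESR1, low E2F1/CCNE1).
_CLASS_RANKS = {
    "A": [10, 8, 9, 7, 3, 4, 0, 6, 5, 1, 2],
    "H": [2, 9, 10, 8, 4, 5, 0, 7, 6, 1, 3],
    "L": [1, 2, 0, 3, 8, 7, 10, 4, 5, 9, 6],
}

#: Geometric expression ladder (CP20M-scale); adjacent rank gap 1.6x keeps
#: rank flips rare under the default lognormal noise.
_LADDER_BASE = 10.0
_LADDER_STEP = 1.6


def _ladder(rank) -> np.ndarray:
    return _LADDER_BASE * _LADDER_STEP ** np.asarray(rank, dtype=float)


def make_placeholder_reference() -> CentroidReference:
    """Synthetic placeholder centroid reference over the 11-gene panel."""
    return CentroidReference(
        genes=list(PANEL_GENES),
        centroid_A=_ladder(_CLASS_RANKS["A"]),
        centroid_H=_ladder(_CLASS_RANKS["H"]),
        centroid_L=_ladder(_CLASS_RANKS["L"]),
        cdkn2a_gene="CDKN2A",
        provenance="synthetic placeholder reference (generated, not derived from tumors)",
    )


@dataclass
class ExpressionCohort:
    expression: pd.DataFrame          # genes x samples, raw-locus CDKN2A
    labels: pd.Series                 # true A/H/L per sample
    exon1a: pd.Series                 # exon-1alpha expression per sample
    exon1a_fraction: pd.Series        # true exon-1alpha fraction per sample
    reference: CentroidReference
    confounder_ids: list[str] = field(default_factory=list)

    @property
    def known_a_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == "A"])


def simulate_expression_cohort(
    seed: int,
    n_samples: int = 500,
    class_proportions: dict[str, float] | None = None,
    sigma_log: float = 0.1,
    n_confounders: int = 0,
) -> ExpressionCohort:
    """Cohort of 11-gene CP20M vectors with known A/H/L class structure.

    Samples are drawn per class as centroid * exp(N(0, sigma_log)) per
    gene (lognormal noise keeps values nonnegative and ranks meaningful).
    Confounder samples are true-H tumors whose CDKN2A locus signal is
    p14-driven: raw locus expression above even the A centroid, exon-1alpha
    fraction near zero.  Class proportions default to A/L/H =
    0.10/0.50/0.40, approximating the A prevalence seen in tumor cohorts.
    """
    rng = np.random.default_rng(seed)
    props = class_proportions or {"A": 0.10, "L": 0.50, "H": 0.40}
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    ref = make_placeholder_reference()
    labels = rng.choice(list(props), size=n_samples, p=list(props.values()))
    # guarantee at least one profile-A prototype for exon-1alpha scaling
    if n_samples and not (labels == "A").any():
        labels[0] = "A"
    sample_ids = [f"S{i:04d}" for i in range(n_samples + n_confounders)]
    values = np.empty((len(PANEL_GENES), n_samples + n_confounders))
    fractions = np.empty(n_samples + n_confounders)
    all_labels = list(labels) + ["H"] * n_confounders
    p14_locus = _ladder(11)  # p14-driven locus signal above the A centroid's CDKN2A
    for j, lab in enumerate(all_labels):
        base = ref.centroid(lab).copy()
        confounder = j >= n_samples
        if confounder:
            base[ref.cdkn2a_index] = p14_locus
        values[:, j] = base * np.exp(rng.normal(0.0, sigma_log, len(base)))
        if confounder:
            fractions[j] = rng.uniform(0.0, 0.05)
        elif lab == "A":
            fractions[j] = rng.uniform(0.85, 0.95)
        else:
            fractions[j] = rng.uniform(0.3, 0.7)
    expression = pd.DataFrame(values, index=PANEL_GENES, columns=sample_ids)
    labels_s = pd.Series(all_labels, index=sample_ids, name="label")
    frac_s = pd.Series(fractions, index=sample_ids, name="exon1a_fraction")
    exon1a = (expression.loc["CDKN2A"] * frac_s).rename("exon1a_cp20m")
    return ExpressionCohort(
        expression=expression,
        labels=labels_s,
        exon1a=exon1a,
        exon1a_fraction=frac_s,
        reference=ref,
        confounder_ids=sample_ids[n_samples:],
    )


# --- CDKN2A locus coverage --------------------------------------------------

#: Compact synthetic locus mirroring the real exon1beta - exon1alpha -
#: shared-exon order with intron gaps.
DEFAULT_LOCUS_INTERVALS = [
    (0, 400, "intron"),
    (400, 600, "exon1b"),
    (600, 1200, "intron"),
    (1200, 1400, "exon1a"),
    (1400, 2200, "intron"),
    (2200, 2400, "shared_exon"),
    (2400, 3000, "intron"),
]


@dataclass
class CoverageSimulation:
    track: CoverageTrack
    annotation: LocusAnnotation
    true_fraction: float | None
    h1a: float
    h1b: float


def simulate_cdkn2a_coverage(
    seed: int,
    h1a: float = 60.0,
    h1b: float = 40.0,
    slope: float = 0.005,
    intercept: float = 10.0,
    poisson: bool = True,
) -> CoverageSimulation:
    """Locus coverage = linear background + rectangular exon pulses.

    Exon 1alpha carries height ``h1a``, exon 1beta ``h1b`` and the shared
    exon ``h1a + h1b`` (both transcripts traverse it).  With ``poisson``
    the per-base depth is Poisson-sampled around its expectation.  Truth is
    h1a / (h1a + h1b), or None when both are zero.
    """
    rng = np.random.default_rng(seed)
    ann = LocusAnnotation([LocusInterval(*iv) for iv in DEFAULT_LOCUS_INTERVALS])
    positions = np.arange(DEFAULT_LOCUS_INTERVALS[-1][1], dtype=np.int64)
    expected = intercept + slope * positions.astype(float)
    expected[ann.mask(positions, "exon1a")] += h1a
    expected[ann.mask(positions, "exon1b")] += h1b
    expected[ann.mask(positions, "shared_exon")] += h1a + h1b
    depth = rng.poisson(expected).astype(float) if poisson else expected
    truth = h1a / (h1a + h1b) if (h1a + h1b) > 0 else None
    return CoverageSimulation(
        CoverageTrack(positions, depth), ann, truth, h1a, h1b
    )


# --- copy-number profiles ---------------------------------------------------

@dataclass
class CopyNumberSimulation:
    segments: SegmentSet
    rho: float
    psi: float
    copies: np.ndarray


def simulate_cn_profile(
    seed: int,
    rho: float = 0.6,
    n_segments: int = 25,
    copy_range: tuple[int, int] = (0, 6),
    bins_per_segment: tuple[int, int] = (500, 8000),
    noise_sd: float = 0.05,
    grid_align: bool = True,
) -> CopyNumberSimulation:
    """Segmented ratio profile generated from known purity/ploidy and copies.

    Integer copies are drawn per segment; the average ploidy is set
    consistent with the bin-weighted mean copy number,
    psi = rho * mean_w(copies) + 2 * (1 - rho) (``grid_align`` snaps psi to
    the 0.01 search grid).  Gaussian log-ratio noise of per-bin standard
    deviation ``noise_sd`` enters each segment mean scaled by
    1/sqrt(n_bins), matching what bin-level noise averages down to.  The
    default bin counts reflect genome-wide 30 kb binning, where a typical
    segment spans thousands of bins.
    """
    rng = np.random.default_rng(seed)
    copies = rng.integers(copy_range[0], copy_range[1] + 1, n_segments)
    if np.all(copies == copies[0]):  # keep the profile identifiable
        copies[0] = copies[0] + 1 if copies[0] < copy_range[1] else copies[0] - 1
    nbins = rng.integers(bins_per_segment[0], bins_per_segment[1] + 1, n_segments)
    cbar = float(np.average(copies, weights=nbins))
    psi = rho * cbar + 2.0 * (1.0 - rho)
    if grid_align:
        psi = round(psi, 2)
    r = ratio_from_copy(copies, rho, psi)
    log_r = np.log(np.maximum(r, 1e-12))
    if noise_sd > 0:
        log_r = log_r + rng.normal(0.0, noise_sd / np.sqrt(nbins))
    start = np.concatenate([[0], np.cumsum(nbins)[:-1]])
    segments = [
        Segment(int(s), int(s + n), int(n), float(lr))
        for s, n, lr in zip(start, nbins, log_r)
    ]
    return CopyNumberSimulation(SegmentSet(segments), rho, psi, copies)


# --- dose-response ----------------------------------------------------------

@dataclass
class DoseResponseSimulation:
    data: pd.DataFrame            # drug, dose, response, replicate
    dm: float
    m: float


def _dose_grid(dm: float, n_doses: int, dilution: float) -> np.ndarray:
    exponents = np.arange(n_doses) - (n_doses - 1) / 2.0
    return dm * dilution**exponents


def simulate_dose_response(
    seed: int,
    drug: str = "drug",
    dm: float = 0.1,
    m: float = 1.0,
    n_doses: int = 8,
    dilution: float = 2.0,
    replicates: int = 3,
    noise_sd: float = 5.0,
) -> DoseResponseSimulation:
    """Median-effect series: fa(D) = 1/(1 + (Dm/D)^m), response = 100(1-fa)
    plus Gaussian noise in response units, over a serial dilution around Dm."""
    rng = np.random.default_rng(seed)
    doses = _dose_grid(dm, n_doses, dilution)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    rows = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, n_doses) if noise_sd > 0 else 0.0
        resp = 100.0 * (1.0 - fa) + noise
        for d, y in zip(doses, np.atleast_1d(resp)):
            rows.append({"drug": drug, "dose": d, "response": y, "replicate": rep})
    return DoseResponseSimulation(pd.DataFrame(rows), dm, m)


@dataclass
class CombinationSimulation:
    singles: dict[str, DoseResponseSimulation]
    combination: DoseResponseSimulation   # doses are total mixture doses
    ratio: tuple[float, ...]
    synergy_factor: float


def simulate_combination(
    seed: int,
    dms: tuple[float, ...] = (0.1, 0.2),
    m: float = 1.0,
    ratio: tuple[float, ...] | None = None,
    synergy_factor: float = 1.0,
    n_doses: int = 8,
    dilution: float = 2.0,
    replicates: int = 3,
    noise_sd: float = 5.0,
) -> CombinationSimulation:
    """Fixed-ratio combination under the median-effect model.

    With a shared slope m, the Loewe-additive mixture is itself
    median-effect with Dm_mix = 1 / sum(f_i / Dm_i); ``synergy_factor`` > 1
    divides that Dm (potency-shift synergy), < 1 produces antagonism.
    """
    rng = np.random.default_rng(seed)
    frac = np.asarray(ratio if ratio is not None else [1.0] * len(dms), dtype=float)
    frac = frac / frac.sum()
    singles = {}
    for i, dm in enumerate(dms):
        singles[f"drug{i + 1}"] = simulate_dose_response(
            int(rng.integers(2**31)), f"drug{i + 1}", dm, m,
            n_doses, dilution, replicates, noise_sd,
        )
    dm_mix = 1.0 / float(np.sum(frac / np.asarray(dms))) / synergy_factor
    combo = simulate_dose_response(
        int(rng.integers(2**31)), "+".join(singles), dm_mix, m,
        n_doses, dilution, replicates, noise_sd,
    )
    return CombinationSimulation(singles, combo, tuple(frac), synergy_factor)


# --- IHC cells and 2D-gel spots ---------------------------------------------

_BAND_RANGES = {
    "negative": (0.0, 0.2),
    "weak": (0.2, 0.4),
    "moderate": (0.4, 0.6),
    "strong": (0.6, 1.2),
}


def simulate_cells(
    seed: int,
    n_cells: int = 1000,
    fractions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell OD table with known intensity-band composition."""
    rng = np.random.default_rng(seed)
    fr = fractions or {"negative": 0.25, "weak": 0.25, "moderate": 0.25, "strong": 0.25}
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("band fractions must sum to 1")
    bands = rng.choice(list(fr), size=n_cells, p=list(fr.values()))
    od = np.array([rng.uniform(*_BAND_RANGES[b]) for b in bands])
    table = pd.DataFrame(
        {
            "cell_id": [f"C{i}" for i in range(n_cells)],
            "mean_dab_od": od,
            "nucleus_area": rng.uniform(20.0, 60.0, n_cells),
        }
    )
    truth = {b: float(np.mean(bands == b)) for b in _BAND_RANGES}
    return table, truth


_RATIO_RANGES = {"A": (0.0, 0.019), "L": (0.02, 0.49), "H": (0.50, 2.0)}


def simulate_spots(
    seed: int,
    n_samples: int = 30,
    class_proportions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """2D-gel spot volume table with known A/L/H profile per sample."""
    rng = np.random.default_rng(seed)
    props = class_proportions or {"A": 0.2, "L": 0.4, "H": 0.4}
    labels = rng.choice(list(props), size=n_samples, p=list(props.values()))
    rows = []
    for i, lab in enumerate(labels):
        ratio = rng.uniform(*_RATIO_RANGES[lab])
        spot2 = rng.uniform(50.0, 200.0)
        rows.append(
            {
                "sample_id": f"G{i:03d}",
                "spot1": rng.uniform(20.0, 100.0),
                "spot2": spot2,
                "spot3": ratio * spot2,
                "spot4": rng.uniform(0.0, 30.0),
            }
        )
    table = pd.DataFrame(rows)
    truth = pd.Series(labels, index=table["sample_id"], name="label")
    return table, truth
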