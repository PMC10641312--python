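"""Tumor purity/ploidy and integer copy number from off-target read depth.

Targeted-panel sequencing leaves a thin but genome-wide carpet of off-target
reads.  The workflow here:

1. remove target regions (padded +/-1000 bp) and bin the rest of the genome
   in 30 kb bins, counting reads with MAPQ strictly greater than 30;
2. divide each bin by a diploid normal reference profiled with the same
   panel, then by the mean, giving a mean-one ratio track r;
3. segment log(r) (pluggable segmentation; default is a recursive binary
   segmentation with a seeded permutation test);
4. grid-search purity rho in [0.2, 1] and average ploidy psi in [1.5, 5]
   (step 0.01): each segment's real-valued copy number is
   n_T = (psi*r - 2(1-rho))/rho, and the objective is the (bin-weighted)
   sum of distances between n_T and the nearest integers.  The grid
   minimum gives the fit; ties prefer the most parsimonious genome
   (lowest psi, then highest rho) and are flagged ambiguous.

Allele-specific copy number (BAF modeling) and GC correction are out of
scope; the model works on total depth only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAPQ_MIN_DEFAULT = 30
BIN_SIZE_DEFAULT = 30_000
PADDING_DEFAULT = 1_000


# --- model algebra ----------------------------------------------------------

def ratio_from_copy(n_t, rho: float, psi: float):
    """Forward model: r = (n_T*rho + 2*(1-rho)) / psi."""
    return (np.asarray(n_t, dtype=float) * rho + 2.0 * (1.0 - rho)) / psi


def copy_from_ratio(r, rho: float, psi: float):
    """Inverse model: n_T = (psi*r - 2*(1-rho)) / rho."""
    return (psi * np.asarray(r, dtype=float) - 2.0 * (1.0 - rho)) / rho


# --- binning ----------------------------------------------------------------

@dataclass
class BinnedCounts:
    """Off-target bin counts for one sample (and optionally its reference)."""

    bins: pd.DataFrame  # columns: chrom, start, end
    counts: np.ndarray
    reference_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bins):
            raise ValueError("counts and bins differ in length")
        if self.reference_counts is not None:
            self.reference_counts = np.asarray(self.reference_counts)
            if len(self.reference_counts) != len(self.bins):
                raise ValueError("reference counts and bins differ in length")


def make_offtarget_bins(
    chrom_lengths: dict[str, int],
    targets: pd.DataFrame | None = None,
    bin_size: int = BIN_SIZE_DEFAULT,
    padding: int = PADDING_DEFAULT,
) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins, dropping any bin that
    overlaps a padded target interval."""
    rows = []
    for chrom, length in chrom_lengths.items():
        tgt = None
        if targets is not None:
            sub = targets[targets["chrom"] == chrom]
            if len(sub):
                tgt = np.stack(
                    [sub["start"].to_numpy() - padding, sub["end"].to_numpy() + padding],
                    axis=1,
                )
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            if tgt is not None and np.any((tgt[:, 0] < end) & (tgt[:, 1] > start)):
                continue
            rows.append((chrom, start, end))
    if not rows:
        raise ValueError("no off-target space left after removing padded targets")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_offtarget_counts(
    reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    targets: pd.DataFrame | None = None,
    bin_size: int = BIN_SIZE_DEFAULT,
    padding: int = PADDING_DEFAULT,
    mapq_min: int = MAPQ_MIN_DEFAULT,
) -> BinnedCounts:
    """Count reads (MAPQ strictly > ``mapq_min``) whose start falls in each
    off-target bin.  ``reads`` needs columns chrom, pos, mapq."""
    bins = make_offtarget_bins(chrom_lengths, targets, bin_size, padding)
    passing = reads[reads["mapq"] > mapq_min]
    counts = np.zeros(len(bins), dtype=np.int64)
    key = {
        (row.chrom, row.start): i for i, row in enumerate(bins.itertuples(index=False))
    }
    for chrom, pos in zip(passing["chrom"].to_numpy(), passing["pos"].to_numpy()):
        idx = key.get((chrom, int(pos // bin_size) * bin_size))
        if idx is not None:
            counts[idx] += 1
    return BinnedCounts(bins=bins, counts=counts)


# --- ratio track ------------------------------------------------------------

@dataclass
class RatioTrack:
    bins: pd.DataFrame
    r: np.ndarray          # mean-one ratio on unmasked bins (NaN where masked)
    mask: np.ndarray       # True where the bin is usable

    @property
    def log_r(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.mask & (self.r > 0), np.log(self.r), np.nan)


def compute_ratio(sample: BinnedCounts) -> RatioTrack:
    """Reference-normalized, mean-one depth ratio per bin.

    Bins with zero reference count are masked.  The sample count is first
    divided by the diploid reference count, then the track is divided by
    its mean so that mean(r) = 1 over unmasked bins.
    """
    if sample.reference_counts is None:
        raise ValueError("reference counts required to compute the ratio track")
    ref = sample.reference_counts.astype(float)
    mask = ref > 0
    norm = np.full(len(ref), np.nan)
    norm[mask] = sample.counts[mask] / ref[mask]
    mean = norm[mask].mean()
    if not mean > 0:
        raise ValueError("all-zero sample counts on unmasked bins")
    r = norm / mean
    return RatioTrack(bins=sample.bins, r=r, mask=mask)


# --- segmentation -----------------------------------------------------------

@dataclass
class Segment:
    start_bin: int   # index into the unmasked-bin array, inclusive
    end_bin: int     # exclusive
    n_bins: int
    mean_log_r: float

    @property
    def r(self) -> float:
        return float(np.exp(self.mean_log_r))


@dataclass
class SegmentSet:
    segments: list[Segment]

    @property
    def r_values(self) -> np.ndarray:
        return np.array([s.r for s in self.segments])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.n_bins for s in self.segments], dtype=float)


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single changepoint by the two-sample mean-shift t statistic."""
    n = len(x)
    cs = np.cumsum(x)
    i = np.arange(1, n)
    mean_l = cs[:-1] / i
    mean_r = (cs[-1] - cs[:-1]) / (n - i)
    stat = np.abs(mean_l - mean_r) * np.sqrt(i * (n - i) / n)
    k = int(np.argmax(stat))
    return k + 1, float(stat[k])


def segment_log_ratio(
    track: RatioTrack,
    alpha: float = 0.01,
    n_permutations: int = 199,
    min_bins: int = 2,
    seed: int = 0,
) -> SegmentSet:
    """Segment log(r) by recursive binary segmentation with permutation test.

    Each candidate split must beat the permutation null of its segment at
    level ``alpha`` (seeded, hence deterministic).  The stage is pluggable:
    any function returning a :class:`SegmentSet` over the unmasked bins can
    replace it in the pipeline.
    """
    logr = track.log_r
    usable = np.isfinite(logr)
    x = logr[usable]
    if len(x) < 2:
        raise ValueError("need at least 2 usable bins to segment")
    rng = np.random.default_rng(seed)
    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_bins or np.allclose(seg, seg[0]):
            boundaries.append((lo, hi))
            return
        split, stat = _best_split(seg)
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            null[p] = _best_split(rng.permutation(seg))[1]
        pval = (1.0 + np.sum(null >= stat)) / (n_permutations + 1.0)
        if pval > alpha or split < min_bins or n - split < min_bins:
            boundaries.append((lo, hi))
            return
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, len(x))
    boundaries.sort()
    segments = [
        Segment(lo, hi, hi - lo, float(x[lo:hi].mean())) for lo, hi in boundaries
    ]
    return SegmentSet(segments)


# --- purity/ploidy grid search ---------------------------------------------

@dataclass
class PurityPloidyFit:
    rho: float
    psi: float
    distance: float
    n_t: np.ndarray               # per-segment real-valued copy number
    copy_number: np.ndarray       # rounded, clamped at 0
    flags: list[str] = field(default_factory=list)


def grid_fit_purity_ploidy(
    segs: SegmentSet,
    rho_range: tuple[float, float] = (0.2, 1.0),
    psi_range: tuple[float, float] = (1.5, 5.0),
    step: float = 0.01,
    weighted: bool = True,
    ambiguity_rel_tol: float = 0.10,
    ambiguity_dpsi: float = 0.25,
    ambiguity_drho: float = 0.05,
) -> PurityPloidyFit:
    """Exhaustive (rho, psi) grid search minimizing the integer-copy misfit.

    objective(rho, psi) = sum_seg w_seg * |n_T - round(n_T)| with
    n_T = (psi*r - 2(1-rho))/rho; w_seg is the segment's bin count
    (``weighted=False`` gives the literal unweighted sum).  Negative n_T
    are clamped to 0 before rounding and flagged.  Exact ties prefer the
    lowest psi, then the highest rho, and set an ``ambiguous`` flag; a
    distant grid point (|dpsi| > 0.25 or |drho| > 0.05) whose objective is
    within ``ambiguity_rel_tol`` (fraction) of the minimum also flags the
    fit, catching whole-genome-duplication-like degeneracies where a
    shifted copy assignment explains the data essentially as well.
    """
    if not segs.segments:
        raise ValueError("empty segment set")
    r = segs.r_values
    w = segs.weights if weighted else np.ones(len(segs.segments))
    n_rho = int(round((rho_range[1] - rho_range[0]) / step)) + 1
    n_psi = int(round((psi_range[1] - psi_range[0]) / step)) + 1
    # psi ascending, rho descending: the first flat minimum then realizes the
    # lowest-psi / highest-rho tie-break.
    psis = np.round(psi_range[0] + step * np.arange(n_psi), 10)
    rhos = np.round(rho_range[1] - step * np.arange(n_rho), 10)
    P = psis[:, None, None]                  # (n_psi, 1, 1)
    R = rhos[None, :, None]                  # (1, n_rho, 1)
    n_t = (P * r[None, None, :] - 2.0 * (1.0 - R)) / R
    obj = (np.abs(n_t - np.round(n_t)) * w[None, None, :]).sum(axis=2)
    flat = int(np.argmin(obj))
    i_psi, i_rho = np.unravel_index(flat, obj.shape)
    best_obj = float(obj[i_psi, i_rho])
    rho, psi = float(rhos[i_rho]), float(psis[i_psi])
    flags: list[str] = []
    ties = np.argwhere(obj <= best_obj + 1e-9)
    if len(ties) > 1:
        flags.append("ambiguous")
    # distant near-optima: objective within a fraction of the minimum
    norm = obj / w.sum()
    tol = max(ambiguity_rel_tol * norm[i_psi, i_rho], 1e-9)
    near = np.argwhere(norm <= norm[i_psi, i_rho] + tol)
    for ip, ir in near:
        if abs(psis[ip] - psi) > ambiguity_dpsi or abs(rhos[ir] - rho) > ambiguity_drho:
            if "ambiguous" not in flags:
                flags.append("ambiguous")
            break
    nt_best = copy_from_ratio(r, rho, psi)
    if np.any(nt_best < 0):
        flags.append("negative_copy_clamped")
    clamped = np.clip(nt_best, 0.0, None)
    return PurityPloidyFit(
        rho=rho,
        psi=psi,
        distance=best_obj,
        n_t=nt_best,
        copy_number=np.round(clamped).astype(int),
        flags=flags,
    )


def fit_summary(fit: PurityPloidyFit, segs: SegmentSet) -> pd.DataFrame:
    """SEG-like per-segment table for the fitted solution."""
    return pd.DataFrame(
        {
            "start_bin": [s.start_bin for s in segs.segments],
            "end_bin": [s.end_bin for s in segs.segments],
            "n_bins": [s.n_bins for s in segs.segments],
            "log_r": [s.mean_log_r for s in segs.segments],
            "n_t": fit.n_t,
            "copy_number": fit.copy_number,
        }
    )
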