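# Methods

This note records the models the toolkit implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer should know about.  It states no
empirical result the tests or `scripts/acceptance.py` do not themselves
compute.

## CDK4 modification profiles from 2D-gel densitometry

CDK4 separates by charge into up to four spots; the T172-phosphorylated
form (spot 3) relative to the non-phospho modified form (spot 2) defines
the profile: **A** (absent) for spot3/spot2 < 0.02, **L** for
0.02 ≤ ratio < 0.50, **H** for ratio ≥ 0.50.  Both band boundaries are
inclusive on the left, matching the defining convention ("equal or above"
for H).  Inputs are assumed background-corrected; a linear baseline
subtraction helper exists but is optional.  Degenerate spot2 = 0 records
(never observed in practice) do not abort a cohort run: spot3 > 0 maps to
ratio +∞ / label H, spot3 = 0 to ratio 0 / label A, both flagged
`zero_spot2`.  Saturation of 16-bit scans is checked warning-only, since
no quantitative rule exists for it.

## Expression normalization and signature scores

CP20M = counts × 2·10⁷ / library size.  Gene z-scores are computed across
samples with the **sample** standard deviation (ddof = 1, configurable);
the choice is conventional and cancels in any score comparison within a
cohort.  Zero-variance genes are dropped with a warning rather than set to
z = 0, so NaNs cannot propagate into scores.  TDS is the mean z-score of a
16-gene thyroid-identity panel; the EMT score subtracts the mean z of 4
epithelial markers from the mean z of 13 mesenchymal markers.  The shipped
gene lists are *reconstructed* defaults in `data/gene_sets.yaml` (the
signatures' defining publications are the authority; OCLN is included
among the epithelial markers) and are plain editable config.

Sample QC: proteomic stage excludes RIN < 3; transcriptomic stage excludes
RIN < 4.5 or PCR-duplicate fraction > 0.5% of the library.  Exclusions
carry their triggering rule(s).  The filter reproduces rules, not any
particular cohort tally.

## CDKN2A exon-1α quantification

Model: observed per-base depth over the locus = transcript signal on exons
+ a slowly varying non-specific background.  The background is an OLS line
of depth on genomic coordinate fitted over **all** intron-labeled
positions (whether only exon-flanking introns should be used is
unspecified; using all positions maximizes the regression's support).
Exon depth is background-subtracted and clipped at 0.  Each first exon's
peak height is then summarized and

    fraction = peak(exon 1α) / (peak(exon 1α) + peak(exon 1β))
    exon-1α expression = fraction × CDKN2A gene CP20M.

**Peak statistic.**  The peak is the maximum of a 31-bp centered rolling
mean of the corrected depth, computed within the exon (edge-truncated).
A literal per-base maximum is an extreme-value statistic: on noisy tracks
it is biased upward by ~3σ of the per-base noise and its fluctuation
scales with depth, which at realistic coverage (tens to low hundreds)
costs several percent of fraction accuracy.  The light smoothing leaves
noiseless rectangular pulses exact (a constant is its own rolling mean)
while averaging the per-base noise; 31 bp ≈ half a short read, well below
the exon widths.  The literal `max` and a whole-exon `mean` remain
selectable (`stat=` / `--stat`) for sensitivity analysis.

A silent locus (both peaks zero) yields an undefined fraction, flagged;
downstream the exon-1α expression is set to 0 so the predictor sees "no
p16 transcription" instead of NaN.  Intervals are BED-style 0-based
half-open; the shipped GRCh38 CDKN2A annotation is a default, overridable
by any BED4 with roles in the name field.  Whether peaks are compared
before or after CP20M scaling is immaterial — the scale cancels in the
ratio.

## 11-gene centroid prediction

A sample's 11-gene CP20M vector is Spearman-correlated (average ranks on
ties) with the A, H and L reference centroids; the highest correlation
wins.  Rank correlation makes the call invariant to any strictly monotone
transform of the sample vector, hence to normalization scale.  Reference
centroids are data (JSON/TSV with an `is_cdkn2a` flag), never constants;
the synthetic placeholder reference is clearly labelled as such.

Exon-1α correction: the CDKN2A feature is replaced by the exon-1α
expression after scaling the **whole cohort** by one factor chosen so the
mean exon-1α expression of known profile-A samples equals the reference's
CDKN2A value.  The factor is stored with the result for prospective reuse;
with no known-A samples the caller must fall back to raw-locus mode.

Tie handling: exact ties in the maximal correlation resolve with priority
A > H > L and set `tie_flag` — in the clinical use a tie involving A must
surface as potentially resistant.  For consistency, a flagged top tie
involving A is reported as A in both the three-class and the binary mode;
with 11-point rank correlations exact ties are a measure-zero curiosity
outside constructed fixtures.  Binary mode otherwise calls A only when
ρ_A is strictly greatest.  A constant sample vector has no ranks and
raises a prediction error rather than returning an arbitrary label.

## Purity/ploidy from off-target depth

Off-target reads of a targeted panel are counted in 30 kb bins (targets
padded ±1000 bp removed; MAPQ strictly > 30), divided by a diploid normal
profiled with the same panel, then by the track mean, so mean(r) = 1.  The
log track is segmented; per segment, under purity ρ and average ploidy ψ,

    r = (n_T·ρ + 2(1−ρ)) / ψ      ⇔      n_T = (ψ·r − 2(1−ρ)) / ρ.

The grid search covers ψ ∈ [1.5, 5], ρ ∈ [0.2, 1] in 0.01 steps and
minimizes Σ_seg w_seg · |n_T − round(n_T)|, with w_seg = segment bin count
by default (an unweighted mode implements the literal reading; unweighted
fits are dominated by tiny segments).  Negative n_T (possible at low ρ)
are clamped to 0 and flagged.  Exact ties prefer the lowest ψ, then the
highest ρ — the most parsimonious genome — and are flagged `ambiguous`.
A distant grid point (|Δψ| > 0.25 or |Δρ| > 0.05) whose objective comes
within 10% of the minimum also flags the fit: this is the
whole-genome-duplication-type degeneracy, where a shifted integer
assignment explains the data essentially as well, and no total-depth
method can resolve it without allele-specific information.

Segmentation is a recursive binary segmentation on log r: the best
mean-shift split per segment is kept if it beats a seeded permutation null
(199 permutations, α = 0.01 — the smallest attainable p, 0.005, clears
the level).  The stage is pluggable so a full circular-binary-segmentation
port can be swapped in; for piecewise-constant tracks with well-separated
levels the two agree.  Not modeled: allele fractions (BAF), GC and
mappability correction.

## Dose-response and drug combinations

GI50: least squares on y(D) = 100 / (1 + D/GI50) — the log-concentration
vs normalized-response model with standard Hill slope −1 — fitted on
log10(GI50) for stability, with a t-based 95% CI from the fit covariance.
Fits beyond 100× either end of the tested dose range are flagged; a fit
pinned at the upper search bound (no inhibition) returns an infinite GI50
sentinel.  Note on precision: with 8 two-fold dilutions, triplicates and
response noise σ = 5, the information content of one curve bounds the
GI50 sampling error at ≈ 6% (1 σ) — per-curve recovery claims below that
are not achievable by any unbiased estimator, so recovery is assessed on
the median error across many simulated curves.

Median-effect model: fa/fu = (D/Dm)^m, fitted by OLS on the linearized
plot (log10 D, log10 fa/fu); points with fa outside (0.01, 0.99) are
excluded with a warning (their logit is numerically meaningless);
m ≤ 0 (non-monotone data) raises.  fa(Dm) = 0.5 holds identically.

Combination index, mutually nonexclusive, fixed ratio: at each requested
fa, Dx_i = Dm_i·[fa/(1−fa)]^{1/m_i}; the combination's total dose comes
from the combination's **own** median-effect fit (CompuSyn behavior, not
raw interpolation) and is split by the mixing ratio into d_i.  Two drugs:
CI = d₁/Dx₁ + d₂/Dx₂ + d₁d₂/(Dx₁Dx₂).  Three drugs: all singles, all
pairwise products and the triple product (the standard generalization;
reconstructed, as no printed three-drug formula exists).  Useful algebraic
anchor: a drug sham-combined 1:1 with itself gives exclusive sum exactly 1
and nonexclusive CI exactly 1.25 at every effect level.  CI is invariant
under rescaling all doses.  Synergy bands default to a coarse
synergism / additive / antagonism call with a ±0.1 additive band;
fine-grained band configs ({label: [low, high)}) can be supplied.

## IHC scoring

p16: per-cell mean DAB OD banded at 0.2 / 0.4 / 0.6 (inclusive-left):
negative, weak, moderate, strong; H-score = 100·(weak + 2·moderate +
3·strong) ∈ [0, 300].  KI67: positive at nuclear OD ≥ 0.2 (the boundary
counts positive, consistent with the band convention).  Cells below the
nucleus-area detection minimum are excluded first; the default 15 µm² sits
inside the usual 10–25 µm² detection-setting range and is configurable.
Upstream image analysis (stain deconvolution, cell detection) is out of
scope — inputs are measurement tables.

## Synthetic data: what it emulates, what it does not

All generators take a seed, use an isolated `numpy.random.Generator`, and
emit ground truth beside the data; identical configs are bit-identical.

- **Expression cohorts**: 11-gene vectors drawn per class as
  centroid · exp(N(0, σ_log)) — lognormal noise keeps values nonnegative
  and makes rank-based invariance testable.  The placeholder centroids put
  the genes on a geometric ladder (10·1.6ᵏ) with class-specific rank
  orders: A and H share a proliferative pattern (high E2F1/CCNE1/MYBL2,
  low RB1) and differ mainly in CDKN2A (top-ranked in A), L is
  quiescent-like.  The 1.6× rank gap against σ_log = 0.1 noise makes rank
  flips rare, so class recovery is expected to be high — passing those
  tests validates the pipeline mechanics, not clinical accuracy on real
  tumors, whose class geometry is unknown here.  Defaults: n = 500,
  proportions A/L/H = 0.10/0.50/0.40 (A-profile prevalence of the order
  seen in tumor cohorts), σ_log = 0.1.
- **p14 confounders**: true-H samples with locus expression above even the
  A centroid but exon-1α fraction < 0.05 — the documented failure mode of
  the raw-locus predictor, by construction called A in raw mode and
  resolved by the correction.
- **Locus coverage**: linear background plus rectangular pulses (h₁β on
  exon 1β, h₁α on exon 1α, h₁α+h₁β on the shared exon), iid per-base
  Poisson sampling; defaults h₁α = 60, h₁β = 40 over a background of
  10–25.  Real coverage is smoother (reads correlate neighboring bases)
  and has exon-boundary ramps; the iid model is the harsher test for the
  peak statistic.
- **Copy-number profiles**: integer copies per segment, ψ set consistent
  with the bin-weighted mean copy number (snapped to the 0.01 grid when
  requested), per-bin log noise σ = 0.05 entering segment means as
  σ/√n_bins.  Default 500–8000 bins per segment reflects genome-wide
  30 kb binning, where a typical segment spans thousands of bins; far
  smaller segments leave the ±1-copy degeneracy unresolvable by any
  total-depth method.
- **Dose-response**: fa from the median-effect model on a 2-fold dilution
  around Dm, response = 100(1−fa) + N(0, 5) per replicate.  Combinations
  share the slope m, making the Loewe-additive mixture itself
  median-effect with Dm_mix = 1/Σ(f_i/Dm_i); a potency-shift factor
  divides Dm_mix to create synergy (> 1) or antagonism (< 1).
- **Cells / spots**: OD drawn uniformly within intensity bands with known
  mixture fractions; spot ratios drawn inside the A/L/H bands.

## Problem sizes

Shipped analyses and tests use: 100 coverage tracks, 500 + 10-sample
cohorts, 50 copy-number profiles (~25 segments each), 100 dose-response
curves, 10⁵ random ODs for band-partition checks.  These sizes make every
recovery estimate stable while keeping the full suite in seconds.

## Known limitations

- The true 11-gene panel and breast-cohort reference centroids are
  external data; everything here runs on labelled synthetic placeholders,
  so no clinical accuracy claim transfers.
- Purity/ploidy fitting is total-depth only; WGD-type degeneracies are
  flagged, not resolved.
- The segmentation is binary segmentation with a permutation stop, not a
  full CBS port (pluggable by design).
- Gene lists for TDS/EMT are reconstructed defaults, flagged as such.
- The CI machinery assumes fixed-ratio designs and median-effect-faithful
  data; Bliss/HSA/ZIP-style models are out of scope.
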