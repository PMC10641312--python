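"""Expression normalization, z-scores, TDS/EMT signature scores and sample QC.

Raw transcript counts are normalized to library size as counts per 20
million reads (CP20M).  Gene z-scores are computed across samples; the
thyroid differentiation score (TDS) is the mean z-score of a 16-gene
thyroid-identity panel and the EMT score subtracts the mean z-score of 4
epithelial markers from that of 13 mesenchymal markers.  The shipped gene
lists are reconstructed defaults from the signatures' original sources
(with OCLN included among the epithelial markers) and are fully editable
via YAML config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

CP20M_SCALE = 2e7


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression values.

    ``unit`` is ``"counts"`` (raw counts, ``library_sizes`` required for
    normalization) or ``"cp20m"``.
    """

    values: pd.DataFrame
    unit: str = "counts"
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "cp20m"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.library_sizes is not None:
            self.library_sizes = self.library_sizes.reindex(self.values.columns)
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()]
                raise ValueError(f"missing library sizes for {list(missing)}")
            if (self.library_sizes <= 0).any():
                raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def normalize_cp20m(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize raw counts to counts per 20 million reads.

    value' = value * 2e7 / library_size of its sample.
    """
    if m.unit != "counts":
        raise ValueError("matrix is not in raw counts")
    if m.library_sizes is None:
        raise ValueError("library sizes required for CP20M normalization")
    scaled = m.values * (CP20M_SCALE / m.library_sizes)
    return ExpressionMatrix(values=scaled, unit="cp20m")


def gene_zscores(m: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores across samples (mean-centered, sd-scaled).

    Genes with zero standard deviation are dropped with a warning rather
    than producing NaN columns.  ``ddof=1`` (sample sd) is the default;
    population sd is available via ``ddof=0``.
    """
    if m.values.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    sd = m.values.std(axis=1, ddof=ddof)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"dropping {int(zero_sd.sum())} zero-variance gene(s): "
            f"{list(m.values.index[zero_sd])[:5]}...",
            stacklevel=2,
        )
    kept = m.values.loc[~zero_sd]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~zero_sd], axis=0)


@dataclass(frozen=True)
class GeneSetScore:
    sample_id: str
    score: float
    set_name: str


def _require_genes(z: pd.DataFrame, genes: list[str], what: str) -> None:
    missing = [g for g in genes if g not in z.index]
    if missing:
        raise KeyError(f"{what}: genes missing from z-score matrix: {missing}")


def thyroid_differentiation_score(z: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """TDS per sample: mean z-score of the 16 thyroid-identity genes."""
    if len(gene_set) != 16:
        warnings.warn(f"TDS gene set has {len(gene_set)} genes (expected 16)", stacklevel=2)
    _require_genes(z, gene_set, "TDS")
    return z.loc[gene_set].mean(axis=0).rename("TDS")


def emt_score(
    z: pd.DataFrame, mesenchymal: list[str], epithelial: list[str]
) -> pd.Series:
    """EMT score per sample: mean(z mesenchymal) - mean(z epithelial)."""
    _require_genes(z, mesenchymal, "EMT mesenchymal")
    _require_genes(z, epithelial, "EMT epithelial")
    score = z.loc[mesenchymal].mean(axis=0) - z.loc[epithelial].mean(axis=0)
    return score.rename("EMT")


def load_gene_sets(path=None) -> dict:
    """Load the TDS/EMT gene-set config (package default when no path given)."""
    if path is None:
        text = (
            resources.files("cdk4prof").joinpath("data/gene_sets.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


# --- sample quality control -------------------------------------------------

#: Exclusion thresholds per analysis stage.  Proteomic stage excludes on RNA
#: integrity number (RIN) < 3; the transcriptomic stage additionally requires
#: RIN >= 4.5 and a PCR-duplicate fraction of at most 0.5% of the library.
QC_THRESHOLDS = {
    "proteomic": {"min_rin": 3.0},
    "transcriptomic": {"min_rin": 4.5, "max_pcr_duplicate_fraction": 0.005},
}


@dataclass
class SampleQCRecord:
    sample_id: str
    rin: float
    pcr_duplicate_fraction: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rin < 0:
            raise ValueError(f"{self.sample_id}: negative RIN")
        if not 0 <= self.pcr_duplicate_fraction <= 1:
            raise ValueError(f"{self.sample_id}: PCR-duplicate fraction outside [0,1]")


def apply_sample_qc(
    records: list[SampleQCRecord],
    stage: str,
    thresholds: dict | None = None,
) -> tuple[list[SampleQCRecord], list[SampleQCRecord]]:
    """Partition samples into (kept, excluded); excluded carry their reasons."""
    if stage not in QC_THRESHOLDS:
        raise ValueError(f"unknown QC stage {stage!r}")
    th = dict(QC_THRESHOLDS[stage])
    if thresholds:
        th.update(thresholds)
    kept, excluded = [], []
    for rec in records:
        flags = []
        if rec.rin < th["min_rin"]:
            flags.append(f"low_rin(<{th['min_rin']})")
        max_dup = th.get("max_pcr_duplicate_fraction")
        if max_dup is not None and rec.pcr_duplicate_fraction > max_dup:
            flags.append(f"high_pcr_duplicates(>{max_dup})")
        rec.flags = flags
        (excluded if flags else kept).append(rec)
    return kept, excluded


# --- TSV ingestion ----------------------------------------------------------

def read_expression_tsv(path, unit: str = "counts", library_sizes_path=None) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lib = None
    if library_sizes_path is not None:
        lib_df = pd.read_csv(library_sizes_path, sep="\t", index_col=0)
        lib = lib_df.iloc[:, 0]
    return ExpressionMatrix(values=df, unit=unit, library_sizes=lib)
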