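"""End-to-end orchestration: simulate -> exon-1alpha -> predict -> evaluate.

A pipeline run is fully specified by a small config (YAML-friendly dict);
unknown keys are rejected so typos fail loudly.  Outputs are deterministic
given config + seed: per-stage TSV tables plus a machine-readable
``summary.json`` embedding the accuracy figures, the config hash and the
package version.  Structured progress goes to stderr.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .centroid_predictor import evaluate_predictions, predict_cohort
from .synthetic_data import simulate_expression_cohort

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    n_samples: int = 500
    sigma_log: float = 0.1
    n_confounders: int = 0
    class_proportions: dict[str, float] | None = None
    cdkn2a_mode: str = "exon1a_corrected"  # raw_locus | exon1a_corrected | both

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.cdkn2a_mode not in ("raw_locus", "exon1a_corrected", "both"):
            raise PipelineError("config", f"unknown cdkn2a_mode {cfg.cdkn2a_mode!r}")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log(msg: str) -> None:
    print(f"cdk4prof: {msg}", file=sys.stderr)


def run_pipeline(config: dict | PipelineConfig, outdir) -> dict:
    """Run the simulate/predict/evaluate pipeline into ``outdir``.

    Returns the summary dict that is also written to ``summary.json``.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    _log(f"simulate: n={cfg.n_samples} (+{cfg.n_confounders} confounders), "
         f"sigma_log={cfg.sigma_log}, seed={cfg.seed}")
    try:
        cohort = simulate_expression_cohort(
            seed=cfg.seed,
            n_samples=cfg.n_samples,
            class_proportions=cfg.class_proportions,
            sigma_log=cfg.sigma_log,
            n_confounders=cfg.n_confounders,
        )
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    cohort.expression.to_csv(out / "expression_cp20m.tsv", sep="\t")
    cohort.labels.to_frame().to_csv(out / "truth.tsv", sep="\t")
    cohort.exon1a.to_frame().to_csv(out / "exon1a.tsv", sep="\t")
    cohort.reference.to_json(out / "reference.json")

    summary: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "n_samples": int(cfg.n_samples + cfg.n_confounders),
        "modes": {},
    }
    modes = (
        ["raw_locus", "exon1a_corrected"] if cfg.cdkn2a_mode == "both" else [cfg.cdkn2a_mode]
    )
    truth = list(cohort.labels)
    for mode in modes:
        _log(f"predict: mode={mode}")
        try:
            preds = predict_cohort(
                cohort.expression,
                cohort.reference,
                exon1a=cohort.exon1a if mode == "exon1a_corrected" else None,
                known_a_sample_ids=cohort.known_a_ids if mode == "exon1a_corrected" else None,
            )
        except Exception as exc:
            raise PipelineError(f"predict:{mode}", str(exc)) from exc
        preds.to_csv(out / f"predictions_{mode}.tsv", sep="\t", index=False)
        ev3 = evaluate_predictions(truth, list(preds["predicted"]), "three_class")
        ev2 = evaluate_predictions(truth, list(preds["binary"]), "binary")
        summary["modes"][mode] = {
            "three_class_accuracy": ev3.accuracy,
            "binary_accuracy": ev2.accuracy,
            "confusion_three_class": ev3.confusion.to_dict(),
        }
        _log(f"  three-class accuracy {ev3.accuracy:.3f}, binary {ev2.accuracy:.3f}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _log(f"summary written to {out / 'summary.json'}")
    return summary
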