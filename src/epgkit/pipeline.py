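"""End-to-end orchestration: annotations + metadata -> parameter table,
cohort summaries, group statistics with compact letters, and QC report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .io import (AnnotationError, MetadataTable, read_annotation,
                 read_metadata, validate_grammar)
from .model import ModelConfig, reclassify_early_g
from .parameters import (compute_cohort, compute_insect_parameters,
                         parameters_to_table)
from .stats import group_compare

__all__ = ["RunConfig", "QcSummary", "qc_summary", "run_pipeline"]

log = logging.getLogger("epgkit")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Defaults follow the standard study design: 12-h recordings,
    alpha = 0.05, 10-min early-G and sustained thresholds.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    alpha: float = 0.05
    factor: str = "group"
    proportion_params: list[str] = field(
        default_factory=lambda: ["pct_E1_of_phloem"]
    )
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not self.factor:
            raise ValueError("factor must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelConfig(**raw.pop("model", {}))
        return cls(model=model, **raw)


@dataclass(frozen=True)
class QcSummary:
    """Data-quality accounting for one experiment.

    ``completed`` counts insects whose full-length recording succeeded
    (including those later judged bad); ``high_quality`` counts the
    recordings retained for analysis.  Percentages are reported rounded
    to the nearest integer with the exact values retained.
    """

    n_wired: int
    n_completed: int
    n_high_quality: int
    pct_completed: float        # exact, completed / wired * 100
    pct_high_quality: float     # exact, high-quality / completed * 100
    pct_completed_rounded: int
    pct_high_quality_rounded: int


def qc_summary(metadata: MetadataTable, n_wired: int) -> QcSummary:
    """Compute recording-success and retention rates.

    ``status == completed`` marks a retained high-quality recording;
    ``excluded_bad_recording`` marks a full-length recording judged
    unusable; ``escaped`` insects never completed the recording.
    """
    if n_wired <= 0:
        raise ValueError("n_wired must be positive")
    df = metadata.frame
    n_completed = int((df["status"].isin(["completed", "excluded_bad_recording"])).sum())
    n_hq = int((df["status"] == "completed").sum())
    if n_wired < n_completed:
        raise ValueError(
            f"n_wired ({n_wired}) smaller than completed recordings ({n_completed})"
        )
    pct_completed = 100.0 * n_completed / n_wired
    if n_completed == 0:
        warnings.warn("no completed recordings; retention rate undefined, set to 0")
        pct_hq = 0.0
    else:
        pct_hq = 100.0 * n_hq / n_completed
    return QcSummary(
        n_wired=n_wired,
        n_completed=n_completed,
        n_high_quality=n_hq,
        pct_completed=pct_completed,
        pct_high_quality=pct_hq,
        pct_completed_rounded=round(pct_completed),
        pct_high_quality_rounded=round(pct_hq),
    )


def run_pipeline(
    config: RunConfig,
    annotation_dir: str | Path,
    metadata_file: str | Path,
    n_wired: int | None = None,
) -> dict:
    """Run the full analysis and write the result bundle.

    Reads every annotation referenced by a ``completed`` metadata row,
    validates its grammar, applies the early-G reclassification,
    computes the per-insect parameter battery, summarizes cohorts, and
    runs the transformation + Tukey-Kramer + letter-display statistics
    across ``config.factor``.

    Writes under ``config.out_dir``: ``parameters.csv`` (storage units,
    seconds), ``parameters_display.csv`` (table units),
    ``cohorts.csv``, ``stats.csv``, ``stats_transformed.csv``
    (supplementary transformed-scale means and CIs), ``qc.json`` and
    ``manifest.json``.  Returns the bundle as a dict.  Per-file
    failures are collected, not fatal, unless every file fails or any
    recording has grammar errors.
    """
    logging.basicConfig(level=config.log_level)
    annotation_dir = Path(annotation_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metadata = read_metadata(metadata_file)
    if config.factor not in metadata.frame.columns:
        raise ValueError(f"factor {config.factor!r} not in metadata")

    records, errors, grammar_errors = [], {}, {}
    completed = metadata.completed()
    if completed.empty:
        raise AnnotationError("metadata contains no completed recordings")
    for _, row in completed.iterrows():
        path = annotation_dir / row["file"]
        try:
            rec = read_annotation(path, insect_id=row["insect_id"])
            viol = [v for v in validate_grammar(rec) if v.severity == "error"]
            if viol:
                grammar_errors[row["insect_id"]] = [
                    f"{v.rule_id}@{v.position}: {v.message}" for v in viol
                ]
                continue
            rec = reclassify_early_g(rec, config.model)
            records.append(compute_insect_parameters(rec, config.model))
        except (OSError, AnnotationError, ValueError) as exc:
            errors[row["insect_id"]] = str(exc)
            log.error("failed on %s: %s", row["insect_id"], exc)
    if not records:
        raise AnnotationError(f"no usable recordings; errors: {errors}")

    table = parameters_to_table(records)
    table.to_csv(out_dir / "parameters.csv")
    parameters_to_table(records, display_units=True).to_csv(
        out_dir / "parameters_display.csv"
    )

    grouping = metadata.frame.set_index("insect_id")[config.factor]
    cohort_rows = []
    for level in sorted(grouping.loc[table.index].unique()):
        recs = [r for r in records if grouping[r.insect_id] == level]
        summ = compute_cohort(recs, group=level)
        s = summ.stats.copy()
        s.insert(0, "group", level)
        s.insert(1, "n_group", summ.n)
        s["percent_with_E2"] = summ.percent_with_E2
        cohort_rows.append(s.reset_index(names="parameter"))
    cohorts = pd.concat(cohort_rows, ignore_index=True)
    cohorts.to_csv(out_dir / "cohorts.csv", index=False)

    comparisons = group_compare(
        table, metadata, config.factor, alpha=config.alpha,
        proportion_params=config.proportion_params,
    )
    stat_rows, supp_rows = [], []
    for cmp_ in comparisons:
        if cmp_.skipped:
            stat_rows.append({"parameter": cmp_.parameter, "skipped": cmp_.skipped})
            continue
        for lev, row in cmp_.summary.iterrows():
            stat_rows.append({
                "parameter": cmp_.parameter, "group": lev, "n": int(row["n"]),
                "mean_original": row["mean_original"], "letter": row["letter"],
                "lambda": cmp_.transform.lam, "shift": cmp_.transform.shift,
                "arcsine": cmp_.transform.arcsine_first,
                "shapiro_w": cmp_.transform.shapiro_w,
            })
            supp_rows.append({
                "parameter": cmp_.parameter, "group": lev,
                "mean_transformed": row["mean_transformed"],
                "ci_low": row["ci_low"], "ci_high": row["ci_high"],
            })
    stats_df = pd.DataFrame(stat_rows)
    stats_df.to_csv(out_dir / "stats.csv", index=False)
    pd.DataFrame(supp_rows).to_csv(out_dir / "stats_transformed.csv", index=False)

    qc = None
    if n_wired is not None:
        qc = qc_summary(metadata, n_wired)
        (out_dir / "qc.json").write_text(json.dumps(asdict(qc), indent=2))

    manifest = {
        "n_insects": len(records),
        "n_errors": len(errors),
        "errors": errors,
        "grammar_errors": grammar_errors,
        "factor": config.factor,
        "alpha": config.alpha,
        "seed": config.seed,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "parameters": table,
        "cohorts": cohorts,
        "comparisons": comparisons,
        "stats": stats_df,
        "qc": qc,
        "manifest": manifest,
    }
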