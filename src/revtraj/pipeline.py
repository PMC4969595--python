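"""End-to-end orchestration.

A single :class:`PipelineConfig` (usually loaded from YAML) names the
input matrix (or a generator configuration), maps matrix columns to the
roles baseline / perturbed / treated / endpoint / pre_endpoint, carries a
:class:`ClassificationConfig`, and points at an output directory.
``run_pipeline`` executes every applicable stage, writes machine-readable
reports, and returns a summary that echoes every threshold used.  Output
is deterministic: re-running with identical inputs reproduces identical
bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .config import ClassificationConfig
from .exceptions import ConfigError, UnknownConditionError
from .expression_io import (
    ExpressionMatrix,
    compute_ratio,
    filter_detectable,
    load_expression_matrix,
    load_gene_sets,
)
from .pathways import pathway_direction_fractions
from .reversal import (
    assign_bins,
    classify_t20_response,
    summarize_bins,
    summarize_strata,
)
from .simulate import GeneratorConfig, generate
from .trajectory import (
    classify_trajectory,
    favorability_report,
    labels_to_records,
    select_responsive_genes,
)

logger = logging.getLogger(__name__)

REQUIRED_ROLES = ("baseline", "perturbed", "treated")
OPTIONAL_ROLES = ("endpoint", "pre_endpoint")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``matrix_path`` / ``generator`` must be set.  ``roles``
    maps role names to matrix condition ids; baseline, perturbed and
    treated are required, endpoint and pre_endpoint enable the trajectory
    stage.  ``gene_sets_path`` (GMT) enables the pathway stage.
    """

    output_dir: str
    matrix_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    roles: dict = field(
        default_factory=lambda: {
            "baseline": "baseline",
            "perturbed": "perturbed",
            "treated": "treated",
        }
    )
    gene_sets_path: Optional[str] = None
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    def __post_init__(self) -> None:
        if (self.matrix_path is None) == (self.generator is None):
            raise ConfigError("set exactly one of matrix_path or generator")
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise ConfigError(f"missing condition roles: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"pipeline config {path} must be a mapping")
        kwargs = dict(raw)
        if "classification" in kwargs and kwargs["classification"] is not None:
            kwargs["classification"] = ClassificationConfig(**kwargs["classification"])
        if "generator" in kwargs and kwargs["generator"] is not None:
            gen = dict(kwargs["generator"])
            if gen.get("timepoints") is not None:
                gen["timepoints"] = tuple(gen["timepoints"])
            kwargs["generator"] = GeneratorConfig(**gen)
        return cls(**kwargs)


def _json_dump(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages and write reports into ``output_dir``.

    Returns the summary report (also written as ``summary.json``), whose
    manifest lists every file produced.  Raised stage errors carry the
    stage name in their message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {
        "version": __version__,
        "classification_config": config.classification.as_dict(),
        "roles": dict(config.roles),
    }

    # --- input stage -----------------------------------------------------
    try:
        if config.generator is not None:
            matrix, truth = generate(config.generator)
            summary["seed"] = config.generator.seed
            summary["generator_config"] = config.generator.as_dict()
            matrix.to_tsv(outdir / "matrix.tsv")
            _json_dump(truth.as_dict(), outdir / "truth.json")
            manifest += ["matrix.tsv", "truth.json"]
        else:
            matrix = load_expression_matrix(config.matrix_path)
            summary["matrix_path"] = str(config.matrix_path)
    except Exception as exc:
        raise type(exc)(f"[input stage] {exc}") from exc

    cc = config.classification
    for role, cond in config.roles.items():
        if cond not in matrix.condition_ids:
            raise UnknownConditionError(
                f"[input stage] role {role!r} maps to unknown condition {cond!r}"
            )

    # --- detectability filter --------------------------------------------
    n_input = matrix.shape[0]
    detectable = filter_detectable(matrix, cc.min_tpm, cc.min_conditions)
    n_detectable = detectable.shape[0]
    logger.info(
        "detectability: %d input genes = %d retained + %d filtered",
        n_input,
        n_detectable,
        n_input - n_detectable,
    )
    summary["gene_counts"] = {
        "input": n_input,
        "detectable": n_detectable,
        "filtered_out": n_input - n_detectable,
    }

    # --- reversal stage ---------------------------------------------------
    try:
        r1 = compute_ratio(
            detectable, config.roles["perturbed"], config.roles["baseline"], cc.pseudocount
        )
        rT = compute_ratio(
            detectable, config.roles["treated"], config.roles["perturbed"], cc.pseudocount
        )
        labels = classify_t20_response(r1, rT, cc)
        bins = assign_bins(r1, cc)
        label_frame = pd.DataFrame(
            {
                "gene_id": [l.gene_id for l in labels],
                "r1": r1.ratio,
                "rT": rT.ratio,
                "stratum": [l.baseline_stratum for l in labels],
                "category": [l.t20_category for l in labels],
                "interpretation": [l.interpretation for l in labels],
                "bin": bins,
            }
        )
        label_frame.to_csv(
            outdir / "gene_labels.tsv", sep="\t", index=False, float_format="%.17g"
        )
        manifest.append("gene_labels.tsv")

        strata = summarize_strata(labels)
        _json_dump(strata, outdir / "stratum_report.json")
        manifest.append("stratum_report.json")
        summary["stratum_report"] = strata

        bin_rows = [
            {
                "bin_index": b.bin_index,
                "log2_lower": b.bin_log2_bounds[0],
                "log2_upper": b.bin_log2_bounds[1],
                "gene_count": b.gene_count,
                "mean_log2_rT": b.mean_log2_rT,
                "standard_error_log2_rT": b.standard_error_log2_rT,
            }
            for b in summarize_bins(r1, rT, cc)
        ]
        pd.DataFrame(bin_rows).to_csv(
            outdir / "bin_summary.tsv", sep="\t", index=False, float_format="%.17g"
        )
        manifest.append("bin_summary.tsv")
    except Exception as exc:
        raise type(exc)(f"[reversal stage] {exc}") from exc

    # --- trajectory stage (needs endpoint columns) ------------------------
    if all(r in config.roles for r in OPTIONAL_ROLES):
        try:
            r2 = compute_ratio(
                detectable,
                config.roles["endpoint"],
                config.roles["baseline"],
                cc.pseudocount,
            )
            r3 = compute_ratio(
                detectable,
                config.roles["pre_endpoint"],
                config.roles["endpoint"],
                cc.pseudocount,
            )
            responsive = select_responsive_genes(r1, cc.responsive_fold_threshold)
            summary["gene_counts"]["responsive"] = len(responsive)
            if responsive:
                tlabels = classify_trajectory(r1.subset(responsive), r2, r3, cc)
                pd.DataFrame(labels_to_records(tlabels)).to_csv(
                    outdir / "trajectory_labels.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.17g",
                )
                manifest.append("trajectory_labels.tsv")
                fav = favorability_report(tlabels).as_dict()
                fav["responsive_fold_threshold"] = cc.responsive_fold_threshold
                _json_dump(fav, outdir / "favorability.json")
                manifest.append("favorability.json")
                summary["favorability"] = fav
        except Exception as exc:
            raise type(exc)(f"[trajectory stage] {exc}") from exc

    # --- pathway stage ----------------------------------------------------
    if config.gene_sets_path is not None:
        try:
            sets = load_gene_sets(config.gene_sets_path)
            reports = [
                pathway_direction_fractions(matrix, s, r1, rT, cc).as_dict()
                for s in sets
            ]
            _json_dump({"pathways": reports}, outdir / "pathway_reports.json")
            manifest.append("pathway_reports.json")
            summary["pathways"] = reports
        except Exception as exc:
            raise type(exc)(f"[pathway stage] {exc}") from exc

    manifest.append("summary.json")
    summary["manifest"] = sorted(manifest)
    _json_dump(summary, outdir / "summary.json")
    return summary
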