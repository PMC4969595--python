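"""Treated-vs-perturbed reversal analysis.

Given two ratio tables over the same genes — r1 (perturbed vs baseline)
and rT (treated vs perturbed) — this module bins genes by r1 on a log2
scale and summarizes rT per bin, and classifies each gene's treated
response into not-significant / increased / decreased with a
reversed / consistent / unaffected interpretation relative to the gene's
baseline stratum.

The not-significant band on rT is inclusive at both ends; the down/up
strata on r1 use strict inequalities (down-regulated by *more than* 50%,
up-regulated by *more than* 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ClassificationConfig, round_half_up
from .exceptions import GeneMismatchError
from .expression_io import RatioTable

STRATA = ("down", "up", "neither")
CATEGORIES = ("not_significant", "increased", "decreased")
INTERPRETATIONS = ("unaffected", "reversed", "consistent", "not_applicable")


@dataclass(frozen=True)
class ResponseLabel:
    """Per-gene outcome of the treated-response classification."""

    gene_id: str
    baseline_stratum: str  # down | up | neither, from r1
    t20_category: str  # not_significant | increased | decreased, from rT
    interpretation: str  # reversed | consistent | unaffected | not_applicable


@dataclass(frozen=True)
class BinSummary:
    """Mean and standard error of log2 rT within one r1 bin.

    ``standard_error_log2_rT`` is the sample standard deviation divided by
    sqrt(gene_count); both statistics are None when the bin holds fewer
    than the required genes (mean: 1, SE: 2).
    """

    bin_index: int
    bin_log2_bounds: tuple[float, float]  # half-open, lower inclusive
    gene_count: int
    mean_log2_rT: Optional[float]
    standard_error_log2_rT: Optional[float]


def _check_matched(r1: RatioTable, rT: RatioTable) -> None:
    if r1.gene_ids != rT.gene_ids:
        raise GeneMismatchError(
            "r1 and rT must cover the same genes in the same order "
            f"({len(r1)} vs {len(rT)} genes)"
        )


def bin_edges(config: ClassificationConfig) -> np.ndarray:
    """The n_bins+1 log2 edges, equal width over [-range, +range)."""
    return np.linspace(-config.bin_range_log2, config.bin_range_log2, config.n_bins + 1)


def assign_bins(r1: RatioTable, config: ClassificationConfig) -> np.ndarray:
    """Assign each gene to one of n_bins equal-width log2(r1) bins.

    Bins are half-open (lower edge inclusive); the first and last bins
    additionally absorb values below / above the covered range, so every
    gene receives exactly one bin index in [0, n_bins).
    """
    if len(r1) == 0:
        raise GeneMismatchError("cannot bin an empty ratio table")
    edges = bin_edges(config)
    idx = np.digitize(r1.log2_ratio, edges) - 1
    return np.clip(idx, 0, config.n_bins - 1)


def summarize_bins(
    r1: RatioTable, rT: RatioTable, config: ClassificationConfig
) -> list[BinSummary]:
    """Per-bin mean and standard error of log2(rT), binned by log2(r1)."""
    _check_matched(r1, rT)
    bins = assign_bins(r1, config)
    edges = bin_edges(config)
    out: list[BinSummary] = []
    for b in range(config.n_bins):
        vals = rT.log2_ratio[bins == b]
        n = int(vals.size)
        mean = float(np.mean(vals)) if n >= 1 else None
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
        out.append(
            BinSummary(
                bin_index=b,
                bin_log2_bounds=(float(edges[b]), float(edges[b + 1])),
                gene_count=n,
                mean_log2_rT=mean,
                standard_error_log2_rT=se,
            )
        )
    return out


def classify_t20_response(
    r1: RatioTable, rT: RatioTable, config: ClassificationConfig
) -> list[ResponseLabel]:
    """Classify each gene's treated response relative to its baseline stratum.

    Stratum from r1: down iff r1 < down_stratum_max_ratio, up iff
    r1 > up_stratum_min_ratio, else neither.  Category from rT:
    not_significant iff ns_lower <= rT <= ns_upper (inclusive band),
    increased above it, decreased below it.  Interpretation: a response
    opposing the stratum direction is "reversed", one amplifying it is
    "consistent", a not-significant response is "unaffected"; genes outside
    both strata are "not_applicable".
    """
    _check_matched(r1, rT)
    labels: list[ResponseLabel] = []
    for gene, v1, vT in zip(r1.gene_ids, r1.ratio, rT.ratio):
        if v1 < config.down_stratum_max_ratio:
            stratum = "down"
        elif v1 > config.up_stratum_min_ratio:
            stratum = "up"
        else:
            stratum = "neither"
        if config.ns_lower <= vT <= config.ns_upper:
            category = "not_significant"
        elif vT > config.ns_upper:
            category = "increased"
        else:
            category = "decreased"
        if stratum == "neither":
            interp = "not_applicable"
        elif category == "not_significant":
            interp = "unaffected"
        elif (stratum == "down") == (category == "increased"):
            interp = "reversed"
        else:
            interp = "consistent"
        labels.append(ResponseLabel(gene, stratum, category, interp))
    return labels


def summarize_strata(labels: list[ResponseLabel]) -> dict:
    """Counts and percentages per stratum x interpretation.

    For the down and up strata the unaffected/reversed/consistent counts
    sum to the stratum total; percentages are relative to the stratum total
    and rounded to one decimal.  The "neither" stratum reports its total
    only (all its genes are not_applicable).
    """
    report: dict = {}
    for stratum in STRATA:
        in_stratum = [l for l in labels if l.baseline_stratum == stratum]
        total = len(in_stratum)
        entry: dict = {"total": total}
        if stratum != "neither":
            counts = {
                interp: sum(1 for l in in_stratum if l.interpretation == interp)
                for interp in ("unaffected", "reversed", "consistent")
            }
            entry["counts"] = counts
            entry["percentages"] = {
                interp: (round_half_up(100.0 * c / total, 1) if total else 0.0)
                for interp, c in counts.items()
            }
        report[stratum] = entry
    report["total_genes"] = len(labels)
    return report
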