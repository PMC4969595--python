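"""Four-way favorability classification of perturbation-induced changes.

Three ratios describe each gene's trajectory: r1 = perturbed vs baseline
(the induced change), r2 = endpoint vs baseline (the change the
destination cell state actually requires), and r3 = pre-endpoint vs
endpoint (how a partially converted intermediate differs from the
destination).  Working in log2 with d1 = log2 r1 and d2 = log2 r2, the
default rule labels each responsive gene:

* ``un_necessary``   — |d2| < endpoint_change_min_log2: the endpoint barely
  changes, so any induced change addresses nothing;
* ``opposite``       — sign(d1) != sign(d2): induced change points away
  from the endpoint;
* ``over_regulated`` — |d1| > |d2| + overshoot_margin_log2: right
  direction, overshooting the endpoint;
* ``consistent``     — otherwise.

d3 = log2 r3 is passed to rule functions but unused by the default rule;
the rule is pluggable and every report records which rule produced it.
Changes labeled opposite, un_necessary, or over_regulated are pooled as
"unfavorable".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .config import ClassificationConfig, round_half_up
from .exceptions import RevtrajError
from .expression_io import RatioTable

TRAJECTORY_CATEGORIES = (
    "consistent",
    "un_necessary",
    "opposite",
    "over_regulated",
    "unclassified",
)
UNFAVORABLE_CATEGORIES = ("un_necessary", "opposite", "over_regulated")

# rule signature: (d1, d2, d3, config) -> category for one gene
RuleFunction = Callable[[float, float, Optional[float], ClassificationConfig], str]


@dataclass(frozen=True)
class TrajectoryLabel:
    gene_id: str
    category: str
    r1_log2: float
    r2_log2: Optional[float]
    r3_log2: Optional[float]


@dataclass(frozen=True)
class FavorabilityReport:
    """Category counts and nearest-integer percentages over classified genes.

    ``unfavorable_percentage`` pools un_necessary, opposite and
    over_regulated against the full gene total (unclassified genes count in
    the denominator, matching an accounting where some selected genes
    escape all four categories).
    """

    total_genes: int
    counts: dict
    percentages: dict
    opposite_or_unnecessary_count: int
    opposite_or_unnecessary_percentage: float
    unfavorable_percentage: float
    rule_name: str = "default_four_way"

    def as_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "opposite_or_unnecessary_count": self.opposite_or_unnecessary_count,
            "opposite_or_unnecessary_percentage": self.opposite_or_unnecessary_percentage,
            "unfavorable_percentage": self.unfavorable_percentage,
            "rule_name": self.rule_name,
        }


def default_four_way_rule(
    d1: float, d2: float, d3: Optional[float], config: ClassificationConfig
) -> str:
    if abs(d2) < config.endpoint_change_min_log2:
        return "un_necessary"
    if d1 * d2 < 0:
        return "opposite"
    if abs(d1) > abs(d2) + config.overshoot_margin_log2:
        return "over_regulated"
    return "consistent"


def select_responsive_genes(r1: RatioTable, fold_threshold: float = 2.0) -> list[str]:
    """Genes whose r1 exceeds ``fold_threshold`` in either direction (strict)."""
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must exceed 1, got {fold_threshold}")
    mask = (r1.ratio > fold_threshold) | (r1.ratio < 1.0 / fold_threshold)
    return [g for g, m in zip(r1.gene_ids, mask) if m]


def classify_trajectory(
    r1: RatioTable,
    r2: RatioTable,
    r3: RatioTable,
    config: ClassificationConfig,
    rule: RuleFunction = default_four_way_rule,
    rule_name: Optional[str] = None,
) -> list[TrajectoryLabel]:
    """Apply the four-way rule to every gene of ``r1``.

    Genes missing from ``r2`` or ``r3`` are labeled ``unclassified``.
    ``r1`` is expected to already be restricted to responsive genes (see
    :func:`select_responsive_genes`); the rule sees log2 values.
    """
    d2_by_gene = dict(zip(r2.gene_ids, r2.log2_ratio))
    d3_by_gene = dict(zip(r3.gene_ids, r3.log2_ratio))
    labels: list[TrajectoryLabel] = []
    for gene, d1 in zip(r1.gene_ids, r1.log2_ratio):
        d2 = d2_by_gene.get(gene)
        d3 = d3_by_gene.get(gene)
        if d2 is None:
            labels.append(TrajectoryLabel(gene, "unclassified", float(d1), None, d3))
            continue
        category = rule(float(d1), float(d2), d3, config)
        if category not in TRAJECTORY_CATEGORIES:
            raise RevtrajError(f"rule returned unknown category {category!r}")
        labels.append(
            TrajectoryLabel(
                gene,
                category,
                float(d1),
                float(d2),
                float(d3) if d3 is not None else None,
            )
        )
    return labels


def favorability_report(
    labels: Sequence[TrajectoryLabel], rule_name: str = "default_four_way"
) -> FavorabilityReport:
    """Counts, nearest-integer percentages, and the unfavorable fraction."""
    if not labels:
        raise ValueError("favorability_report requires at least one label")
    total = len(labels)
    counts = {
        cat: sum(1 for l in labels if l.category == cat)
        for cat in TRAJECTORY_CATEGORIES
    }
    percentages = {
        cat: round_half_up(100.0 * c / total) for cat, c in counts.items()
    }
    pooled = counts["opposite"] + counts["un_necessary"]
    unfavorable = sum(counts[c] for c in UNFAVORABLE_CATEGORIES)
    return FavorabilityReport(
        total_genes=total,
        counts=counts,
        percentages=percentages,
        opposite_or_unnecessary_count=pooled,
        opposite_or_unnecessary_percentage=round_half_up(100.0 * pooled / total),
        unfavorable_percentage=round_half_up(100.0 * unfavorable / total),
        rule_name=rule_name,
    )


def timecourse_unfavorable(
    r1_series: Sequence[tuple[str, RatioTable]],
    r2: RatioTable,
    r3: RatioTable,
    config: ClassificationConfig,
    rule: RuleFunction = default_four_way_rule,
) -> list[tuple[str, Optional[FavorabilityReport]]]:
    """One favorability report per time point.

    Responsive-gene selection (``config.responsive_fold_threshold``) is
    re-applied at every time point, so each report records its own
    responsive-gene count.  Every time point must cover the same gene
    universe.  A time point with no responsive genes yields None.
    """
    universes = {t[1].gene_ids for t in r1_series}
    if len(universes) > 1:
        raise RevtrajError("time points cover inconsistent gene universes")
    out: list[tuple[str, Optional[FavorabilityReport]]] = []
    for label, r1_t in r1_series:
        responsive = select_responsive_genes(r1_t, config.responsive_fold_threshold)
        if not responsive:
            out.append((label, None))
            continue
        labels = classify_trajectory(r1_t.subset(responsive), r2, r3, config, rule)
        out.append((label, favorability_report(labels)))
    return out


def labels_to_records(labels: Sequence[TrajectoryLabel]) -> list[dict]:
    """Flatten labels for TSV output."""
    return [
        {
            "gene_id": l.gene_id,
            "category": l.category,
            "r1_log2": l.r1_log2,
            "r2_log2": l.r2_log2 if l.r2_log2 is not None else np.nan,
            "r3_log2": l.r3_log2 if l.r3_log2 is not None else np.nan,
        }
        for l in labels
    ]
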