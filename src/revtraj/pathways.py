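"""Per-gene-set direction fractions and divergent-gene shortlists.

For a gene set (e.g. KEGG oxidative phosphorylation or glycolysis), report
how many members are detectable, what share of detectable members the
perturbation moved up or down, what share the treatment moved back, and
which members changed strongly in both comparisons (the shortlist fed to
expression heat maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ClassificationConfig
from .expression_io import ExpressionMatrix, GeneSet, RatioTable, filter_detectable

# Shortlist defaults: 2-fold on the perturbation ratio, 1.5-fold on the
# treated ratio (the edge of the not-significant band).  These are this
# package's own choices and are flagged as such in reports.
DEFAULT_MIN_ABS_LOG2_R1 = 1.0
DEFAULT_MIN_ABS_LOG2_RT = 0.585


@dataclass(frozen=True)
class PathwayDirectionReport:
    set_name: str
    members_total: int
    members_detectable: int
    fraction_up_r1: Optional[float]
    fraction_down_r1: Optional[float]
    fraction_reversed_by_treatment: Optional[float]
    selected_divergent_genes: tuple[str, ...]
    divergence_thresholds_log2: tuple[float, float] = (
        DEFAULT_MIN_ABS_LOG2_R1,
        DEFAULT_MIN_ABS_LOG2_RT,
    )
    thresholds_are_package_defaults: bool = True

    def as_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "members_total": self.members_total,
            "members_detectable": self.members_detectable,
            "fraction_up_r1": self.fraction_up_r1,
            "fraction_down_r1": self.fraction_down_r1,
            "fraction_reversed_by_treatment": self.fraction_reversed_by_treatment,
            "selected_divergent_genes": list(self.selected_divergent_genes),
            "divergence_thresholds_log2": list(self.divergence_thresholds_log2),
            "thresholds_are_package_defaults": self.thresholds_are_package_defaults,
        }


def select_divergent_genes(
    gene_set: GeneSet,
    r1: RatioTable,
    rT: RatioTable,
    min_abs_log2_r1: float = DEFAULT_MIN_ABS_LOG2_R1,
    min_abs_log2_rT: float = DEFAULT_MIN_ABS_LOG2_RT,
) -> list[str]:
    """Set members with |log2 r1| >= t1 AND |log2 rT| >= t2.

    Sorted by descending |log2 r1| (ties broken by gene id for
    determinism).  Members absent from either table are skipped.
    """
    if min_abs_log2_r1 < 0 or min_abs_log2_rT < 0:
        raise ValueError("divergence thresholds must be non-negative")
    d1 = dict(zip(r1.gene_ids, r1.log2_ratio))
    dT = dict(zip(rT.gene_ids, rT.log2_ratio))
    hits = [
        g
        for g in gene_set.members
        if g in d1
        and g in dT
        and abs(d1[g]) >= min_abs_log2_r1
        and abs(dT[g]) >= min_abs_log2_rT
    ]
    return sorted(hits, key=lambda g: (-abs(d1[g]), g))


def pathway_direction_fractions(
    m: ExpressionMatrix,
    gene_set: GeneSet,
    r1: RatioTable,
    rT: RatioTable,
    config: ClassificationConfig,
    min_abs_log2_r1: float = DEFAULT_MIN_ABS_LOG2_R1,
    min_abs_log2_rT: float = DEFAULT_MIN_ABS_LOG2_RT,
) -> PathwayDirectionReport:
    """Direction fractions over the set's detectable members.

    Detectability uses ``config.min_tpm`` / ``config.min_conditions`` on
    ``m``.  fraction_up_r1 counts detectable members with r1 > 1,
    fraction_down_r1 those with r1 < 1 (a ratio of exactly 1 counts in
    neither); fraction_reversed_by_treatment counts detectable members
    whose rT direction opposes their r1 direction.  A set disjoint from the
    matrix yields members_detectable 0 and missing (None) fractions.
    """
    detectable_m = filter_detectable(m, config.min_tpm, config.min_conditions)
    d1 = dict(zip(r1.gene_ids, r1.ratio))
    dT = dict(zip(rT.gene_ids, rT.ratio))
    detectable = [
        g
        for g in detectable_m.gene_ids
        if g in gene_set.members and g in d1 and g in dT
    ]
    n = len(detectable)
    if n == 0:
        return PathwayDirectionReport(
            set_name=gene_set.name,
            members_total=len(gene_set),
            members_detectable=0,
            fraction_up_r1=None,
            fraction_down_r1=None,
            fraction_reversed_by_treatment=None,
            selected_divergent_genes=(),
            divergence_thresholds_log2=(min_abs_log2_r1, min_abs_log2_rT),
        )
    v1 = np.array([d1[g] for g in detectable])
    vT = np.array([dT[g] for g in detectable])
    reversed_mask = ((v1 > 1) & (vT < 1)) | ((v1 < 1) & (vT > 1))
    detectable_set = GeneSet(
        name=gene_set.name,
        description=gene_set.description,
        members=frozenset(detectable),
    )
    shortlist = select_divergent_genes(
        detectable_set, r1, rT, min_abs_log2_r1, min_abs_log2_rT
    )
    return PathwayDirectionReport(
        set_name=gene_set.name,
        members_total=len(gene_set),
        members_detectable=n,
        fraction_up_r1=float(np.mean(v1 > 1)),
        fraction_down_r1=float(np.mean(v1 < 1)),
        fraction_reversed_by_treatment=float(np.mean(reversed_mask)),
        selected_divergent_genes=tuple(shortlist),
        divergence_thresholds_log2=(min_abs_log2_r1, min_abs_log2_rT),
    )
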