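"""Classification thresholds.

All fold-change thresholds used anywhere in the pipeline live in one
validated object so that every report can echo exactly the values it was
produced with.  Ratios are linear-scale unless a field name says log2.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .exceptions import ConfigError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (conventional reporting rounding).

    Python's built-in ``round`` uses banker's rounding; report percentages
    follow the everyday half-up convention instead.
    """
    factor = 10.0 ** ndigits
    rounded = math.floor(abs(x) * factor + 0.5) / factor
    rounded = math.copysign(rounded, x)
    return rounded if ndigits > 0 else float(int(rounded))


@dataclass(frozen=True)
class ClassificationConfig:
    """Every threshold the classifiers use.

    Parameters
    ----------
    ns_lower, ns_upper
        Bounds (linear ratio, inclusive) of the treated-vs-perturbed
        "not significant" band.  Defaults 0.67 and 1.50.
    down_stratum_max_ratio
        A gene is in the down stratum when its perturbed-vs-baseline ratio
        is strictly below this (default 0.50: down-regulated by more than
        50%).
    up_stratum_min_ratio
        A gene is in the up stratum when its perturbed-vs-baseline ratio is
        strictly above this (default 2.00: up-regulated by more than 100%).
    n_bins, bin_range_log2
        Equal-width log2 binning of the perturbed-vs-baseline ratio:
        ``n_bins`` bins over ``[-bin_range_log2, +bin_range_log2)``, with
        the outer bins absorbing out-of-range values.
    min_tpm, min_conditions
        Detectability rule: a gene is detectable when its TPM is at least
        ``min_tpm`` in at least ``min_conditions`` conditions.
    pseudocount
        TPM added symmetrically to numerator and denominator of every
        expression ratio.
    endpoint_change_min_log2
        Minimum |log2| baseline-to-endpoint change for a perturbation
        response to count as addressing a real endpoint change (below it
        the response is "un_necessary").
    overshoot_margin_log2
        How far |log2 perturbation change| must exceed |log2 endpoint
        change| before a same-direction response is called
        "over_regulated".
    responsive_fold_threshold
        Linear fold threshold (strict, both directions) selecting the
        responsive genes fed to the trajectory classifier.
    """

    ns_lower: float = 0.67
    ns_upper: float = 1.50
    down_stratum_max_ratio: float = 0.50
    up_stratum_min_ratio: float = 2.00
    n_bins: int = 14
    bin_range_log2: float = 3.5
    min_tpm: float = 1.0
    min_conditions: int = 1
    pseudocount: float = 1.0
    endpoint_change_min_log2: float = 1.0
    overshoot_margin_log2: float = 1.0
    responsive_fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.ns_lower < 1 < self.ns_upper):
            raise ConfigError(
                f"need ns_lower < 1 < ns_upper, got {self.ns_lower}, {self.ns_upper}"
            )
        if not (0 < self.down_stratum_max_ratio < 1 < self.up_stratum_min_ratio):
            raise ConfigError(
                "need down_stratum_max_ratio < 1 < up_stratum_min_ratio, got "
                f"{self.down_stratum_max_ratio}, {self.up_stratum_min_ratio}"
            )
        if self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bin_range_log2 <= 0:
            raise ConfigError("bin_range_log2 must be positive")
        if self.min_tpm < 0:
            raise ConfigError("min_tpm must be non-negative")
        if self.min_conditions < 1:
            raise ConfigError("min_conditions must be a positive integer")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be non-negative")
        if self.endpoint_change_min_log2 <= 0 or self.overshoot_margin_log2 <= 0:
            raise ConfigError("log2 margins must be positive")
        if self.responsive_fold_threshold <= 1:
            raise ConfigError("responsive_fold_threshold must exceed 1")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
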