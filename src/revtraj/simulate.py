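"""Synthetic TPM matrices with ground truth.

The generator emulates the statistical structure the analyses assume:

* log-normal baseline TPM across genes;
* a perturbation that shifts a configurable fraction of genes up or down
  by log-normal-magnitude log2 effects, with the direction coupled to
  baseline expression rank (negative coupling: highly expressed genes
  tend to go down, lowly expressed ones up);
* a treatment that undoes a configurable share (``reversal_strength``) of
  the perturbation effect for a random ``reversal_fraction`` of perturbed
  genes;
* optional endpoint / pre-endpoint columns whose per-gene relationship to
  the perturbation effect is drawn from programmed trajectory categories
  (attractor mode) or independently;
* optional time-course columns in which transient (opposite and
  un-necessary) effects rise to a programmed peak time point and then
  fade, while consistent and over-regulated effects persist;
* independent multiplicative log-normal measurement noise on every cell.

Everything is deterministic given the seed, and the returned
:class:`SyntheticTruth` records which genes were perturbed/reversed and
with what effects, so recovery by the classifiers is testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, GeneMismatchError
from .expression_io import ExpressionMatrix
from .reversal import ResponseLabel

CONDITION_BASELINE = "baseline"
CONDITION_PERTURBED = "perturbed"
CONDITION_TREATED = "treated"
CONDITION_ENDPOINT = "endpoint"
CONDITION_PRE_ENDPOINT = "pre_endpoint"

# Endpoint-category mix among perturbed genes in attractor mode: roughly a
# third of induced changes point where the endpoint goes, over half are
# transient or misdirected, a small tail overshoots.
ENDPOINT_CATEGORY_PROBS = {
    "consistent": 0.34,
    "opposite": 0.28,
    "un_necessary": 0.28,
    "over_regulated": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator.

    Effects are log2-scale magnitudes (sign supplied by the sampled
    direction).  ``baseline_coupling`` in [-1, 1] couples perturbation
    direction to baseline rank: -1 pushes highly expressed genes down and
    lowly expressed genes up as strongly as the logistic link allows, 0 is
    no coupling.  ``endpoint_mode`` is "attractor" (endpoint effects drawn
    per programmed trajectory category), "independent" (endpoint effects
    unrelated to the perturbation), or None (no endpoint columns).
    ``timepoints`` adds one perturbed column per label; ``timecourse_peak``
    is the index at which transient effects peak (default: middle).
    """

    n_genes: int = 2000
    seed: int = 0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    frac_perturbed_down: float = 0.12
    frac_perturbed_up: float = 0.12
    effect_log2_mean: float = 2.5
    effect_log2_sd: float = 0.3
    baseline_coupling: float = -0.8
    reversal_fraction: float = 0.5
    reversal_strength: float = 1.0
    noise_log2_sd: float = 0.2
    endpoint_mode: Optional[str] = "attractor"
    pre_endpoint_log2_sd: float = 0.5
    timepoints: Optional[tuple[str, ...]] = None
    timecourse_peak: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError(f"n_genes must be >= 10, got {self.n_genes}")
        for name in ("frac_perturbed_down", "frac_perturbed_up", "reversal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_perturbed_down + self.frac_perturbed_up > 1:
            raise ConfigError("perturbed fractions must sum to <= 1")
        if not 0 < self.reversal_strength <= 1:
            raise ConfigError("reversal_strength must be in (0, 1]")
        if not -1 <= self.baseline_coupling <= 1:
            raise ConfigError("baseline_coupling must be in [-1, 1]")
        if self.effect_log2_mean <= 0 or self.effect_log2_sd <= 0:
            raise ConfigError("effect_log2_mean and effect_log2_sd must be positive")
        if self.noise_log2_sd < 0:
            raise ConfigError("noise_log2_sd must be non-negative")
        if self.endpoint_mode not in (None, "attractor", "independent"):
            raise ConfigError(f"unknown endpoint_mode {self.endpoint_mode!r}")
        if self.timepoints is not None:
            object.__setattr__(self, "timepoints", tuple(self.timepoints))
            if len(self.timepoints) < 1:
                raise ConfigError("timepoints must be a non-empty sequence")
            peak = self.timecourse_peak
            if peak is None:
                object.__setattr__(self, "timecourse_peak", len(self.timepoints) // 2)
            elif not 0 <= peak < len(self.timepoints):
                raise ConfigError("timecourse_peak out of range")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["timepoints"] is not None:
            d["timepoints"] = list(d["timepoints"])
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated matrix (arrays in gene order)."""

    gene_ids: tuple[str, ...]
    perturbed: np.ndarray  # bool
    direction: np.ndarray  # -1 / 0 / +1
    effect_log2: np.ndarray  # signed; 0 for unperturbed genes
    reversed_flag: np.ndarray  # bool, only set on perturbed genes
    endpoint_log2: np.ndarray  # signed endpoint effect; 0 without endpoint
    endpoint_category: tuple[Optional[str], ...]  # attractor mode only
    config: GeneratorConfig

    def as_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "perturbed": self.perturbed.astype(bool).tolist(),
            "direction": self.direction.astype(int).tolist(),
            "effect_log2": self.effect_log2.tolist(),
            "reversed_flag": self.reversed_flag.astype(bool).tolist(),
            "endpoint_log2": self.endpoint_log2.tolist(),
            "endpoint_category": list(self.endpoint_category),
            "config": self.config.as_dict(),
        }


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: GeneratorConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one matrix plus its ground truth, deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = tuple(f"g{i:05d}" for i in range(n))

    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    # which genes are perturbed, and in which direction
    frac_total = config.frac_perturbed_down + config.frac_perturbed_up
    n_perturbed = int(round(frac_total * n))
    perturbed_idx = rng.choice(n, size=n_perturbed, replace=False)
    perturbed = np.zeros(n, dtype=bool)
    perturbed[perturbed_idx] = True

    direction = np.zeros(n, dtype=int)
    if n_perturbed:
        p_down_base = (
            config.frac_perturbed_down / frac_total if frac_total > 0 else 0.5
        )
        # logistic link: rank percentile u in [0,1]; negative coupling makes
        # p(down) increase with u (highly expressed genes tend down)
        u = (np.argsort(np.argsort(baseline_log2)) / max(n - 1, 1))[perturbed_idx]
        logit0 = np.log(p_down_base / (1 - p_down_base)) if 0 < p_down_base < 1 else (
            np.inf if p_down_base >= 1 else -np.inf
        )
        slope = 4.0  # internal link steepness; recorded via the config echo
        p_down = _logistic(logit0 + slope * (-config.baseline_coupling) * (2 * u - 1))
        down = rng.random(n_perturbed) < p_down
        direction[perturbed_idx] = np.where(down, -1, 1)

    magnitude = np.abs(rng.normal(config.effect_log2_mean, config.effect_log2_sd, n))
    effect_log2 = direction * magnitude

    reversed_flag = np.zeros(n, dtype=bool)
    if n_perturbed:
        reversed_flag[perturbed_idx] = (
            rng.random(n_perturbed) < config.reversal_fraction
        )

    cols: dict[str, np.ndarray] = {}
    cols[CONDITION_BASELINE] = baseline_log2
    cols[CONDITION_PERTURBED] = baseline_log2 + effect_log2
    cols[CONDITION_TREATED] = (
        baseline_log2
        + effect_log2
        - reversed_flag * config.reversal_strength * effect_log2
    )

    endpoint_log2 = np.zeros(n)
    endpoint_category: list[Optional[str]] = [None] * n
    if config.endpoint_mode == "attractor":
        cats = list(ENDPOINT_CATEGORY_PROBS)
        probs = np.array([ENDPOINT_CATEGORY_PROBS[c] for c in cats])
        drawn = rng.choice(len(cats), size=n_perturbed, p=probs / probs.sum())
        for j, idx in enumerate(perturbed_idx):
            cat = cats[drawn[j]]
            endpoint_category[idx] = cat
            e1 = effect_log2[idx]
            if cat == "consistent":
                endpoint_log2[idx] = e1
            elif cat == "opposite":
                endpoint_log2[idx] = -e1
            elif cat == "un_necessary":
                endpoint_log2[idx] = 0.0
            else:  # over_regulated: same direction, smaller than e1 by a clear margin
                endpoint_log2[idx] = np.sign(e1) * max(1.25, abs(e1) - 1.25)
    elif config.endpoint_mode == "independent":
        n_moved = int(round(frac_total * n))
        moved = rng.choice(n, size=n_moved, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_moved)
        endpoint_log2[moved] = signs * np.abs(
            rng.normal(config.effect_log2_mean, config.effect_log2_sd, n_moved)
        )

    if config.endpoint_mode is not None:
        cols[CONDITION_ENDPOINT] = baseline_log2 + endpoint_log2
        cols[CONDITION_PRE_ENDPOINT] = cols[CONDITION_ENDPOINT] + rng.normal(
            0.0, config.pre_endpoint_log2_sd, n
        )

    if config.timepoints is not None:
        for t, label in enumerate(config.timepoints):
            weight = _timecourse_weights(
                t, len(config.timepoints), config.timecourse_peak, endpoint_category
            )
            cols[f"perturbed_{label}"] = baseline_log2 + weight * effect_log2

    noisy = {
        name: 2.0
        ** (values + rng.normal(0.0, config.noise_log2_sd, n))
        for name, values in cols.items()
    }
    matrix = ExpressionMatrix(pd.DataFrame(noisy, index=list(gene_ids)))
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        perturbed=perturbed,
        direction=direction,
        effect_log2=effect_log2,
        reversed_flag=reversed_flag,
        endpoint_log2=endpoint_log2,
        endpoint_category=tuple(endpoint_category),
        config=config,
    )
    return matrix, truth


def _timecourse_weights(
    t: int, n_times: int, peak: int, endpoint_category: Sequence[Optional[str]]
) -> np.ndarray:
    """Per-gene effect amplitude at time index ``t``.

    Transient effects (opposite and un-necessary categories) ramp linearly
    from 0.4 to 1.0 at the peak index and fall to 0.1 by the last time
    point; persistent effects (consistent, over_regulated, and any gene
    without a category) hold amplitude 1.0 throughout, so the unfavorable
    share of responsive genes peaks exactly when the transient amplitude
    does.
    """
    if t <= peak:
        transient = 0.4 + 0.6 * (t / peak if peak > 0 else 1.0)
    else:
        tail = n_times - 1 - peak
        transient = 1.0 - 0.9 * ((t - peak) / tail if tail > 0 else 1.0)
    weights = np.ones(len(endpoint_category))
    is_transient = np.array(
        [c in ("opposite", "un_necessary") for c in endpoint_category]
    )
    weights[is_transient] = transient
    return weights


def truth_confusion(
    labels: Sequence[ResponseLabel], truth: SyntheticTruth
) -> dict:
    """Confusion of the truth reversed flag against pipeline interpretations.

    Restricted to truth-perturbed genes.  Rows: truth reversed yes/no;
    columns: the three in-stratum interpretations (reversed, consistent,
    unaffected).  Perturbed genes whose measured r1 fell outside both
    strata (interpretation not_applicable) are excluded from the table and
    counted separately.  Sensitivity and specificity of the "reversed"
    label are derived from the table.
    """
    if labels and tuple(l.gene_id for l in labels) != truth.gene_ids:
        raise GeneMismatchError("labels and truth cover different genes")
    table = {
        row: {col: 0 for col in ("reversed", "consistent", "unaffected")}
        for row in ("truth_reversed", "truth_not_reversed")
    }
    excluded = 0
    for i, label in enumerate(labels):
        if not truth.perturbed[i]:
            continue
        if label.interpretation == "not_applicable":
            excluded += 1
            continue
        row = "truth_reversed" if truth.reversed_flag[i] else "truth_not_reversed"
        table[row][label.interpretation] += 1
    pos = table["truth_reversed"]
    neg = table["truth_not_reversed"]
    n_pos = sum(pos.values())
    n_neg = sum(neg.values())
    sensitivity = pos["reversed"] / n_pos if n_pos else None
    specificity = (
        (neg["consistent"] + neg["unaffected"]) / n_neg if n_neg else None
    )
    return {
        "table": table,
        "excluded_not_applicable": excluded,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }
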