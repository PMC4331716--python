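"""Synthetic staged-expression benchmark with nine monotonicity archetypes.

The default dataset holds 120 genes over 50 samples in 5 equal stages:
10 genes each of ``good_distinct``, ``good_close``, ``outliers_slight``,
``outliers_severe``, ``partial_close`` and ``partial_far``, and 20 each of
``slightly``, ``moderately`` and ``severely``.  Stage means step up (or
down) by ``base_step`` and the within-stage spread grows from the Good
archetypes through Slightly/Moderately/Severely, producing increasing
inter-stage overlap.  Outlier archetypes displace at most ``floor(0.06 *
S)`` samples away from an otherwise clean trend; Partially-ordered
archetypes move one whole stage's mean out of monotone order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ASCENDING,
    DESCENDING,
    ExpressionMatrix,
    StageDesign,
    canonicalize_design,
    normalize_direction,
)

#: The nine archetypes, strongest to weakest monotonicity (with the two
#: special families at the end of each group).
ARCHETYPES = (
    "good_distinct",
    "good_close",
    "slightly",
    "outliers_slight",
    "outliers_severe",
    "moderately",
    "severely",
    "partial_far",
    "partial_close",
)

_OUTLIER_ARCHETYPES = ("outliers_slight", "outliers_severe")
_PARTIAL_ARCHETYPES = ("partial_far", "partial_close")

#: Gene-id order and per-archetype counts of the default 120-gene dataset.
DATASET_LAYOUT = (
    ("good_distinct", 10),
    ("good_close", 10),
    ("slightly", 20),
    ("outliers_slight", 10),
    ("outliers_severe", 10),
    ("moderately", 20),
    ("severely", 20),
    ("partial_close", 10),
    ("partial_far", 10),
)

#: Fraction of samples an outliers-type gene may displace.
OUTLIER_BUDGET_FRACTION = 0.06


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable shape parameters of the archetype generator.

    ``sd_fraction``, ``outlier_shift_*`` and ``partial_shift_*`` are all
    expressed as multiples of ``base_step``.
    """

    base_step: float = 2.0
    sd_fraction: Mapping[str, float] = field(
        default_factory=lambda: {
            "good_distinct": 0.15,
            "good_close": 0.28,
            "slightly": 0.35,
            "outliers_slight": 0.15,
            "outliers_severe": 0.15,
            "moderately": 0.95,
            "severely": 1.45,
            "partial_far": 0.15,
            "partial_close": 0.15,
        }
    )
    outlier_shift_slight: float = 1.5
    outlier_shift_severe: float = 4.0
    partial_shift_close: float = 0.7
    partial_shift_far: float = 3.0


DEFAULT_CONFIG = GeneratorConfig()


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Fully resolved recipe for one synthetic gene."""

    archetype: str
    direction: str
    stage_sizes: tuple
    base_step: float
    within_sd: float
    outlier_indices: tuple | None = None  # 0-based sample positions
    outlier_shift: float = 0.0  # multiples of base_step
    displaced_stage: int | None = None  # 1-based stage index
    partial_shift: float = 0.0  # multiples of base_step
    seed: object = None

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        object.__setattr__(self, "direction", normalize_direction(self.direction))
        object.__setattr__(self, "stage_sizes", tuple(int(x) for x in self.stage_sizes))
        if any(x < 1 for x in self.stage_sizes) or len(self.stage_sizes) < 2:
            raise ValueError(f"invalid stage sizes {self.stage_sizes}")
        if self.base_step == 0:
            raise ValueError("base_step must be non-zero; a flat profile realises no archetype")
        total = sum(self.stage_sizes)
        if self.archetype in _OUTLIER_ARCHETYPES:
            if not self.outlier_indices:
                raise ValueError(f"{self.archetype} requires outlier positions")
            idx = tuple(int(i) for i in self.outlier_indices)
            if len(set(idx)) != len(idx) or any(not 0 <= i < total for i in idx):
                raise ValueError(f"invalid outlier positions {idx}")
            budget = math.floor(OUTLIER_BUDGET_FRACTION * total)
            if len(idx) > budget:
                raise ValueError(
                    f"{len(idx)} outliers exceed the budget of {budget} "
                    f"(<= {OUTLIER_BUDGET_FRACTION:.0%} of {total} samples)"
                )
            object.__setattr__(self, "outlier_indices", idx)
        elif self.outlier_indices:
            raise ValueError(f"outlier positions only apply to outliers archetypes")
        if self.archetype in _PARTIAL_ARCHETYPES:
            if self.displaced_stage is None:
                raise ValueError(f"{self.archetype} requires a displaced stage")
            if not 1 <= self.displaced_stage <= len(self.stage_sizes):
                raise ValueError(f"displaced stage {self.displaced_stage} out of range")
        elif self.displaced_stage is not None:
            raise ValueError("displaced stage only applies to partial archetypes")

    @property
    def n_samples(self) -> int:
        return sum(self.stage_sizes)


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    design: StageDesign
    truth: Mapping  # gene_id -> archetype


def make_gene_spec(
    archetype: str,
    direction: str,
    stage_sizes: Sequence,
    rng: np.random.Generator,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> SyntheticGeneSpec:
    """Draw the random placement choices (outliers / displaced stage) for a gene."""
    stage_sizes = tuple(int(x) for x in stage_sizes)
    total = sum(stage_sizes)
    outlier_indices = None
    outlier_shift = 0.0
    displaced_stage = None
    partial_shift = 0.0
    if archetype in _OUTLIER_ARCHETYPES:
        budget = math.floor(OUTLIER_BUDGET_FRACTION * total)
        if budget < 1:
            raise ValueError(
                f"too few samples ({total}) for an outliers archetype: budget is 0"
            )
        count = int(rng.integers(1, budget + 1))
        outlier_indices = tuple(sorted(rng.choice(total, size=count, replace=False)))
        outlier_shift = (
            config.outlier_shift_slight
            if archetype == "outliers_slight"
            else config.outlier_shift_severe
        )
    elif archetype in _PARTIAL_ARCHETYPES:
        displaced_stage = int(rng.integers(1, len(stage_sizes) + 1))
        partial_shift = (
            config.partial_shift_close
            if archetype == "partial_close"
            else config.partial_shift_far
        )
    return SyntheticGeneSpec(
        archetype=archetype,
        direction=direction,
        stage_sizes=stage_sizes,
        base_step=config.base_step,
        within_sd=config.sd_fraction[archetype] * abs(config.base_step),
        outlier_indices=outlier_indices,
        outlier_shift=outlier_shift,
        displaced_stage=displaced_stage,
        partial_shift=partial_shift,
    )


def _stage_means(spec: SyntheticGeneSpec) -> np.ndarray:
    """Per-stage target means, monotone except for a displaced partial stage."""
    n = len(spec.stage_sizes)
    step = abs(spec.base_step)
    means = step * np.arange(1, n + 1, dtype=float)
    if spec.displaced_stage is not None:
        d = spec.displaced_stage
        shift = spec.partial_shift * step
        if d < n:
            # push the stage just past its successor, breaking the order
            means[d - 1] = means[d] + shift
        else:
            means[d - 1] = means[d - 2] - shift
    if spec.direction == DESCENDING:
        means = means[::-1]
    return means


def make_gene(spec: SyntheticGeneSpec, rng: np.random.Generator) -> np.ndarray:
    """Realise one gene: length-S values in stage-major sample order."""
    means = _stage_means(spec)
    values = np.concatenate(
        [
            rng.normal(means[i], spec.within_sd, size=size)
            for i, size in enumerate(spec.stage_sizes)
        ]
    )
    if spec.outlier_indices:
        step = abs(spec.base_step)
        for i in spec.outlier_indices:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[i] += sign * spec.outlier_shift * step
    return values


def make_dataset(
    direction: str = ASCENDING,
    seed=None,
    stage_sizes: Sequence = (10, 10, 10, 10, 10),
    config: GeneratorConfig = DEFAULT_CONFIG,
    layout: Sequence = DATASET_LAYOUT,
) -> SyntheticDataset:
    """Generate the 120-gene benchmark (or a variant) reproducibly from a seed."""
    direction = normalize_direction(direction)
    rng = np.random.default_rng(seed)
    stage_sizes = tuple(int(x) for x in stage_sizes)
    total = sum(stage_sizes)

    rows, gene_ids, truth = [], [], {}
    gene_no = 0
    for archetype, count in layout:
        for _ in range(count):
            gene_no += 1
            gene_id = f"g{gene_no}"
            spec = make_gene_spec(archetype, direction, stage_sizes, rng, config)
            rows.append(make_gene(spec, rng))
            gene_ids.append(gene_id)
            truth[gene_id] = archetype

    sample_ids = tuple(f"s{i + 1:02d}" for i in range(total))
    stage_labels = tuple(f"Stage{i + 1}" for i in range(len(stage_sizes)))
    assignment = {}
    k = 0
    for label, size in zip(stage_labels, stage_sizes):
        for _ in range(size):
            assignment[sample_ids[k]] = label
            k += 1
    design = canonicalize_design(assignment, stage_labels, sample_ids)
    matrix = ExpressionMatrix(tuple(gene_ids), sample_ids, np.vstack(rows))
    return SyntheticDataset(matrix=matrix, design=design, truth=truth)
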