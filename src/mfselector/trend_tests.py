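"""Weighted-rank (Wilcoxon-type) test for trend across ordered stages.

Each sample carries the weight of its stage (1..N for ascending trends,
N..1 for descending) and the statistic is the weighted sum of the sample's
midranks.  Its permutation mean and variance have closed forms, giving a
z-score and a one-sided normal p-value.  Ties receive midranks; the
variance uses the no-ties formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ASCENDING, DESCENDING, StageDesign, normalize_direction


@dataclass(frozen=True)
class CuzickResult:
    T: float
    expect_t: float
    var_t: float
    z: float
    p_one_sided: float

    @property
    def p_two_sided(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def cuzick_weights(direction: str, n_stages: int) -> np.ndarray:
    """Stage weights: ``1..N`` for ascending, ``N..1`` for descending."""
    if n_stages < 2:
        raise ValueError(f"need at least 2 stages, got {n_stages}")
    w = np.arange(1, n_stages + 1, dtype=float)
    return w if normalize_direction(direction) == ASCENDING else w[::-1]


def cuzick(
    values,
    design: StageDesign,
    direction: str = ASCENDING,
    sample_ids=None,
) -> CuzickResult:
    """Weighted-rank trend statistic for one gene.

    ``values`` follow the design's canonical order unless ``sample_ids``
    states their actual order.  The one-sided p-value is the upper normal
    tail in the trend direction.
    """
    direction = normalize_direction(direction)
    values = np.asarray(values, dtype=float)
    if sample_ids is not None:
        pos = {s: i for i, s in enumerate(sample_ids)}
        values = values[[pos[s] for s in design.canonical_order]]
    n = design.n_samples
    if values.shape != (n,):
        raise ValueError(f"expected {n} values, got shape {values.shape}")
    if design.n_stages < 2:
        raise ValueError("trend test needs at least two stages")

    w = cuzick_weights(direction, design.n_stages)
    stage_idx = design.canonical_stage_indices()  # 1-based
    z_i = w[stage_idx - 1]
    ranks = stats.rankdata(values)  # midranks for ties
    t = float(np.sum(z_i * ranks))

    sizes = np.bincount(stage_idx, minlength=design.n_stages + 1)[1:]
    p_j = sizes / n
    mean_w = float(np.sum(w * p_j))
    expect_t = n * (n + 1) / 2.0 * mean_w
    var_t = n * n * (n + 1) / 12.0 * (float(np.sum(w * w * p_j)) - mean_w**2)
    if var_t <= 0:
        raise ValueError("degenerate design: trend variance is not positive")
    z = (t - expect_t) / np.sqrt(var_t)
    return CuzickResult(
        T=t,
        expect_t=float(expect_t),
        var_t=float(var_t),
        z=float(z),
        p_one_sided=float(stats.norm.sf(z)),
    )
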