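"""Permutation significance, noise-perturbation stability and final ranking.

The permutation null is pooled: the stage labels are permuted ``B`` times,
the same permuted labels are applied to every gene, and both ascending and
descending totals are recomputed each time.  p- and q-values are plain
counting ratios over that pool (granularity ``1 / (G * B)``; no pseudocount
is added, so a reported 0 only means "below resolution").

SVDE (sample variance for discriminating error) breaks ties between genes
with equal ``de_total``: each gene is perturbed ``M`` times with i.i.d.
Gaussian noise of standard deviation ``sd(gene) / 10``, the scan is re-run
from scratch, and the mean squared deviation of the perturbed totals from
the original total is reported.  Smaller SVDE = sturdier monotonicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ASCENDING,
    DESCENDING,
    ExpressionMatrix,
    MonotoneScore,
    StageDesign,
    _scan_batch,
    canonicalize_design,
    normalize_direction,
)

#: Defaults used throughout: permutations, noise replicates, filters.
DEFAULT_B = 500
DEFAULT_M = 100
DEFAULT_DE_MAX = 7
DEFAULT_P_MAX = 1e-5


class DegenerateGeneError(ValueError):
    """Raised when a zero-variance gene is given to a perturbation routine."""


@dataclass(frozen=True)
class NullPool:
    """Null ``de_total`` values from B whole-label permutations."""

    gene_ids: tuple
    B: int
    seed: object
    ascending: np.ndarray  # (G, B) int
    descending: np.ndarray  # (G, B) int

    def pooled(self, direction: str) -> np.ndarray:
        direction = normalize_direction(direction)
        arr = self.ascending if direction == ASCENDING else self.descending
        return arr.ravel()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SignificanceResult:
    gene_id: object
    direction: str
    observed: int
    p: float
    q: float


@dataclass(frozen=True)
class SVDEResult:
    gene_id: object
    direction: str
    de_org: int
    perturbed: tuple
    svde: float
    noise_sd: float
    M: int
    seed: object


def _canonical_matrix(matrix: ExpressionMatrix, design: StageDesign) -> np.ndarray:
    if set(matrix.sample_ids) != set(design.canonical_order):
        raise ValueError("matrix and design sample ids do not match")
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    return matrix.values[:, [pos[s] for s in design.canonical_order]]


def build_null_pool(
    matrix: ExpressionMatrix,
    design: StageDesign,
    B: int = DEFAULT_B,
    seed=None,
) -> NullPool:
    """Permute the stage labels ``B`` times and rescore every gene.

    One permutation of the label vector is drawn per round and shared by all
    genes and both directions, so ascending and descending nulls stay coupled.
    Stage sizes are preserved (the label multiset is shuffled).
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    labels = [design.assignment[s] for s in matrix.sample_ids]
    asc = np.empty((matrix.n_genes, B), dtype=np.int64)
    desc = np.empty((matrix.n_genes, B), dtype=np.int64)
    for b in range(B):
        perm = rng.permutation(len(labels))
        permuted = {s: labels[perm[i]] for i, s in enumerate(matrix.sample_ids)}
        pdesign = canonicalize_design(permuted, design.stage_labels, matrix.sample_ids)
        canon = _canonical_matrix(matrix, pdesign)
        stage_idx = pdesign.canonical_stage_indices()
        asc[:, b], _, _ = _scan_batch(canon, stage_idx)
        desc[:, b], _, _ = _scan_batch(-canon, stage_idx)
    return NullPool(
        gene_ids=matrix.gene_ids, B=B, seed=seed, ascending=asc, descending=desc
    )


def p_value(observed: int, pool: NullPool, direction: str) -> float:
    """Pooled permutation p-value: fraction of null totals <= observed."""
    pooled = pool.pooled(direction)
    p = np.count_nonzero(pooled <= observed) / pooled.size
    if p == 0.0:
        warnings.warn(
            f"p-value below the pool resolution 1/{pooled.size}; reported as 0",
            stacklevel=2,
        )
    return float(p)


def p_values(observed: Sequence, pool: NullPool, direction: str) -> np.ndarray:
    """Vectorised :func:`p_value` without the resolution warning."""
    pooled = np.sort(pool.pooled(direction))
    obs = np.asarray(observed)
    return np.searchsorted(pooled, obs, side="right") / pooled.size


def q_values(observed_all: Sequence, pool: NullPool, direction: str) -> np.ndarray:
    """Pooled permutation q-values, capped at 1.

    For each gene the numerator is the pooled-null count ``<= observed`` and
    the denominator is ``B`` times the number of genes whose observed total
    is ``<= observed``.
    """
    obs = np.asarray(observed_all)
    if obs.shape != (pool.n_genes,):
        raise ValueError(
            f"need one observed value per pooled gene ({pool.n_genes}), got {obs.shape}"
        )
    pooled = np.sort(pool.pooled(direction))
    num = np.searchsorted(pooled, obs, side="right")
    obs_sorted = np.sort(obs)
    den = np.searchsorted(obs_sorted, obs, side="right") * pool.B
    return np.minimum(num / den, 1.0)


def significance_table(
    scores: Sequence[MonotoneScore],
    pool: NullPool,
    direction: str,
) -> list:
    """p and q for a full direction's scores (order preserved)."""
    direction = normalize_direction(direction)
    scores = [s for s in scores if s.direction == direction]
    if tuple(s.gene_id for s in scores) != pool.gene_ids:
        raise ValueError("scores and null pool cover different genes")
    obs = np.array([s.de_total for s in scores])
    p = p_values(obs, pool, direction)
    q = q_values(obs, pool, direction)
    return [
        SignificanceResult(s.gene_id, direction, s.de_total, float(p[i]), float(q[i]))
        for i, s in enumerate(scores)
    ]


def svde(
    values,
    design: StageDesign,
    direction: str = ASCENDING,
    M: int = DEFAULT_M,
    seed=None,
    gene_id="gene",
    sample_ids=None,
) -> SVDEResult:
    """Noise-perturbation stability of one gene's ``de_total``.

    ``M`` replicates add i.i.d. normal noise (sd = gene sd / 10, sample
    standard deviation) to every sample and re-run the full scan with fresh
    masks; the result is the mean squared deviation of the perturbed totals
    from the unperturbed total.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    direction = normalize_direction(direction)
    values = np.asarray(values, dtype=float)
    if sample_ids is not None:
        pos = {s: i for i, s in enumerate(sample_ids)}
        values = values[[pos[s] for s in design.canonical_order]]
    if values.shape != (design.n_samples,):
        raise ValueError(f"expected {design.n_samples} values, got {values.shape}")
    sigma = float(np.std(values, ddof=1))
    if sigma == 0.0:
        raise DegenerateGeneError(
            f"gene {gene_id!r} has zero variance; SVDE is undefined"
        )
    noise_sd = sigma / 10.0
    stage_idx = design.canonical_stage_indices()
    sign = -1.0 if direction == DESCENDING else 1.0
    de_org, _, _ = _scan_batch(sign * values[None, :], stage_idx)
    de_org = int(de_org[0])
    rng = np.random.default_rng(seed)
    noisy = values[None, :] + rng.normal(0.0, noise_sd, size=(M, values.size))
    de_i, _, _ = _scan_batch(sign * noisy, stage_idx)
    return SVDEResult(
        gene_id=gene_id,
        direction=direction,
        de_org=de_org,
        perturbed=tuple(int(x) for x in de_i),
        svde=float(np.mean((de_i - de_org) ** 2)),
        noise_sd=noise_sd,
        M=M,
        seed=seed,
    )


def svde_matrix(
    matrix: ExpressionMatrix,
    design: StageDesign,
    direction: str = ASCENDING,
    M: int = DEFAULT_M,
    seed=None,
    gene_ids: Sequence | None = None,
) -> dict:
    """SVDE for many genes; skips degenerate genes.

    Each gene gets its own RNG stream keyed by ``(seed, row index)`` so the
    result for a gene does not depend on which other genes are requested.
    Returns ``{gene_id: SVDEResult}``.
    """
    direction = normalize_direction(direction)
    wanted = set(matrix.gene_ids if gene_ids is None else gene_ids)
    out = {}
    for row, gene in enumerate(matrix.gene_ids):
        if gene not in wanted:
            continue
        values = matrix.values[row]
        if np.ptp(values) == 0:
            continue
        out[gene] = svde(
            values,
            design,
            direction,
            M=M,
            seed=np.random.SeedSequence([_seed_int(seed), row]),
            gene_id=gene,
            sample_ids=matrix.sample_ids,
        )
    return out


def _seed_int(seed) -> int:
    if seed is None:
        return int(np.random.SeedSequence().entropy) % (2**32)
    return int(seed)


def rank_and_filter(
    scores: Sequence[MonotoneScore],
    significance: Mapping,
    svde_results: Mapping | None,
    de_max: int | None = DEFAULT_DE_MAX,
    p_max: float | None = DEFAULT_P_MAX,
    require_distinct: bool = True,
    n_stages: int | None = None,
) -> list:
    """Filter and order one direction's scores.

    Degenerate genes are dropped; then ``de_total <= de_max``,
    ``p < p_max`` and (optionally) ``distinct_lines == N - 1`` are applied;
    survivors are sorted by ``(de_total, svde, input order)``.  ``de_max`` or
    ``p_max`` may be ``None`` to disable that filter.  A missing SVDE is
    reported as ``None`` and sorts after computed ones within its
    ``de_total`` block.

    Returns a list of plain dicts ready for serialisation, with dense ranks.
    """
    directions = {s.direction for s in scores}
    if len(directions) > 1:
        raise ValueError("rank_and_filter takes scores of a single direction")

    def svde_of(gene):
        if svde_results is None or gene not in svde_results:
            return None
        res = svde_results[gene]
        return res.svde if isinstance(res, SVDEResult) else float(res)

    retained = []
    for idx, s in enumerate(scores):
        if s.degenerate:
            continue
        if de_max is not None and s.de_total > de_max:
            continue
        sig = significance.get(s.gene_id) if significance is not None else None
        p = sig.p if isinstance(sig, SignificanceResult) else sig
        if p_max is not None:
            if p is None:
                raise ValueError(f"no p-value supplied for gene {s.gene_id!r}")
            if not p < p_max:
                continue
        if require_distinct and n_stages is not None and s.distinct_lines != n_stages - 1:
            continue
        q = sig.q if isinstance(sig, SignificanceResult) else None
        retained.append((idx, s, p, q, svde_of(s.gene_id)))

    retained.sort(
        key=lambda t: (t[1].de_total, t[4] is None, t[4] if t[4] is not None else 0.0, t[0])
    )
    records = []
    for rank, (idx, s, p, q, sv) in enumerate(retained, start=1):
        records.append(
            {
                "rank": rank,
                "gene_id": s.gene_id,
                "direction": s.direction,
                "de_total": s.de_total,
                "level_errors": s.level_errors,
                "distinct_lines": s.distinct_lines,
                "p": p,
                "q": q,
                "svde": sv,
                "degenerate": s.degenerate,
            }
        )
    return records
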