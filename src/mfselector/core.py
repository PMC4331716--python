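"""Level-wise discriminating-error scan for monotonic expression profiles.

A gene measured over ``N`` ordered stages is scanned with ``N - 1`` *level*
processes.  At level ``k`` the union of stages ``1..k`` (the *lower group*)
is separated from the remaining stages by a horizontal *discriminating line*
drawn at the expression value of one lower-group sample.  Samples on the
wrong side of the line are *discriminating errors*; the line with the fewest
errors is selected, its error samples are masked for all later levels (each
sample is charged at most once), and the per-level error counts are summed
into the total discriminating error ``de_total``.  Small ``de_total`` means a
strongly monotonic gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

ASCENDING = "ascending"
DESCENDING = "descending"
DIRECTIONS = (ASCENDING, DESCENDING)

_DIRECTION_ALIASES = {
    "asc": ASCENDING,
    "ascending": ASCENDING,
    "desc": DESCENDING,
    "descending": DESCENDING,
}


def normalize_direction(direction: str) -> str:
    """Map ``asc``/``desc`` abbreviations onto the canonical direction names."""
    try:
        return _DIRECTION_ALIASES[str(direction).lower()]
    except KeyError:
        raise ValueError(
            f"direction must be one of {sorted(set(_DIRECTION_ALIASES))}, got {direction!r}"
        ) from None


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples table of (log-scale) expression intensities.

    Parameters
    ----------
    gene_ids
        Unique gene/probe identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Real-valued ``(G, S)`` array; missing values are rejected.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        g, s = values.shape
        if g < 1:
            raise ValueError("expression matrix needs at least one gene")
        if s < 2:
            raise ValueError("expression matrix needs at least two samples")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.sample_ids) != s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {s} columns")
        if len(set(self.gene_ids)) != g:
            dupes = sorted({x for x in self.gene_ids if self.gene_ids.count(x) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != s:
            dupes = sorted({x for x in self.sample_ids if self.sample_ids.count(x) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene_id) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages with a canonical, stage-major sample numbering.

    ``canonical_order`` lists every sample stage-by-stage (stage one first),
    preserving the input order within each stage; ``sample_number`` maps each
    sample onto its 1-based position in that order.
    """

    stage_labels: tuple
    assignment: Mapping
    canonical_order: tuple
    sample_number: Mapping

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def n_samples(self) -> int:
        return len(self.canonical_order)

    def stage_index(self, sample) -> int:
        """1-based stage position of a sample."""
        return self.stage_labels.index(self.assignment[sample]) + 1

    def canonical_stage_indices(self) -> np.ndarray:
        """1-based stage index of every sample, in canonical order."""
        lookup = {label: i + 1 for i, label in enumerate(self.stage_labels)}
        return np.array([lookup[self.assignment[s]] for s in self.canonical_order])

    def stage_samples(self, label) -> tuple:
        return tuple(s for s in self.canonical_order if self.assignment[s] == label)

    def stage_sizes(self) -> tuple:
        sizes = {label: 0 for label in self.stage_labels}
        for s in self.canonical_order:
            sizes[self.assignment[s]] += 1
        return tuple(sizes[label] for label in self.stage_labels)


@dataclass(frozen=True)
class LevelScan:
    """Outcome of one level process: the candidate sweep and the chosen line."""

    level: int
    candidate_samples: tuple
    candidate_errors: tuple
    selected_sample: object
    selected_error: int
    new_error_samples: frozenset


@dataclass(frozen=True)
class MonotoneScore:
    """Per-gene, per-direction total discriminating error and its breakdown."""

    gene_id: object
    direction: str
    de_total: int
    level_errors: tuple
    line_samples: tuple
    distinct_lines: int
    degenerate: bool = False


def canonicalize_design(
    assignment: Mapping,
    stage_order: Sequence,
    sample_order: Sequence,
) -> StageDesign:
    """Build a :class:`StageDesign` with stage-major canonical numbering.

    Samples are numbered 1..S stage by stage, following ``stage_order``;
    within a stage the relative order of ``sample_order`` is preserved.
    """
    sample_order = list(sample_order)
    if len(set(sample_order)) != len(sample_order):
        dupes = sorted({s for s in sample_order if sample_order.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    stage_order = tuple(stage_order)
    if len(set(stage_order)) != len(stage_order):
        raise ValueError(f"duplicate stage labels in stage order: {stage_order}")
    if len(stage_order) < 2:
        raise ValueError("need at least two stages")
    missing = [s for s in sample_order if s not in assignment]
    if missing:
        raise ValueError(f"samples missing from stage assignment: {missing}")
    unknown = sorted({assignment[s] for s in sample_order} - set(stage_order))
    if unknown:
        raise ValueError(f"stage labels absent from the stage order: {unknown}")

    canonical = [
        s for label in stage_order for s in sample_order if assignment[s] == label
    ]
    empty = [label for label in stage_order if not any(assignment[s] == label for s in sample_order)]
    if empty:
        raise ValueError(f"empty stages: {empty}")
    numbering = {s: i + 1 for i, s in enumerate(canonical)}
    return StageDesign(
        stage_labels=stage_order,
        assignment={s: assignment[s] for s in sample_order},
        canonical_order=tuple(canonical),
        sample_number=numbering,
    )


def _canonical_values(values, design: StageDesign, sample_ids=None) -> np.ndarray:
    """Reorder a length-S value sequence into canonical sample order."""
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_samples,):
        raise ValueError(
            f"expected {design.n_samples} values, got shape {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression value")
    if sample_ids is None:
        return values
    pos = {s: i for i, s in enumerate(sample_ids)}
    return values[[pos[s] for s in design.canonical_order]]


def candidate_errors(
    values,
    design: StageDesign,
    level: int,
    direction: str = ASCENDING,
    masked: Iterable = (),
    sample_ids=None,
) -> list:
    """Enumerate the per-candidate discriminating errors at one level.

    ``values`` are taken in canonical sample order unless ``sample_ids``
    gives their actual order.  Every lower-group sample (stages ``1..level``)
    is a candidate, masked or not; masked samples are simply never counted as
    errors.  For an ascending profile the error count of a candidate line at
    value ``v`` is the number of unmasked lower-group samples strictly above
    ``v`` plus the number of unmasked upper-group samples strictly below
    ``v``; descending reverses the inequalities.  Values exactly on the line
    contribute no error.

    Returns a list of ``(sample_id, error_count)`` in canonical order.
    """
    direction = normalize_direction(direction)
    n = design.n_stages
    if not 1 <= level <= n - 1:
        raise ValueError(f"level must be in 1..{n - 1}, got {level}")
    v = _canonical_values(values, design, sample_ids)
    if direction == DESCENDING:
        v = -v
    stage_idx = design.canonical_stage_indices()
    lower = stage_idx <= level
    masked = set(masked)
    ok = np.array([s not in masked for s in design.canonical_order])
    cand_pos = np.flatnonzero(lower)
    out = []
    for pos in cand_pos:
        line = v[pos]
        err = int(np.count_nonzero((v > line) & lower & ok)
                  + np.count_nonzero((v < line) & ~lower & ok))
        out.append((design.canonical_order[pos], err))
    return out


def select_line(candidates: Sequence, design: StageDesign):
    """Pick the discriminating line among ``(sample, stage, error)`` triples.

    The minimum error wins; among tied minimizers the highest stage has
    priority, and within that stage the lowest canonical sample number.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate lines to select from")
    stage_rank = {label: i for i, label in enumerate(design.stage_labels)}

    def key(item):
        sample, stage, err = item
        return (err, -stage_rank[stage], design.sample_number[sample])

    sample, _, err = min(candidates, key=key)
    return sample, int(err)


def scan_levels(
    values,
    design: StageDesign,
    direction: str = ASCENDING,
    sample_ids=None,
) -> list:
    """Run all ``N - 1`` level processes for one gene, carrying the mask.

    After each level, the samples on the wrong side of the *selected* line
    are added to the mask so they are never counted again.  Returns one
    :class:`LevelScan` per level.
    """
    direction = normalize_direction(direction)
    v = _canonical_values(values, design, sample_ids)
    sv = -v if direction == DESCENDING else v
    stage_idx = design.canonical_stage_indices()
    order = design.canonical_order
    masked: set = set()
    scans = []
    for level in range(1, design.n_stages):
        cand = candidate_errors(v, design, level, direction, masked)
        triples = [(s, design.assignment[s], e) for s, e in cand]
        sel_sample, sel_err = select_line(triples, design)
        line = sv[order.index(sel_sample)]
        lower = stage_idx <= level
        new_err = frozenset(
            order[i]
            for i in range(len(order))
            if order[i] not in masked
            and ((lower[i] and sv[i] > line) or (not lower[i] and sv[i] < line))
        )
        masked |= new_err
        scans.append(
            LevelScan(
                level=level,
                candidate_samples=tuple(s for s, _ in cand),
                candidate_errors=tuple(e for _, e in cand),
                selected_sample=sel_sample,
                selected_error=sel_err,
                new_error_samples=new_err,
            )
        )
    return scans


def scan_gene(
    values,
    design: StageDesign,
    direction: str = ASCENDING,
    gene_id="gene",
    sample_ids=None,
) -> MonotoneScore:
    """Score one gene in one direction; see the module docstring."""
    v = _canonical_values(values, design, sample_ids)
    scans = scan_levels(v, design, direction)
    lines = tuple(s.selected_sample for s in scans)
    return MonotoneScore(
        gene_id=gene_id,
        direction=normalize_direction(direction),
        de_total=int(sum(s.selected_error for s in scans)),
        level_errors=tuple(s.selected_error for s in scans),
        line_samples=lines,
        distinct_lines=len(set(lines)),
        degenerate=bool(np.ptp(v) == 0),
    )


def _scan_batch(values: np.ndarray, stage_idx: np.ndarray):
    """Vectorised ascending scan of many genes at once.

    Parameters
    ----------
    values
        ``(G, S)`` array in canonical sample order (negate for descending).
    stage_idx
        ``(S,)`` 1-based stage index per canonical sample.

    Returns ``(de_total, level_errors, line_positions)`` where
    ``line_positions`` holds 0-based canonical positions of the selected
    line samples, shape ``(G, N - 1)``.
    """
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    n = int(stage_idx.max())
    masked = np.zeros((g, s), dtype=bool)
    level_errors = np.zeros((g, n - 1), dtype=np.int64)
    line_pos = np.zeros((g, n - 1), dtype=np.int64)
    rows = np.arange(g)
    numbers = np.arange(1, s + 1)
    for level in range(1, n):
        lower = stage_idx <= level
        cand = np.flatnonzero(lower)
        cand_vals = values[:, cand]                       # (G, C)
        ok = ~masked                                      # (G, S)
        gt = values[:, None, :] > cand_vals[:, :, None]   # (G, C, S)
        lt = values[:, None, :] < cand_vals[:, :, None]
        err = (
            (gt & (lower & np.ones(s, bool))[None, None, :] & ok[:, None, :]).sum(axis=2)
            + (lt & (~lower)[None, None, :] & ok[:, None, :]).sum(axis=2)
        )
        # lexicographic tie-break (min error, max stage, min sample number)
        # folded into one integer key
        key = (
            err * ((n + 1) * (s + 1))
            + ((n - stage_idx[cand]) * (s + 1))[None, :]
            + numbers[cand][None, :]
        )
        sel = np.argmin(key, axis=1)
        sel_pos = cand[sel]
        sel_err = err[rows, sel]
        line = values[rows, sel_pos][:, None]
        wrong = ((values > line) & lower[None, :]) | ((values < line) & ~lower[None, :])
        masked |= wrong & ok
        level_errors[:, level - 1] = sel_err
        line_pos[:, level - 1] = sel_pos
    return level_errors.sum(axis=1), level_errors, line_pos


def score_matrix(
    matrix: ExpressionMatrix,
    design: StageDesign,
    directions: Sequence = DIRECTIONS,
) -> list:
    """Score every gene of ``matrix`` in each requested direction.

    Returns a flat list of :class:`MonotoneScore`, gene order preserved
    within each direction (all requested directions for gene 1, etc. are
    grouped per direction: ascending scores first, then descending).
    """
    if set(matrix.sample_ids) != set(design.canonical_order):
        raise ValueError("matrix and design sample ids do not match")
    directions = [normalize_direction(d) for d in directions]
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    reorder = [pos[s] for s in design.canonical_order]
    canon = matrix.values[:, reorder]
    stage_idx = design.canonical_stage_indices()
    degenerate = np.ptp(canon, axis=1) == 0
    out = []
    for direction in directions:
        v = -canon if direction == DESCENDING else canon
        _, level_errors, line_pos = _scan_batch(v, stage_idx)
        for i, gene in enumerate(matrix.gene_ids):
            lines = tuple(design.canonical_order[p] for p in line_pos[i])
            out.append(
                MonotoneScore(
                    gene_id=gene,
                    direction=direction,
                    de_total=int(level_errors[i].sum()),
                    level_errors=tuple(int(e) for e in level_errors[i]),
                    line_samples=lines,
                    distinct_lines=len(set(lines)),
                    degenerate=bool(degenerate[i]),
                )
            )
    return out
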