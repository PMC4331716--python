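"""End-to-end scoring pipeline shared by the CLI and library users."""

from __future__ import annotations

from typing import Sequence

from .core import ExpressionMatrix, StageDesign, normalize_direction, score_matrix
from .significance import (
    DEFAULT_B,
    DEFAULT_DE_MAX,
    DEFAULT_M,
    DEFAULT_P_MAX,
    build_null_pool,
    rank_and_filter,
    significance_table,
    svde_matrix,
)


def score_pipeline(
    matrix: ExpressionMatrix,
    design: StageDesign,
    directions: Sequence = ("ascending", "descending"),
    B: int = DEFAULT_B,
    M: int = DEFAULT_M,
    de_max: int | None = DEFAULT_DE_MAX,
    p_max: float | None = DEFAULT_P_MAX,
    require_distinct: bool = True,
    seed=None,
) -> list:
    """Score, test, perturb and rank; returns ranked records of all directions.

    One null pool (seeded) is shared by both directions, as is the SVDE
    noise scheme.  SVDE is computed only for genes that survive the filters,
    since it only has to order the retained list.
    """
    directions = [normalize_direction(d) for d in directions]
    scores = score_matrix(matrix, design, directions)
    pool = build_null_pool(matrix, design, B=B, seed=seed)
    records = []
    for direction in directions:
        dir_scores = [s for s in scores if s.direction == direction]
        sig = {r.gene_id: r for r in significance_table(dir_scores, pool, direction)}
        survivors = [
            s.gene_id
            for s in dir_scores
            if not s.degenerate
            and (de_max is None or s.de_total <= de_max)
            and (p_max is None or sig[s.gene_id].p < p_max)
            and (not require_distinct or s.distinct_lines == design.n_stages - 1)
        ]
        svde_map = svde_matrix(
            matrix, design, direction, M=M, seed=seed, gene_ids=survivors
        )
        records.extend(
            rank_and_filter(
                dir_scores,
                sig,
                svde_map,
                de_max=de_max,
                p_max=p_max,
                require_distinct=require_distinct,
                n_stages=design.n_stages,
            )
        )
    return records
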