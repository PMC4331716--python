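"""Small built-in example profiles used in docs, tests and the report script."""

from __future__ import annotations

import numpy as np

from .core import StageDesign, canonicalize_design

#: Stage sizes of the five-stage demo profile.
DEMO_STAGE_SIZES = (3, 3, 6, 4, 4)

# Canonical-order values of a hand-built 20-sample, five-stage profile with
# one high outlier in stage one (sample 1) and one low outlier in stage four
# (sample 13).  Its ascending scan selects lines at samples 2, 4, 10 and 16
# with level errors (2, 0, 1, 0), i.e. de_total = 3, and the level-wise
# candidate sweeps enumerate to (7, 2, 2), (3, 3, 4, 0, 2, 1) and
# (3, 9, 10, 6, 8, 7, 2, 4, 5, 1, 3, 1).
_DEMO_VALUES = np.array([
    4.0, 1.6, 1.0,                 # stage 1 (sample 1 is a high outlier)
    2.6, 2.0, 2.3,                 # stage 2
    4.4, 3.3, 3.0, 4.8, 3.6, 5.6,  # stage 3
    1.3, 5.2, 6.0, 6.4,            # stage 4 (sample 13 is a low outlier)
    7.0, 7.3, 7.6, 7.9,            # stage 5
])


def five_stage_demo() -> tuple[np.ndarray, StageDesign]:
    """Return ``(values, design)`` for the 20-sample five-stage demo gene.

    Sample ids are the canonical numbers 1..20 and stage labels are
    ``"Stage1"``..``"Stage5"`` with sizes ``(3, 3, 6, 4, 4)``.
    """
    labels = [
        f"Stage{i + 1}" for i, size in enumerate(DEMO_STAGE_SIZES) for _ in range(size)
    ]
    samples = list(range(1, len(labels) + 1))
    design = canonicalize_design(
        assignment=dict(zip(samples, labels)),
        stage_order=tuple(f"Stage{i + 1}" for i in range(len(DEMO_STAGE_SIZES))),
        sample_order=samples,
    )
    return _DEMO_VALUES.copy(), design
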