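"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain Python loops over
samples, recomputed from the written definitions, so they can serve as
oracles for the vectorised implementations.
"""

from __future__ import annotations

from itertools import combinations


def brute_candidate_errors(values, stages, level, direction, masked):
    """Per-candidate error counts at one level by direct double loop.

    ``values`` and ``stages`` are parallel lists in canonical order
    (stages 1-based); ``masked`` is a set of canonical positions.
    Returns a list of (position, error) for every lower-group sample.
    """
    s = len(values)
    out = []
    for c in range(s):
        if stages[c] > level:
            continue
        line = values[c]
        err = 0
        for i in range(s):
            if i in masked:
                continue
            if stages[i] <= level:  # lower group: wrong side depends on direction
                if direction == "ascending" and values[i] > line:
                    err += 1
                if direction == "descending" and values[i] < line:
                    err += 1
            else:
                if direction == "ascending" and values[i] < line:
                    err += 1
                if direction == "descending" and values[i] > line:
                    err += 1
        out.append((c, err))
    return out


def brute_scan(values, stages, direction="ascending"):
    """Full scan: returns (de_total, level_errors, line_positions).

    Re-states the whole procedure: per level enumerate candidates, count
    errors ignoring previously charged samples, pick the minimum (ties:
    highest stage, then lowest position), charge that line's wrong-side
    samples, and sum the selected errors.
    """
    s = len(values)
    n = max(stages)
    masked = set()
    level_errors = []
    line_positions = []
    for level in range(1, n):
        cand = brute_candidate_errors(values, stages, level, direction, masked)
        best = None
        for c, err in cand:
            key = (err, -stages[c], c)
            if best is None or key < best[0]:
                best = (key, c, err)
        _, sel, err = best
        line = values[sel]
        for i in range(s):
            if i in masked:
                continue
            wrong = False
            if stages[i] <= level:
                wrong = (values[i] > line) if direction == "ascending" else (values[i] < line)
            else:
                wrong = (values[i] < line) if direction == "ascending" else (values[i] > line)
            if wrong:
                masked.add(i)
        level_errors.append(err)
        line_positions.append(sel)
    return sum(level_errors), level_errors, line_positions


def brute_trend_moments(values, sizes, weights):
    """Exhaustive permutation mean/variance of the weighted rank-sum.

    Enumerates every assignment of samples to the two-or-more stages given
    by ``sizes`` and recomputes T = sum(weight * rank) each time.  Only
    distinct values (no ties) are expected.
    """
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    rank = [0] * n
    for r, i in enumerate(order, start=1):
        rank[i] = r

    def enumerate_assignments(remaining, sizes):
        if not sizes:
            yield []
            return
        for group in combinations(remaining, sizes[0]):
            rest = [x for x in remaining if x not in group]
            for tail in enumerate_assignments(rest, sizes[1:]):
                yield [set(group)] + tail

    ts = []
    for groups in enumerate_assignments(list(range(n)), list(sizes)):
        t = 0.0
        for stage, members in enumerate(groups):
            for i in members:
                t += weights[stage] * rank[i]
        ts.append(t)
    mean = sum(ts) / len(ts)
    var = sum((t - mean) ** 2 for t in ts) / len(ts)
    return mean, var, ts
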