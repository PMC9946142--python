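"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule in the most literal way possible
(exhaustive scans, exact rational arithmetic) and share no code with the
package internals they test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, isnan


def brute_force_blocks(
    deviations: list[float],
    threshold: float = 0.7,
    merge_gap_windows: int = 5,
    min_fraction: float = 0.8,
) -> list[tuple[int, int]]:
    """Literal run/merge/fraction enumeration over unit-width windows.

    Returns half-open window-index intervals of kept blocks.  NaN windows
    never satisfy the predicate and do not count as constituents.
    """
    below = [
        (d is not None) and (not isnan(d)) and d < threshold for d in deviations
    ]
    # maximal runs
    runs = []
    for i, b in enumerate(below):
        if b and (i == 0 or not below[i - 1]):
            j = i
            while j < len(below) and below[j]:
                j += 1
            runs.append([i, j])
    # merge until stable
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            if runs[k + 1][0] - runs[k][1] <= merge_gap_windows:
                runs[k][1] = runs[k + 1][1]
                del runs[k + 1]
                changed = True
                break
    # fraction rule over constituent (defined) windows
    kept = []
    for i, j in runs:
        n_const = sum(
            1 for k in range(i, j)
            if deviations[k] is not None and not isnan(deviations[k])
        )
        n_below = sum(1 for k in range(i, j) if below[k])
        if n_const and n_below / n_const >= min_fraction:
            kept.append((i, j))
    return kept


def exact_fisher_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher p by exhaustive table enumeration with exact
    rational hypergeometric probabilities."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def pmf(x: int) -> Fraction:
        if x < 0 or x > c1 or r1 - x < 0 or r1 - x > n - c1:
            return Fraction(0)
        return Fraction(comb(c1, x) * comb(n - c1, r1 - x), comb(n, r1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = pmf(x)
        # standard relative slack for the "no more probable" tie rule
        if p <= p_obs or float(p / p_obs) <= 1 + 1e-7:
            total += p
    return float(min(total, Fraction(1)))


def brute_force_rbh(
    hits_ab: list[tuple],
    hits_ba: list[tuple],
    qlen_a: dict[str, int],
    qlen_b: dict[str, int],
    min_identity: float = 90.0,
    min_query_coverage: float = 0.8,
) -> set[tuple[str, str]]:
    """All-pairs mutual-best search over hit tuples
    (query, subject, pident, length, evalue, bitscore)."""

    def best(hits, qlen):
        filtered = [
            h for h in hits
            if h[2] >= min_identity and h[3] >= min_query_coverage * qlen[h[0]]
        ]
        out = {}
        for h in filtered:
            q = h[0]
            cur = out.get(q)
            key = (-h[5], h[4], h[1])  # -bitscore, evalue, subject id
            if cur is None or key < cur[0]:
                out[q] = (key, h[1])
        return {q: s for q, (_, s) in out.items()}

    ab = best(hits_ab, qlen_a)
    ba = best(hits_ba, qlen_b)
    return {(q, s) for q, s in ab.items() if ba.get(s) == q}
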