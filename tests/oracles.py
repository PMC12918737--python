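"""Independent reference implementations used to check the package.

Everything here is deliberately naive — exhaustive recursion over
alignment paths, explicit pairwise graphs, per-base bitmaps — and shares
no code with the implementations under test.
"""

from functools import lru_cache


def make_local_oracle(match: int, mismatch: int, gap_open: int,
                      gap_extend: int):
    """Best affine-gap local alignment score by enumeration.

    The best score over every pair of substrings, each scored by
    recursive enumeration of global alignment paths (memoised on the
    remaining suffixes and the previous operation).
    """
    go = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def global_score(a: str, b: str, prev: str) -> int:
        if not a and not b:
            return 0
        best = -(1 << 30)
        if a and b:
            s = match if a[0] == b[0] else mismatch
            best = max(best, s + global_score(a[1:], b[1:], "D"))
        if a:
            cost = gap_extend if prev == "U" else go
            best = max(best, -cost + global_score(a[1:], b, "U"))
        if b:
            cost = gap_extend if prev == "L" else go
            best = max(best, -cost + global_score(a, b[1:], "L"))
        return best

    def local_best(a: str, b: str) -> int:
        best = 0
        for i in range(len(a)):
            for j in range(i + 1, len(a) + 1):
                for p in range(len(b)):
                    for q in range(p + 1, len(b) + 1):
                        best = max(best,
                                   global_score(a[i:j], b[p:q], "D"))
        return best

    return local_best


def interval_components(intervals, max_gap):
    """Connected components of the interval-proximity graph, brute force.

    ``intervals`` is a list of (start, end); two intervals are adjacent
    when the gap between them (0 if they overlap) is <= max_gap.
    Returns a list of frozensets of indices.
    """
    n = len(intervals)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack = [i]
        comp = set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def coverage_bitmap(intervals, length):
    """Fraction of [0, length) covered by a union of half-open intervals,
    computed with an explicit per-base bitmap."""
    hit = bytearray(length)
    for s, e in intervals:
        for i in range(max(s, 0), min(e, length)):
            hit[i] = 1
    return sum(hit) / length


def mutual_argmax_pairs(bits, ident):
    """Reciprocal pairs of a score matrix by explicit row/column argmax.

    Tie-break: higher identity, then smaller index; a residual tie makes
    the top hit ambiguous and the pair non-reciprocal.
    """
    n_a = len(bits)
    n_b = len(bits[0]) if n_a else 0

    def top(values, idents):
        ranked = sorted(range(len(values)),
                        key=lambda k: (-values[k], -idents[k], k))
        best = ranked[0]
        ambiguous = (len(ranked) > 1
                     and values[ranked[1]] == values[best]
                     and idents[ranked[1]] == idents[best])
        return best, ambiguous

    pairs = set()
    for i in range(n_a):
        j, amb_a = top(bits[i], ident[i])
        i_back, amb_b = top([bits[r][j] for r in range(n_a)],
                            [ident[r][j] for r in range(n_a)])
        if not amb_a and not amb_b and i_back == i:
            pairs.add((i, j))
    return pairs
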