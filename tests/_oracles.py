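"""Independent brute-force reference implementations and random fixture
generators used to cross-check the library's structure operations."""

from __future__ import annotations

import random


def parse_pairs(dot_bracket: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    assert not stack
    return pairs


def brute_terminal_loops(dot_bracket: str) -> int:
    """Hairpin loops = pairs enclosing no other paired position."""
    pairs = parse_pairs(dot_bracket)
    count = 0
    for i, j in pairs.items():
        if i < j and all(k not in pairs for k in range(i + 1, j)):
            count += 1
    return count


def brute_longest_duplex(dot_bracket: str, max_interruptions: int = 2) -> int:
    """Exhaustive scan over all runs [a, b]: ends paired, one bracket
    direction, partners monotonically decreasing, and (unpaired positions
    + partner-side gaps) <= max_interruptions."""
    pairs = parse_pairs(dot_bracket)
    n = len(dot_bracket)
    best = 0
    for a in range(n):
        if a not in pairs:
            continue
        for b in range(a, n):
            if b not in pairs:
                continue
            run = range(a, b + 1)
            paired = [q for q in run if q in pairs]
            if any(dot_bracket[q] != dot_bracket[a] for q in paired):
                continue
            partners = [pairs[q] for q in paired]
            if any(x <= y for x, y in zip(partners, partners[1:])):
                continue
            defects = sum(1 for q in run if q not in pairs)
            defects += sum(x - y - 1 for x, y in zip(partners, partners[1:]))
            if defects <= max_interruptions:
                best = max(best, b - a + 1)
    return best


def random_dot_bracket(length: int, rng: random.Random,
                       min_loop: int = 3) -> str:
    """Uniform-ish random balanced nested structure of exactly ``length``."""

    def gen(n: int) -> str:
        if n == 0:
            return ""
        if n >= min_loop + 2 and rng.random() < 0.6:
            inner = rng.randint(min_loop, n - 2)
            rest = n - 2 - inner
            left = "(" + gen(inner) + ")"
            return left + gen(rest) if rng.random() < 0.5 else gen(rest) + left
        return "." + gen(n - 1)

    return gen(length)


def brute_coverage_islands(reads) -> list[tuple[int, int, int]]:
    """Per-base scan: maximal nonzero-coverage intervals with summed
    multiplicity of overlapping reads, as (start, end, count)."""
    if not reads:
        return []
    hi = max(r.end for r in reads)
    cov = [0] * (hi + 1)
    for r in reads:
        for x in range(r.start, r.end):
            cov[x] += r.multiplicity
    islands = []
    x = 0
    while x <= hi:
        if cov[x] > 0:
            y = x
            while y <= hi and cov[y] > 0:
                y += 1
            count = sum(r.multiplicity for r in reads
                        if r.start < y and r.end > x)
            islands.append((x, y, count))
            x = y
        else:
            x += 1
    return islands


def perfect_partner(arm: int, loop: int) -> list[int]:
    """Pair table of a perfect stem-loop: i <-> n-1-i over both arms."""
    n = 2 * arm + loop
    partner = [-1] * n
    for i in range(arm):
        partner[i] = n - 1 - i
        partner[n - 1 - i] = i
    return partner
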