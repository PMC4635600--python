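"""Stage 2b: empirical structure significance by mono-nucleotide shuffling.

For each candidate precursor a per-sequence null distribution of MFE/nt
is built by folding uniform random permutations of the sequence
(Fisher-Yates; composition preserved exactly). The p-value is the
empirical probability mass at or below the observed MFE/nt, with an
add-one pseudocount so p is never exactly zero:

    p = (1 + #{null <= observed}) / (n + 1)

A di-nucleotide (Eulerian-path) shuffle is available behind a flag; for
sequences in the relevant length range it yields indistinguishable null
distributions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .fold import FoldBackend, FoldError


class SignificanceError(RuntimeError):
    pass


@dataclass
class NullDistribution:
    values: list[float]          # MFE/nt of each shuffled fold
    source_length: int
    source_composition: dict[str, int]


@dataclass
class SignificanceResult:
    p_value: float
    observed_mfe_per_nt: float
    null_mean: float
    null_sd: float


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the characters (mono-nucleotide
    shuffle); composition is conserved exactly."""
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Di-nucleotide-preserving shuffle (random Eulerian path through the
    di-nucleotide multigraph, Altschul-Erickson style)."""
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]
    # pick a random last edge per vertex (except the terminal vertex) that
    # forms a tree toward the terminal vertex; rejection sample
    vertices = list(edges)
    for _ in range(200):
        last_edge = {}
        for v in vertices:
            if v == last and all(t == v for t in edges[v]):
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # check connectivity of last-edge pointers toward `last`
        ok = True
        for v in vertices:
            seen = set()
            cur = v
            while cur != last and cur in last_edge:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok or (cur != last and cur in edges):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return shuffle_sequence(sequence, rng)
    shuffled_edges = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        perm = [pool[i] for i in rng.permutation(len(pool))]
        if v in last_edge:
            perm.append(last_edge[v])
        shuffled_edges[v] = perm
    out = [sequence[0]]
    idx: Counter[str] = Counter()
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = shuffled_edges[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def null_distribution(sequence: str, permutation_count: int,
                      backend: FoldBackend, rng: np.random.Generator,
                      dinucleotide: bool = False) -> NullDistribution:
    """Fold ``permutation_count`` independent shuffles; individual fold
    failures are tolerated up to 10 % of the shuffles."""
    if permutation_count < 1:
        raise ValueError("permutation_count >= 1 required")
    shuffler = dinucleotide_shuffle if dinucleotide else shuffle_sequence
    values: list[float] = []
    errors = 0
    for _ in range(permutation_count):
        shuffled = shuffler(sequence, rng)
        try:
            _, mfe = backend.fold(shuffled)
        except FoldError:
            errors += 1
            continue
        values.append(mfe / len(shuffled))
    if errors > 0.1 * permutation_count:
        raise SignificanceError(
            f"{errors}/{permutation_count} shuffled folds failed")
    return NullDistribution(values=values, source_length=len(sequence),
                            source_composition=dict(Counter(sequence)))


def empirical_p(observed_mfe_per_nt: float,
                null: NullDistribution) -> SignificanceResult:
    """Add-one empirical estimate of P(MFE/nt' <= observed) under the null.

    Ties count as at-or-below (conservative).
    """
    values = np.asarray(null.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    n = values.size
    p = (1 + int((values <= observed_mfe_per_nt).sum())) / (n + 1)
    return SignificanceResult(
        p_value=p,
        observed_mfe_per_nt=observed_mfe_per_nt,
        null_mean=float(values.mean()),
        null_sd=float(values.std(ddof=1)) if n > 1 else 0.0,
    )


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    the pipeline: the method applies a fixed per-candidate threshold)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n, dtype=float)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()
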