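"""RNA secondary-structure folding backends.

Two engines behind one contract:

* :class:`ViennaBackend` -- thermodynamic minimum-free-energy folding via
  the ViennaRNA bindings; additionally exposes a sliding-window local
  scan (``RNA.Lfold``) used by the pipeline to locate locally stable
  hairpins cheaply.
* :class:`MaxPairBackend` -- a bundled base-pair-maximization engine with
  simple stacking bonuses. Its pseudo-energies are NOT thermodynamic and
  are never meaningful against published free-energy thresholds; the
  engine exists so the library and its tests run without the external
  thermodynamics package.

Both return pseudoknot-free dot-bracket strings over "()." and an energy
in kcal/mol (pseudo-kcal/mol for the fallback).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Protocol

import numpy as np

_ALLOWED = set("ACGUTN")
MIN_FOLD_LENGTH = 10


class FoldError(ValueError):
    pass


class LocalHit(NamedTuple):
    """A locally stable structure from a sliding-window scan.

    ``start``/``end`` are 0-based half-open within the scanned sequence.
    """

    start: int
    end: int
    energy: float
    structure: str


class FoldBackend(Protocol):
    name: str
    thermodynamic: bool

    def fold(self, sequence: str) -> tuple[str, float]: ...


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if len(seq) < MIN_FOLD_LENGTH:
        raise FoldError(f"sequence too short to fold ({len(seq)} < "
                        f"{MIN_FOLD_LENGTH} nt)")
    if not set(seq) <= _ALLOWED:
        bad = sorted(set(seq) - _ALLOWED)
        raise FoldError(f"sequence contains non-nucleotide characters {bad}")
    return seq


def _check_structure(structure: str, length: int) -> str:
    if len(structure) != length or not set(structure) <= set("()."):
        raise FoldError("backend returned a non dot-bracket structure "
                        "(pseudoknot annotation is rejected)")
    return structure


class ViennaBackend:
    """Thermodynamic MFE folding (ViennaRNA)."""

    name = "vienna"
    thermodynamic = True

    def __init__(self) -> None:
        import RNA  # deferred: optional at import time
        self._rna = RNA

    def fold(self, sequence: str) -> tuple[str, float]:
        seq = _check_sequence(sequence)
        structure, mfe = self._rna.fold(seq)
        return _check_structure(structure, len(seq)), float(mfe)

    def local_scan(self, sequence: str, window: int | None = None) -> list[LocalHit]:
        """Locally stable structures via RNALfold-style scanning."""
        seq = _check_sequence(sequence)
        span = min(len(seq), window or len(seq))
        hits: list[LocalHit] = []

        def _cb(start: int, end: int, structure: str, energy: float, data) -> None:
            if structure:
                # callback reports 1-based inclusive coordinates
                hits.append(LocalHit(start - 1, end, float(energy), structure))

        self._rna.Lfold_cb(seq, span, _cb, None)
        return hits


# ---------------------------------------------------------------------------
# fallback engine: weighted base-pair maximization with stacking bonuses
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# pair scores: GC=3, AU=2, GU=1, else unpairable
_PAIR_SCORE = np.zeros((5, 5), dtype=np.float32)
for _a, _b, _s in (("G", "C", 3.0), ("A", "U", 2.0), ("G", "U", 1.0)):
    _PAIR_SCORE[_ENC[_a], _ENC[_b]] = _s
    _PAIR_SCORE[_ENC[_b], _ENC[_a]] = _s

_STACK_BONUS = np.float32(1.0)
_MIN_LOOP = 3
_NEG_INF = np.float32(-1e9)
_ENERGY_PER_SCORE = -0.35  # pseudo-kcal/mol per score unit (arbitrary scale)


def _build_kernels():
    from numba import njit

    @njit(cache=False)
    def _tables(enc, pair_score):
        n = enc.shape[0]
        W = np.zeros((n, n), dtype=np.float32)
        V = np.full((n, n), _NEG_INF, dtype=np.float32)
        for span in range(_MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                s = pair_score[enc[i], enc[j]]
                if s > 0.0:
                    inner = W[i + 1, j - 1]
                    if V[i + 1, j - 1] > _NEG_INF / 2:
                        stacked = V[i + 1, j - 1] + _STACK_BONUS
                        if stacked > inner:
                            inner = stacked
                    V[i, j] = s + inner
                best = W[i, j - 1]
                for k in range(i, j - _MIN_LOOP):
                    if V[k, j] > _NEG_INF / 2:
                        left = W[i, k - 1] if k > i else np.float32(0.0)
                        cand = left + V[k, j]
                        if cand > best:
                            best = cand
                W[i, j] = best
        return W, V

    @njit(cache=False)
    def _traceback(enc, pair_score, W, V):
        n = enc.shape[0]
        pairs = np.full(n, -1, dtype=np.int64)
        # stack of (i, j, in_V) triples
        stack_i = np.empty(2 * n + 4, dtype=np.int64)
        stack_j = np.empty(2 * n + 4, dtype=np.int64)
        stack_v = np.empty(2 * n + 4, dtype=np.int64)
        top = 0
        stack_i[top], stack_j[top], stack_v[top] = 0, n - 1, 0
        top += 1
        while top > 0:
            top -= 1
            i, j, in_v = stack_i[top], stack_j[top], stack_v[top]
            if j <= i:
                continue
            if in_v == 1:
                pairs[i] = j
                pairs[j] = i
                s = pair_score[enc[i], enc[j]]
                if (V[i + 1, j - 1] > _NEG_INF / 2
                        and abs(V[i, j] - (s + V[i + 1, j - 1] + _STACK_BONUS)) < 1e-4):
                    stack_i[top], stack_j[top], stack_v[top] = i + 1, j - 1, 1
                    top += 1
                else:
                    stack_i[top], stack_j[top], stack_v[top] = i + 1, j - 1, 0
                    top += 1
                continue
            if abs(W[i, j] - W[i, j - 1]) < 1e-6:
                stack_i[top], stack_j[top], stack_v[top] = i, j - 1, 0
                top += 1
                continue
            done = False
            for k in range(i, j - _MIN_LOOP):
                if V[k, j] > _NEG_INF / 2:
                    left = W[i, k - 1] if k > i else np.float32(0.0)
                    if abs(W[i, j] - (left + V[k, j])) < 1e-4:
                        if k > i:
                            stack_i[top], stack_j[top], stack_v[top] = i, k - 1, 0
                            top += 1
                        stack_i[top], stack_j[top], stack_v[top] = k, j, 1
                        top += 1
                        done = True
                        break
            if not done:
                # numerical fallback: treat j as unpaired
                stack_i[top], stack_j[top], stack_v[top] = i, j - 1, 0
                top += 1
        return pairs

    return _tables, _traceback


class MaxPairBackend:
    """Bundled non-thermodynamic fallback: maximize weighted base pairs
    (GC=3, AU=2, GU=1) with a +1 bonus per stacked pair; energies are
    ``-0.35 x score`` pseudo-kcal/mol."""

    name = "maxpair"
    thermodynamic = False

    _kernels = None

    def __init__(self) -> None:
        if MaxPairBackend._kernels is None:
            MaxPairBackend._kernels = _build_kernels()
        self._tables, self._traceback = MaxPairBackend._kernels

    def fold(self, sequence: str) -> tuple[str, float]:
        seq = _check_sequence(sequence)
        enc = np.array([_ENC[c] for c in seq], dtype=np.int64)
        W, V = self._tables(enc, _PAIR_SCORE)
        score = float(W[0, len(seq) - 1])
        if score <= 0.0:
            return "." * len(seq), 0.0
        pairs = self._traceback(enc, _PAIR_SCORE, W, V)
        structure = "".join(
            "." if p < 0 else ("(" if p > i else ")")
            for i, p in enumerate(pairs))
        return _check_structure(structure, len(seq)), round(
            _ENERGY_PER_SCORE * score, 2)


@dataclass
class _BackendCache:
    vienna: ViennaBackend | None = None
    maxpair: MaxPairBackend | None = None


_CACHE = _BackendCache()


def get_backend(name: str) -> FoldBackend:
    if name == "vienna":
        if _CACHE.vienna is None:
            _CACHE.vienna = ViennaBackend()
        return _CACHE.vienna
    if name == "maxpair":
        if _CACHE.maxpair is None:
            _CACHE.maxpair = MaxPairBackend()
        return _CACHE.maxpair
    raise FoldError(f"unknown fold backend '{name}'")
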