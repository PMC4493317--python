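"""Pairwise lexical dissimilarities between language varieties.

Three measures are provided, all symmetric with zero self-distance:

* ``ldn`` — normalized Levenshtein distance, averaged over shared concepts.
  The per-concept value is edit distance divided by the longer word's
  length, so it lies in [0, 1].  With synonyms, the per-concept distance is
  the minimum over all cross-variety form pairs (synonyms should not
  inflate distance); this follows standard practice for short standardized
  wordlists.
* ``ldnd`` — LDN divided, per variety pair, by the mean LDN over all
  cross-meaning form pairs.  This corrects for chance similarity due to
  shared sound inventories: two varieties whose *unrelated* words already
  look alike are not rewarded for same-meaning resemblance.  Values are
  >= 0 and may exceed 1.
* ``cognate`` — 1 minus the proportion of shared concepts whose
  cognate-class sets intersect; requires cognate coding on both wordlists.

``pairwise_matrix`` computes the full matrix; for the edit-distance
measures the inner loops run through a numba-compiled kernel, which the
pure-Python reference functions (``variety_ldn``, ``ldnd``) are tested
against.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
from numba import njit
from skbio.stats.distance import DistanceMatrix

from .lexical_io import ValidationError, Wordlist

logger = logging.getLogger("galtonlex")

MEASURES = ("ldn", "ldnd", "cognate")


class NoSharedConceptsError(ValueError):
    """Two wordlists have no concept in common."""


class DegenerateNormalizerError(ValueError):
    """The LDND cross-meaning normalizer is zero or undefined."""


class PairwiseDistanceError(ValueError):
    """One or more variety pairs fail the chosen measure's preconditions."""

    def __init__(self, failures: list[tuple[str, str, str]]):
        self.failures = failures
        lines = ", ".join(f"({a}, {b}): {why}" for a, b, why in failures)
        super().__init__(f"{len(failures)} failing pair(s): {lines}")


# ---------------------------------------------------------------------------
# String-level distances
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-symbol edits (ins/del/sub) turning a into b.

    Symbols are Unicode code points; strings should be NFC-normalized
    upstream (Wordlist does this).
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[lb]


def ldn(a: str, b: str) -> float:
    """Levenshtein distance normalized by the longer word's length, in [0,1]."""
    if not a and not b:
        raise ValueError("LDN undefined for two empty strings")
    return levenshtein(a, b) / max(len(a), len(b))


# ---------------------------------------------------------------------------
# Variety-level distances (pure-Python reference implementations)
# ---------------------------------------------------------------------------

def _shared_concepts(w1: Wordlist, w2: Wordlist) -> list[str]:
    shared = sorted(w1.concepts & w2.concepts)
    if not shared:
        raise NoSharedConceptsError(
            f"varieties {w1.variety_id!r} and {w2.variety_id!r} share no concepts"
        )
    return shared


def _concept_ldn(w1: Wordlist, w2: Wordlist, concept: str) -> float:
    return min(ldn(f1, f2) for f1 in w1.forms(concept) for f2 in w2.forms(concept))


def variety_ldn(w1: Wordlist, w2: Wordlist) -> float:
    """Mean per-concept LDN over shared concepts (min over synonym pairs)."""
    shared = _shared_concepts(w1, w2)
    return sum(_concept_ldn(w1, w2, c) for c in shared) / len(shared)


def ldnd(w1: Wordlist, w2: Wordlist) -> float:
    """Variety LDN divided by the mean cross-meaning LDN of this pair.

    The normalizer averages LDN over every form of ``w1`` for concept *i*
    against every form of ``w2`` for concept *j*, for all i != j with both
    concepts shared.
    """
    shared = _shared_concepts(w1, w2)
    numerator = sum(_concept_ldn(w1, w2, c) for c in shared) / len(shared)
    total = 0.0
    count = 0
    for ci in shared:
        for cj in shared:
            if ci == cj:
                continue
            for f1 in w1.forms(ci):
                for f2 in w2.forms(cj):
                    total += ldn(f1, f2)
                    count += 1
    if count == 0:
        raise DegenerateNormalizerError(
            f"no cross-meaning pairs between {w1.variety_id!r} and {w2.variety_id!r}"
        )
    if total == 0.0:
        raise DegenerateNormalizerError(
            f"cross-meaning mean LDN is zero between "
            f"{w1.variety_id!r} and {w2.variety_id!r}"
        )
    return numerator / (total / count)


def cognate_distance(w1: Wordlist, w2: Wordlist) -> float:
    """1 − proportion of shared concepts whose cognate-class sets intersect."""
    for w in (w1, w2):
        if not w.has_cognates:
            raise ValidationError(
                f"variety {w.variety_id!r} carries no cognate coding"
            )
    shared = _shared_concepts(w1, w2)
    hits = sum(
        1 for c in shared if w1.cognate_classes(c) & w2.cognate_classes(c)
    )
    return 1.0 - hits / len(shared)


# ---------------------------------------------------------------------------
# Fast kernel for full LDN/LDND matrices
# ---------------------------------------------------------------------------

@njit(cache=False)
def _lev_arr(a, la, b, lb, prev, cur):  # pragma: no cover - numba
    if la == 0:
        return lb
    if lb == 0:
        return la
    for j in range(lb + 1):
        prev[j] = j
    for i in range(1, la + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = prev[j - 1] + (0 if ai == b[j - 1] else 1)
            d = prev[j] + 1
            e = cur[j - 1] + 1
            m = s
            if d < m:
                m = d
            if e < m:
                m = e
            cur[j] = m
        for j in range(lb + 1):
            prev[j] = cur[j]
    return prev[lb]


@njit(cache=False)
def _pair_stats(fa, la, ca, fb, lb, cb, n_concepts, need_cross):  # pragma: no cover
    """Per-pair (n_shared, mean same-meaning LDN, mean cross-meaning LDN).

    fa/fb: (n_forms, max_len) int32 code points; la/lb lengths; ca/cb
    concept indices.  cross mean is -1.0 when there are no cross pairs.
    """
    in_a = np.zeros(n_concepts, np.bool_)
    in_b = np.zeros(n_concepts, np.bool_)
    for i in range(ca.shape[0]):
        in_a[ca[i]] = True
    for j in range(cb.shape[0]):
        in_b[cb[j]] = True
    shared = np.zeros(n_concepts, np.bool_)
    n_shared = 0
    for c in range(n_concepts):
        if in_a[c] and in_b[c]:
            shared[c] = True
            n_shared += 1
    if n_shared == 0:
        return 0, -1.0, -1.0
    maxlen = fa.shape[1]
    if fb.shape[1] > maxlen:
        maxlen = fb.shape[1]
    prev = np.empty(maxlen + 1, np.int32)
    cur = np.empty(maxlen + 1, np.int32)
    min_ldn = np.full(n_concepts, 2.0)
    cross_sum = 0.0
    cross_n = 0
    for i in range(fa.shape[0]):
        ci = ca[i]
        if not shared[ci]:
            continue
        for j in range(fb.shape[0]):
            cj = cb[j]
            if not shared[cj]:
                continue
            same = ci == cj
            if not same and not need_cross:
                continue
            d = _lev_arr(fa[i], la[i], fb[j], lb[j], prev, cur)
            ml = la[i] if la[i] > lb[j] else lb[j]
            nd = d / ml
            if same:
                if nd < min_ldn[ci]:
                    min_ldn[ci] = nd
            else:
                cross_sum += nd
                cross_n += 1
    s = 0.0
    for c in range(n_concepts):
        if shared[c]:
            s += min_ldn[c]
    ldn_mean = s / n_shared
    cross_mean = cross_sum / cross_n if cross_n > 0 else -1.0
    return n_shared, ldn_mean, cross_mean


def _encode(w: Wordlist, concept_index: dict[str, int]):
    forms: list[str] = []
    concepts: list[int] = []
    for concept in sorted(w.entries):
        for form in w.forms(concept):
            forms.append(form)
            concepts.append(concept_index[concept])
    max_len = max(len(f) for f in forms)
    mat = np.zeros((len(forms), max_len), dtype=np.int32)
    lens = np.zeros(len(forms), dtype=np.int32)
    for i, f in enumerate(forms):
        lens[i] = len(f)
        mat[i, : len(f)] = [ord(ch) for ch in f]
    return mat, lens, np.asarray(concepts, dtype=np.int32)


# ---------------------------------------------------------------------------
# Full matrices
# ---------------------------------------------------------------------------

def pairwise_matrix(
    wordlists: Sequence[Wordlist], measure: str = "ldnd"
) -> DistanceMatrix:
    """Symmetric variety-by-variety distance matrix, labels in input order.

    Any pair failing the measure's preconditions is collected and reported
    in a single aggregate error.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    wordlists = list(wordlists)
    if len(wordlists) < 2:
        raise ValidationError("need at least 2 wordlists")
    ids = [w.variety_id for w in wordlists]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate variety ids")
    n = len(wordlists)
    data = np.zeros((n, n))
    failures: list[tuple[str, str, str]] = []

    if measure == "cognate":
        class_sets = [
            {c: w.cognate_classes(c) for c in w.entries} if w.has_cognates else None
            for w in wordlists
        ]
        for i in range(n):
            if class_sets[i] is None:
                raise ValidationError(
                    f"variety {ids[i]!r} carries no cognate coding"
                )
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = class_sets[i], class_sets[j]
                shared = si.keys() & sj.keys()
                if not shared:
                    failures.append((ids[i], ids[j], "no shared concepts"))
                    continue
                hits = sum(1 for c in shared if si[c] & sj[c])
                data[i, j] = data[j, i] = 1.0 - hits / len(shared)
    else:
        concept_index = {
            c: k
            for k, c in enumerate(
                sorted(set().union(*(w.concepts for w in wordlists)))
            )
        }
        enc = [_encode(w, concept_index) for w in wordlists]
        need_cross = measure == "ldnd"
        n_concepts = len(concept_index)
        for i in range(n):
            fa, la, ca = enc[i]
            for j in range(i + 1, n):
                fb, lb, cb = enc[j]
                n_shared, ldn_mean, cross_mean = _pair_stats(
                    fa, la, ca, fb, lb, cb, n_concepts, need_cross
                )
                if n_shared == 0:
                    failures.append((ids[i], ids[j], "no shared concepts"))
                    continue
                if measure == "ldn":
                    data[i, j] = data[j, i] = ldn_mean
                else:
                    if cross_mean < 0:
                        failures.append(
                            (ids[i], ids[j], "no cross-meaning pairs")
                        )
                    elif cross_mean == 0.0:
                        failures.append(
                            (ids[i], ids[j], "cross-meaning mean LDN is zero")
                        )
                    else:
                        data[i, j] = data[j, i] = ldn_mean / cross_mean
    if failures:
        raise PairwiseDistanceError(failures)
    return DistanceMatrix(data, ids)
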