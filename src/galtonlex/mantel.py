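"""Permutation Mantel test of association between two distance matrices.

The observed statistic is the Pearson correlation over the strictly-upper
triangles.  The null distribution is generated by jointly permuting rows
and columns of the second matrix; the sampled test uses the add-one
(include-identity) correction p = (1 + hits) / (1 + n_perm), so p is never
zero and the test is exactly valid.  For small matrices an exact test over
all n! relabelings is available as an oracle.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix

from .lexical_io import ValidationError

logger = logging.getLogger("galtonlex")

TAILS = ("greater", "less", "two_sided")

#: slack when comparing permuted statistics with the observed one, so that
#: ties are counted even under floating-point noise
_TIE_EPS = 1e-12


class UndefinedCorrelationError(ValueError):
    """One of the condensed distance vectors has zero variance."""


@dataclass(frozen=True)
class MantelResult:
    """Outcome of a Mantel test."""

    r_obs: float
    p_value: float
    n_perm: int
    tail: str
    seed: int | None
    n: int
    method: str = "pearson"

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r_obs <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r_obs} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "r": self.r_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "tail": self.tail,
            "seed": self.seed,
            "n": self.n,
            "method": self.method,
        }


def _check_pair(a: DistanceMatrix, b: DistanceMatrix) -> None:
    if list(a.ids) != list(b.ids):
        raise ValidationError(
            "matrices must have identical labels in identical order; "
            "use aggregation.align_matrices first"
        )
    if a.shape[0] < 3:
        raise ValidationError("need at least 3 labels")


def _condense(m: DistanceMatrix, method: str) -> np.ndarray:
    v = squareform(np.asarray(m.data), checks=False)
    if method == "spearman":
        v = rankdata(v)
    if np.ptp(v) == 0.0:
        raise UndefinedCorrelationError(
            "distance vector is constant; correlation undefined"
        )
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def matrix_correlation(
    a: DistanceMatrix, b: DistanceMatrix, method: str = "pearson"
) -> float:
    """Correlation over the strictly-upper-triangle entries of two matrices."""
    _check_pair(a, b)
    return _pearson(_condense(a, method), _condense(b, method))


def _tail_hits(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    if tail == "greater":
        return int(np.sum(r_perm >= r_obs - _TIE_EPS))
    if tail == "less":
        return int(np.sum(r_perm <= r_obs + _TIE_EPS))
    if tail == "two_sided":
        return int(np.sum(np.abs(r_perm) >= abs(r_obs) - _TIE_EPS))
    raise ValueError(f"unknown tail {tail!r}; choose from {TAILS}")


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 10_000,
    tail: str = "greater",
    seed: int | None = 0,
    method: str = "pearson",
) -> MantelResult:
    """Sampled permutation Mantel test, deterministic given ``seed``.

    Permutations are drawn uniformly with replacement over the permutation
    group; rows and columns of ``b`` are re-indexed by the same
    permutation. p = (1 + hits) / (1 + n_perm).
    """
    _check_pair(a, b)
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}; choose from {TAILS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    av = _condense(a, method)
    bv = _condense(b, method)
    r_obs = _pearson(av, bv)
    n = a.shape[0]
    b_full = squareform(bv)  # ranks already applied for spearman
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    ac = av - av.mean()
    denom_a = math.sqrt(ac @ ac)
    # the condensed multiset is permutation-invariant, so center/scale of b
    # can be precomputed once
    b_mean = bv.mean()
    denom_b = math.sqrt(((bv - b_mean) ** 2).sum())
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        bp = b_full[np.ix_(p, p)][iu]
        r_perm[k] = (ac @ bp) / (denom_a * denom_b)
    hits = _tail_hits(r_perm, r_obs, tail)
    p_value = (1 + hits) / (1 + n_perm)
    return MantelResult(r_obs, p_value, n_perm, tail, seed, n, method)


def mantel_exact(
    a: DistanceMatrix,
    b: DistanceMatrix,
    tail: str = "greater",
    method: str = "pearson",
) -> MantelResult:
    """Exact Mantel test over all n! relabelings (n <= 8).

    The identity permutation is part of the enumeration, so no add-one
    correction is applied: p = hits / n!.
    """
    _check_pair(a, b)
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}; choose from {TAILS}")
    n = a.shape[0]
    if n > 8:
        raise ValidationError(f"exact enumeration refused for n={n} > 8")
    av = _condense(a, method)
    bv = _condense(b, method)
    r_obs = _pearson(av, bv)
    b_full = squareform(bv)
    iu = np.triu_indices(n, k=1)
    ac = av - av.mean()
    denom_a = math.sqrt(ac @ ac)
    denom_b = math.sqrt(((bv - bv.mean()) ** 2).sum())
    r_perm = np.empty(math.factorial(n))
    for k, p in enumerate(itertools.permutations(range(n))):
        idx = np.asarray(p)
        bp = b_full[np.ix_(idx, idx)][iu]
        r_perm[k] = (ac @ bp) / (denom_a * denom_b)
    hits = _tail_hits(r_perm, r_obs, tail)
    p_value = hits / len(r_perm)
    return MantelResult(r_obs, p_value, len(r_perm), tail, None, n, method)
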