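"""Lift variety-level distances to group (province) level; trait differences.

The between-group distance is the arithmetic mean of the variety-level
distances over all cross-group variety pairs; within-group pairs never
enter a between-group average.  Trait differences are absolute differences
of the bounded trait (e.g. proportion of rice-paddy land), so the result
is itself a valid distance matrix.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
from skbio.stats.distance import DistanceMatrix

from .lexical_io import GroupMap, ValidationError

logger = logging.getLogger("galtonlex")


def group_distance_matrix(d: DistanceMatrix, g: GroupMap) -> DistanceMatrix:
    """Average cross-group variety distances into a group-level matrix.

    Groups are ordered by first appearance among ``d.ids``.  Every variety
    in the matrix must be mapped; groups in the map that have no variety in
    the matrix are dropped with a warning.
    """
    unmapped = [v for v in d.ids if v not in g]
    if unmapped:
        raise ValidationError(f"varieties not in group map: {unmapped}")
    groups: list[str] = []
    members: dict[str, list[int]] = {}
    for idx, v in enumerate(d.ids):
        grp = g[v]
        if grp not in members:
            members[grp] = []
            groups.append(grp)
    # second pass keeps member lists in matrix order
    for idx, v in enumerate(d.ids):
        members[g[v]].append(idx)
    empty = sorted(set(g.values()) - set(groups))
    if empty:
        logger.warning("groups with no varieties dropped: %s", empty)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups with varieties")
    k = len(groups)
    data = np.zeros((k, k))
    values = np.asarray(d.data)
    for i in range(k):
        rows = members[groups[i]]
        for j in range(i + 1, k):
            cols = members[groups[j]]
            data[i, j] = data[j, i] = values[np.ix_(rows, cols)].mean()
    return DistanceMatrix(data, groups)


def trait_difference_matrix(
    t: Mapping[str, float], groups: Sequence[str]
) -> DistanceMatrix:
    """|t_P − t_Q| for each group pair, in the given group order."""
    missing = [grp for grp in groups if grp not in t]
    if missing:
        raise ValidationError(f"groups missing from trait table: {missing}")
    x = np.asarray([float(t[grp]) for grp in groups])
    data = np.abs(x[:, None] - x[None, :])
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, list(groups))


def align_matrices(
    a: DistanceMatrix, b: DistanceMatrix
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Restrict both matrices to their shared labels, in ``a``'s order."""
    shared = [lab for lab in a.ids if lab in set(b.ids)]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} shared labels; need >= 3 for a Mantel test"
        )
    dropped = sorted((set(a.ids) | set(b.ids)) - set(shared))
    if dropped:
        logger.warning("labels dropped during alignment: %s", dropped)
    if list(a.ids) == shared and list(b.ids) == shared:
        return a, b
    return a.filter(shared), b.filter(shared)
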