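"""Group-level IBD sharing statistics and empirical p-values.

Averages always use the number of *possible* pairs as the denominator
(within-group: n(n-1)/2; between-group: n_a * n_b), so pairs sharing no
IBD contribute zeros rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from paleoibd.segments import IBDMatrix

#: Value substituted for a zero denominator in sharing ratios (cM).
ZERO_SUBSTITUTE_CM = 0.01


@dataclass(frozen=True)
class GroupPairStat:
    group_a: str
    group_b: str
    mean_cM: float
    n_pairs: int
    total_cM: float


def mean_pair_ibd(
    matrix: IBDMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str] | None = None,
    name_a: str = "A",
    name_b: str = "B",
) -> GroupPairStat:
    """Average total IBD per possible pair, within or between groups.

    With ``group_b`` omitted (or identical to ``group_a``), computes the
    within-group mean over n(n-1)/2 pairs; otherwise the groups must be
    disjoint and the mean runs over n_a * n_b pairs. Zero-sharing pairs
    count in the denominator.
    """
    ids_a = list(group_a)
    if group_b is None or set(group_b) == set(ids_a):
        if len(ids_a) < 2:
            raise ValueError(f"within-group mean needs >= 2 members, got {len(ids_a)}")
        sub = matrix.submatrix(ids_a, ids_a)
        n_pairs = len(ids_a) * (len(ids_a) - 1) // 2
        total = float(sub.sum()) / 2.0
        return GroupPairStat(name_a, name_a, total / n_pairs, n_pairs, total)
    ids_b = list(group_b)
    if not ids_a or not ids_b:
        raise ValueError("groups must be nonempty")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"distinct groups overlap: {sorted(overlap)}")
    sub = matrix.submatrix(ids_a, ids_b)
    n_pairs = len(ids_a) * len(ids_b)
    total = float(sub.sum())
    return GroupPairStat(name_a, name_b, total / n_pairs, n_pairs, total)


def within_between_stat(matrix: IBDMatrix, labels: Mapping[str, str]) -> float:
    """Mean within-group sharing (averaged over the two groups) minus between.

    ``labels`` maps each analyzed individual id to one of exactly two group
    labels; each group needs >= 2 members.
    """
    groups: dict[str, list[str]] = {}
    for iid, lab in labels.items():
        groups.setdefault(lab, []).append(iid)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(groups)}")
    (la, ids_a), (lb, ids_b) = sorted(groups.items())
    for lab, ids in ((la, ids_a), (lb, ids_b)):
        if len(ids) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
    w_a = mean_pair_ibd(matrix, ids_a).mean_cM
    w_b = mean_pair_ibd(matrix, ids_b).mean_cM
    between = mean_pair_ibd(matrix, ids_a, ids_b).mean_cM
    return (w_a + w_b) / 2.0 - between


def continuity_ratio(
    fcsc: float,
    fcso: float,
    fesc: float,
    feso: float,
    zero_sub: float = ZERO_SUBSTITUTE_CM,
) -> float:
    """Normalized sharing contrast ``(FcSc/FcSo) / (FeSc/FeSo)``.

    Values landing in a denominator position (FcSo, FeSo, FeSc) that are
    zero are replaced by ``zero_sub`` before dividing.
    """
    if min(fcsc, fcso, fesc, feso) < 0:
        raise ValueError("sharing means must be >= 0")
    fcso = fcso if fcso > 0 else zero_sub
    feso = feso if feso > 0 else zero_sub
    fesc = fesc if fesc > 0 else zero_sub
    return (fcsc / fcso) / (fesc / feso)


def empirical_p(null_values: Sequence[float] | np.ndarray, observed: float) -> float:
    """Proportion of null values >= observed (ties count; no +1 smoothing)."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null >= observed)) / null.size
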