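"""Permutation tests on pairwise IBD matrices.

Three tests, each with a seeded and reproducible null:

* ``label_shuffle_test`` — within-vs-between group sharing, null built by
  shuffling individual labels over the fixed matrix;
* ``continuity_test`` — normalized regional-continuity ratio on a
  rectangular (focal-rows x reference-columns) sharing matrix, null built
  by reassigning columns to the two column groups;
* ``contribution_test`` — sharing-contribution ratio, null built by
  reassigning rows, exhaustively when the assignment space is small.

Nulls are sampled with replacement from the relabeling space (independent
uniform draws); the observed labeling is not force-included. Empirical p
is the proportion of null values >= observed, ties counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

from paleoibd.groupstats import ZERO_SUBSTITUTE_CM, empirical_p, within_between_stat
from paleoibd.segments import IBDMatrix


@dataclass
class PermutationResult:
    """Observed statistic, null distribution, and empirical p-value."""

    observed: float
    null: np.ndarray = field(repr=False)
    n_perm: int
    p: float
    seed: int | str
    statistic: str
    n_substituted: int = 0
    substituted_indices: list[int] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        hist, edges = np.histogram(self.null, bins=50)
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_substituted": self.n_substituted,
            "null_histogram": {
                "counts": hist.tolist(),
                "bin_edges": edges.tolist(),
            },
        }


def _wb_stat(values: np.ndarray, in_a: np.ndarray) -> float:
    # within/between statistic on a symmetric matrix given a boolean group mask
    na = int(in_a.sum())
    nb = in_a.size - na
    a = values[np.ix_(in_a, in_a)].sum()
    b = values[np.ix_(~in_a, ~in_a)].sum()
    between = values[np.ix_(in_a, ~in_a)].sum()
    w_a = a / (na * (na - 1))
    w_b = b / (nb * (nb - 1))
    return (w_a + w_b) / 2.0 - between / (na * nb)


def label_shuffle_test(
    matrix: IBDMatrix,
    labels: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Within-vs-between sharing statistic with a label-shuffling null.

    Each permutation uniformly relabels the individuals while keeping the
    two group sizes (and the matrix) fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = within_between_stat(matrix, labels)
    ids = sorted(labels)
    group_names = sorted(set(labels.values()))
    idx = matrix.indices(ids)
    values = matrix.values[np.ix_(idx, idx)]
    in_a = np.array([labels[i] == group_names[0] for i in ids])
    na = int(in_a.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = np.zeros(len(ids), dtype=bool)
    for k in range(n_perm):
        mask[:] = False
        mask[rng.choice(len(ids), size=na, replace=False)] = True
        null[k] = _wb_stat(values, mask)
    return PermutationResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        p=empirical_p(null, observed),
        seed=seed,
        statistic="within_between",
    )


def _continuity_stat(
    values: np.ndarray,
    fc_mask: np.ndarray,
    sc_mask: np.ndarray,
    zero_sub: float,
) -> tuple[float, bool]:
    fcsc = values[np.ix_(fc_mask, sc_mask)].mean()
    fcso = values[np.ix_(fc_mask, ~sc_mask)].mean()
    fesc = values[np.ix_(~fc_mask, sc_mask)].mean()
    feso = values[np.ix_(~fc_mask, ~sc_mask)].mean()
    substituted = fcso <= 0 or feso <= 0 or fesc <= 0
    fcso = fcso if fcso > 0 else zero_sub
    feso = feso if feso > 0 else zero_sub
    fesc = fesc if fesc > 0 else zero_sub
    return (fcsc / fcso) / (fesc / feso), substituted


def continuity_test(
    values: np.ndarray,
    fc_rows: Sequence[int],
    sc_cols: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
    zero_sub: float = ZERO_SUBSTITUTE_CM,
) -> PermutationResult:
    """Normalized continuity ratio with a column-reassignment null.

    ``values`` is the rectangular sharing matrix with focal-tradition rows
    (``fc_rows`` marking the focal-region subset, remaining rows being the
    reference subset) and successor-tradition columns. ``sc_cols`` is the
    observed focal-region column set; each permutation reassigns columns to
    a same-sized focal set uniformly at random, keeping each column's
    sharing profile intact.
    """
    values = np.asarray(values, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    nrow, ncol = values.shape
    sc_size = len(sc_cols)
    if not 1 <= sc_size <= ncol - 1:
        raise ValueError(f"sc_cols size must be in [1, {ncol - 1}], got {sc_size}")
    if not 1 <= len(fc_rows) <= nrow - 1:
        raise ValueError(f"fc_rows size must be in [1, {nrow - 1}], got {len(fc_rows)}")
    fc_mask = np.zeros(nrow, dtype=bool)
    fc_mask[list(fc_rows)] = True
    sc_mask = np.zeros(ncol, dtype=bool)
    sc_mask[list(sc_cols)] = True
    observed, _ = _continuity_stat(values, fc_mask, sc_mask, zero_sub)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    subst: list[int] = []
    mask = np.zeros(ncol, dtype=bool)
    for k in range(n_perm):
        mask[:] = False
        mask[rng.choice(ncol, size=sc_size, replace=False)] = True
        null[k], was_sub = _continuity_stat(values, fc_mask, mask, zero_sub)
        if was_sub:
            subst.append(k)
    return PermutationResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        p=empirical_p(null, observed),
        seed=seed,
        statistic="continuity_ratio",
        n_substituted=len(subst),
        substituted_indices=subst,
    )


def _contribution_stat(
    values: np.ndarray, fc_mask: np.ndarray, zero_sub: float
) -> tuple[float, bool]:
    fcs = values[fc_mask, :].mean()
    fes = values[~fc_mask, :].mean()
    substituted = fcs <= 0
    fcs = fcs if fcs > 0 else zero_sub
    return fes / fcs, substituted


def contribution_test(
    values: np.ndarray,
    fc_rows: Sequence[int],
    mode: str = "exhaustive",
    n_perm: int = 10_000,
    seed: int = 0,
    zero_sub: float = ZERO_SUBSTITUTE_CM,
    enumeration_cap: int = 10**6,
) -> PermutationResult:
    """Row-group contribution ratio (reference-rows mean / focal-rows mean).

    ``values`` has source-tradition rows and successor-tradition columns;
    ``fc_rows`` is the observed focal row set. In exhaustive mode the null
    enumerates every C(n_rows, len(fc_rows)) assignment of rows to the
    focal set (seed-independent); in sampled mode assignments are drawn
    uniformly. A zero focal-rows mean is replaced by ``zero_sub`` and the
    permutation is kept in the p-value count.
    """
    values = np.asarray(values, dtype=float)
    nrow = values.shape[0]
    fc_size = len(fc_rows)
    if not 1 <= fc_size <= nrow - 1:
        raise ValueError(f"fc_rows size must be in [1, {nrow - 1}], got {fc_size}")
    fc_mask = np.zeros(nrow, dtype=bool)
    fc_mask[list(fc_rows)] = True
    observed, _ = _contribution_stat(values, fc_mask, zero_sub)
    subst: list[int] = []
    if mode == "exhaustive":
        n_total = comb(nrow, fc_size)
        if n_total > enumeration_cap:
            raise ValueError(
                f"exhaustive null has {n_total} assignments, above the cap "
                f"{enumeration_cap}; use mode='sampled'"
            )
        null = np.empty(n_total)
        mask = np.zeros(nrow, dtype=bool)
        for k, rows in enumerate(combinations(range(nrow), fc_size)):
            mask[:] = False
            mask[list(rows)] = True
            null[k], was_sub = _contribution_stat(values, mask, zero_sub)
            if was_sub:
                subst.append(k)
        seed_record: int | str = "exhaustive"
        n_perm = n_total
    elif mode == "sampled":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        mask = np.zeros(nrow, dtype=bool)
        for k in range(n_perm):
            mask[:] = False
            mask[rng.choice(nrow, size=fc_size, replace=False)] = True
            null[k], was_sub = _contribution_stat(values, mask, zero_sub)
            if was_sub:
                subst.append(k)
        seed_record = seed
    else:
        raise ValueError(f"mode must be 'exhaustive' or 'sampled', got {mode!r}")
    return PermutationResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        p=empirical_p(null, observed),
        seed=seed_record,
        statistic="contribution_ratio",
        n_substituted=len(subst),
        substituted_indices=subst,
    )
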