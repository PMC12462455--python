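"""Kinship inference: pairwise mismatch rate and IBD-envelope classification.

Two complementary routes:

* the pairwise mismatch rate (pmr) of pseudo-haploid genotypes, turned
  into a kinship coefficient against the cohort's density-mode baseline
  and binned into relatedness degrees; and
* classification of an observed (total IBD, segment count) point against
  simulated per-relationship envelopes fitted as bivariate normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

MISSING = 9

#: Degree bin edges on the kinship coefficient: geometric midpoints between
#: the expected coefficients 1/2, 1/4, 1/8, 1/16 and below.
DEGREE_BOUNDS = {
    "identical": 2.0 ** -1.5,
    "1st": 2.0 ** -2.5,
    "2nd": 2.0 ** -3.5,
    "3rd": 2.0 ** -4.5,
}

DEFAULT_MIN_OVERLAP = 5_000

UNRELATED_CALL = "unrelated/beyond 5th degree"


@dataclass(frozen=True)
class KinshipEstimate:
    pair: tuple[str, str]
    pmr: float
    n_overlap: int
    baseline: float
    coefficient: float
    degree_call: str


def pmr(
    geno_a: np.ndarray, geno_b: np.ndarray, missing: int = MISSING
) -> tuple[float, int]:
    """Pairwise mismatch rate over sites covered in both individuals.

    Returns ``(mismatch fraction, overlap count)``. Raises on zero overlap.
    """
    a = np.asarray(geno_a)
    b = np.asarray(geno_b)
    if a.shape != b.shape:
        raise ValueError(f"genotype vectors differ in length: {a.shape} vs {b.shape}")
    mask = (a != missing) & (b != missing)
    n_overlap = int(mask.sum())
    if n_overlap == 0:
        raise ValueError("zero overlap: no sites covered in both individuals")
    mismatches = int(np.count_nonzero(a[mask] != b[mask]))
    return mismatches / n_overlap, n_overlap


def estimate_baseline(pmr_values: Sequence[float] | np.ndarray) -> float:
    """Unrelated-pair pmr: the density mode of the per-pair pmr values.

    Gaussian KDE with Silverman bandwidth, evaluated on a 512-point grid
    spanning the data. Needs at least 10 values; below that, supply a
    manual baseline instead.
    """
    values = np.asarray(pmr_values, dtype=float)
    if values.size < 10:
        raise ValueError(
            f"need >= 10 pmr values for a density-mode baseline, got {values.size}; "
            "provide a manual baseline"
        )
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def kinship_coefficient(pmr_value: float, baseline: float) -> float:
    """``1 - pmr/baseline``: 0 for unrelated pairs, 1/4 for 1st degree, etc."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return 1.0 - pmr_value / baseline


def classify_degree(
    coefficient: float,
    n_overlap: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> str:
    """Bin a kinship coefficient into a relatedness-degree call.

    Bins are centered on the expected coefficients (1/2 identical, 1/4
    first degree, 1/8 second, 1/16 third) with geometric-midpoint edges;
    anything at or below 2^-4.5 is called unrelated. With ``n_overlap``
    given and below ``min_overlap``, returns "low-confidence".
    """
    if n_overlap is not None and n_overlap < min_overlap:
        return "low-confidence"
    for call, bound in DEGREE_BOUNDS.items():
        if coefficient > bound:
            return call
    return "unrelated"


def estimate_kinship_table(
    genotypes: np.ndarray,
    ids: Sequence[str],
    baseline: float | None = None,
    missing: int = MISSING,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[KinshipEstimate]:
    """All-pairs pmr kinship estimates from a (n_individuals, n_sites) matrix.

    When ``baseline`` is None it is taken as the density mode of all pair
    pmr values (close relatives barely shift the mode).
    """
    geno = np.asarray(genotypes)
    n = len(ids)
    if geno.shape[0] != n:
        raise ValueError(f"{n} ids but {geno.shape[0]} genotype rows")
    raw = []
    for i in range(n):
        for j in range(i + 1, n):
            rate, overlap = pmr(geno[i], geno[j], missing=missing)
            raw.append(((ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i]), rate, overlap))
    if baseline is None:
        baseline = estimate_baseline([r[1] for r in raw])
    out = []
    for pair, rate, overlap in raw:
        coef = kinship_coefficient(rate, baseline)
        out.append(
            KinshipEstimate(
                pair=pair,
                pmr=rate,
                n_overlap=overlap,
                baseline=baseline,
                coefficient=coef,
                degree_call=classify_degree(coef, overlap, min_overlap),
            )
        )
    return out


@dataclass
class RelationshipEnvelope:
    """Simulated (sum_cM, n_segments) cloud for one pedigree relationship.

    Carries the raw replicate points and a fitted bivariate normal used
    for likelihood-based classification. Degenerate clouds (all-zero or
    singular even after ridging) are flagged unusable.
    """

    relationship: str
    replicates: np.ndarray = field(repr=False)  # shape (n_rep, 2)
    mean: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    usable: bool = True

    @classmethod
    def fit(cls, relationship: str, replicates: np.ndarray) -> "RelationshipEnvelope":
        pts = np.asarray(replicates, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("replicates must have shape (n_rep, 2)")
        mean = pts.mean(axis=0)
        if pts.shape[0] < 3 or np.all(pts == 0):
            return cls(relationship, pts, mean, np.eye(2), usable=False)
        cov = np.cov(pts, rowvar=False)
        # ridge degenerate clouds so the likelihood stays defined
        ridge = 1e-6 * max(1.0, float(np.trace(cov)))
        cov = cov + ridge * np.eye(2)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return cls(relationship, pts, mean, np.eye(2), usable=False)
        return cls(relationship, pts, mean, cov, usable=True)

    def log_likelihood(self, sum_cM: float, n_segments: float) -> float:
        return float(
            stats.multivariate_normal.logpdf([sum_cM, n_segments], self.mean, self.cov)
        )

    def mahalanobis_sq(self, sum_cM: float, n_segments: float) -> float:
        d = np.array([sum_cM, n_segments]) - self.mean
        return float(d @ np.linalg.solve(self.cov, d))


def classify_relationship(
    sum_cM: float,
    n_segments: float,
    envelopes: Sequence[RelationshipEnvelope],
    window: float = 2.0,
    coverage: float = 0.999,
) -> dict:
    """Rank relationships by bivariate-normal likelihood of (sum, count).

    The call is the top-ranked relationship plus every relationship within
    ``window`` log-units of it. If the observation falls outside every
    envelope's ``coverage`` region (chi-squared with 2 df), the call is
    "unrelated/beyond 5th degree".
    """
    usable = [e for e in envelopes if e.usable]
    if not usable:
        raise ValueError("no usable envelopes")
    threshold = stats.chi2.ppf(coverage, df=2)
    ranked = sorted(
        ((e.relationship, e.log_likelihood(sum_cM, n_segments)) for e in usable),
        key=lambda t: t[1],
        reverse=True,
    )
    inside_any = any(e.mahalanobis_sq(sum_cM, n_segments) <= threshold for e in usable)
    if not inside_any:
        return {"call": [UNRELATED_CALL], "ranked": ranked}
    top_ll = ranked[0][1]
    call = [rel for rel, ll in ranked if top_ll - ll <= window]
    return {"call": call, "ranked": ranked}
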