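"""Proximity-stratified pair classification and rank-sum contrasts.

Pairs of individuals are split into a "mortuary proximity" set (same
mortuary tradition, geographically distant, one member in the focal
region) and a "geographic proximity" set (different traditions, same
geographic area inside the focal region); the per-pair IBD totals of the
two sets are then compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from paleoibd.segments import Individual, PairIBDSummary

EARTH_RADIUS_KM = 6371.0

MORTUARY_PROXIMITY = "mortuary_proximity"
GEOGRAPHIC_PROXIMITY = "geographic_proximity"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PairClass:
    pair: tuple[str, str]
    cls: str
    distance_km: float
    same_mortuary: bool
    same_region: bool


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (spherical Earth, radius 6371.0 km)."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def classify_pairs(
    individuals: Sequence[Individual],
    focal_region: str,
    threshold_km: float = 200.0,
) -> list[PairClass]:
    """Classify every pair into the two proximity sets or exclude it.

    Same geographic area means site distance <= ``threshold_km``
    (coordinates drive the call; region labels only select focal-region
    membership). A pair is *mortuary proximity* when it shares a mortuary
    tradition, sits farther apart than the threshold, and has at least one
    member in the focal region; *geographic proximity* when traditions
    differ, the sites are within the threshold, and both members are in
    the focal region. Individuals without coordinates are skipped with a
    warning.
    """
    usable = []
    for ind in individuals:
        if not ind.has_coordinates:
            warnings.warn(f"skipping {ind.id}: missing coordinates", stacklevel=2)
            continue
        usable.append(ind)
    out: list[PairClass] = []
    for a, b in combinations(usable, 2):
        dist = haversine_km(a.lat, a.lon, b.lat, b.lon)
        same_region = dist <= threshold_km
        same_mortuary = a.mortuary_group == b.mortuary_group
        in_focal = (a.region == focal_region, b.region == focal_region)
        if same_mortuary and not same_region and any(in_focal):
            cls = MORTUARY_PROXIMITY
        elif not same_mortuary and same_region and all(in_focal):
            cls = GEOGRAPHIC_PROXIMITY
        else:
            cls = EXCLUDED
        pair = (a.id, b.id) if a.id < b.id else (b.id, a.id)
        out.append(PairClass(pair, cls, dist, same_mortuary, same_region))
    return out


def pair_values(
    summaries: Mapping[tuple[str, str], PairIBDSummary],
    pairs: Sequence[tuple[str, str]],
    measure: str = "sum",
    include_zero: bool = True,
) -> np.ndarray:
    """Per-pair IBD values (``sum`` or ``max`` of retained lengths).

    Pairs without any retained segment contribute 0 when ``include_zero``
    (the pair universe is label-defined); otherwise they are dropped.
    """
    if measure not in ("sum", "max"):
        raise ValueError(f"measure must be 'sum' or 'max', got {measure!r}")
    vals = []
    for pair in pairs:
        summ = summaries.get(pair)
        if summ is None:
            if include_zero:
                vals.append(0.0)
            continue
        vals.append(summ.sum_cM if measure == "sum" else summ.max_cM)
    return np.asarray(vals)


def compare_pair_sets(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    exact_max_n: int = 12,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two per-pair value sets.

    Uses exact enumeration when both sets have <= ``exact_max_n`` values
    and no ties straddle the groups; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both comparison sets must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return {
        "p": float(res.pvalue),
        "U": float(res.statistic),
        "method": method,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
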