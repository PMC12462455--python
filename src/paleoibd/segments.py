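"""IBD segment tables: reading, merging, filtering, and the pairwise matrix.

Segments are called blocks shared between a pair of individuals, in genetic
map coordinates (cM), carrying a SNP count and an IBD state (one or two
shared haplotypes). Pair identity is unordered; ids are canonicalized so
the lexicographically smaller id comes first. Coordinates are half-open
``[start_cM, end_cM)`` on a per-chromosome genetic map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COORD_TOL = 1e-6

SEGMENT_COLUMNS = ["iid1", "iid2", "ch", "start_cM", "end_cM", "length_cM", "n_snps", "state"]
METADATA_COLUMNS = ["iid", "group", "region", "lat", "lon", "date_lo", "date_hi", "sex"]


class SegmentFormatError(ValueError):
    """Malformed segment table (missing column, unparsable field)."""


class SegmentValidationError(ValueError):
    """A row violates a segment invariant (e.g. end <= start)."""


def pair_key(id_a: str, id_b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically smaller id first."""
    if id_a == id_b:
        raise SegmentValidationError(f"pair of an individual with itself: {id_a!r}")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


@dataclass(frozen=True)
class IBDSegment:
    """One called IBD block between a pair of individuals.

    Invariants: ``end_cM > start_cM``, ``length_cM == end_cM - start_cM``
    (within 1e-6), ``n_snps >= 0``, ``id_a < id_b`` after canonicalization,
    ``state`` in {"IBD1", "IBD2"}.
    """

    id_a: str
    id_b: str
    chrom: int
    start_cM: float
    end_cM: float
    length_cM: float
    n_snps: int
    state: str = "IBD1"

    def __post_init__(self) -> None:
        a, b = pair_key(self.id_a, self.id_b)
        object.__setattr__(self, "id_a", a)
        object.__setattr__(self, "id_b", b)
        if not self.end_cM > self.start_cM:
            raise SegmentValidationError(
                f"end_cM ({self.end_cM}) must exceed start_cM ({self.start_cM})"
            )
        if abs(self.length_cM - (self.end_cM - self.start_cM)) > _COORD_TOL:
            raise SegmentValidationError(
                f"length_cM {self.length_cM} != end-start {self.end_cM - self.start_cM}"
            )
        if self.n_snps < 0:
            raise SegmentValidationError(f"n_snps must be >= 0, got {self.n_snps}")
        if self.state not in ("IBD1", "IBD2"):
            raise SegmentValidationError(f"state must be IBD1 or IBD2, got {self.state!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def snp_density(self) -> float:
        return self.n_snps / self.length_cM


@dataclass(frozen=True)
class Individual:
    """Cohort member with mortuary, geographic, and sex metadata."""

    id: str
    mortuary_group: str
    region: str
    lat: float = np.nan
    lon: float = np.nan
    date_lo: float = np.nan
    date_hi: float = np.nan
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if np.isfinite(self.lat) and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range for {self.id}: {self.lat}")
        if np.isfinite(self.lon) and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range for {self.id}: {self.lon}")

    @property
    def has_coordinates(self) -> bool:
        return bool(np.isfinite(self.lat) and np.isfinite(self.lon))


@dataclass(frozen=True)
class PairIBDSummary:
    """Per-pair totals over retained segments: sum, max, count."""

    pair: tuple[str, str]
    sum_cM: float
    max_cM: float
    n_segments: int

    def __post_init__(self) -> None:
        if not (self.sum_cM >= self.max_cM >= 0):
            raise ValueError(f"need sum >= max >= 0, got {self.sum_cM}, {self.max_cM}")
        if (self.n_segments == 0) != (self.sum_cM == 0):
            raise ValueError("n_segments == 0 iff sum_cM == 0")


def read_segments(path: str | Path) -> list[IBDSegment]:
    """Read a tab-separated segment table into validated segments.

    The file must carry a header naming the seven standard columns (state
    optional, defaulting to IBD1). Pair ids are canonicalized on read.
    Raises :class:`SegmentFormatError` for missing columns and
    :class:`SegmentValidationError` citing the 1-based data row index for
    invariant violations.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"iid1": str, "iid2": str}, float_precision="round_trip"
    )
    required = [c for c in SEGMENT_COLUMNS if c != "state"]
    for col in required:
        if col not in df.columns:
            raise SegmentFormatError(f"segment table {path} is missing column {col!r}")
    if "state" not in df.columns:
        df["state"] = "IBD1"
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segments.append(
                IBDSegment(
                    id_a=str(row.iid1),
                    id_b=str(row.iid2),
                    chrom=int(row.ch),
                    start_cM=float(row.start_cM),
                    end_cM=float(row.end_cM),
                    length_cM=float(row.length_cM),
                    n_snps=int(row.n_snps),
                    state=str(row.state),
                )
            )
        except (SegmentValidationError, ValueError) as exc:
            raise SegmentValidationError(f"row {i}: {exc}") from exc
    return segments


def write_segments(segments: Iterable[IBDSegment], path: str | Path) -> None:
    """Write segments as the standard tab-separated table."""
    rows = [
        (s.id_a, s.id_b, s.chrom, s.start_cM, s.end_cM, s.length_cM, s.n_snps, s.state)
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_metadata(path: str | Path) -> list[Individual]:
    """Read the individual metadata TSV (`iid group region lat lon date_lo date_hi sex`)."""
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    for col in ("iid", "group", "region"):
        if col not in df.columns:
            raise SegmentFormatError(f"metadata table {path} is missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Individual(
                id=str(row.iid),
                mortuary_group=str(row.group),
                region=str(row.region),
                lat=float(getattr(row, "lat", np.nan)),
                lon=float(getattr(row, "lon", np.nan)),
                date_lo=float(getattr(row, "date_lo", np.nan)),
                date_hi=float(getattr(row, "date_hi", np.nan)),
                sex=str(getattr(row, "sex", "unknown")),
            )
        )
    return out


def write_metadata(individuals: Iterable[Individual], path: str | Path) -> None:
    rows = [
        (p.id, p.mortuary_group, p.region, p.lat, p.lon, p.date_lo, p.date_hi, p.sex)
        for p in individuals
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def merge_adjacent_states(
    segments: Sequence[IBDSegment], gap_tol_cM: float = 0.0
) -> list[IBDSegment]:
    """Merge runs of adjacent IBD1/IBD2 segments per pair and chromosome.

    Segments of the same pair/chromosome whose gap is <= ``gap_tol_cM`` are
    replaced by one block spanning min(start) to max(end); SNP counts are
    summed; the merged state is IBD1 unless every constituent is IBD2.
    Overlapping segments are merged likewise, with a warning (their SNP
    counts double-count the overlap).
    """
    if gap_tol_cM < 0:
        raise ValueError("gap_tol_cM must be >= 0")
    by_key: dict[tuple[tuple[str, str], int], list[IBDSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.pair, seg.chrom), []).append(seg)
    merged: list[IBDSegment] = []
    for (pair, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: (s.start_cM, s.end_cM))
        run = [group[0]]
        for seg in group[1:]:
            run_end = max(s.end_cM for s in run)
            gap = seg.start_cM - run_end
            if gap <= gap_tol_cM:
                if gap < 0:
                    warnings.warn(
                        f"overlapping segments for pair {pair} chr{chrom}; "
                        "merging without correcting double-counted SNPs",
                        stacklevel=2,
                    )
                run.append(seg)
            else:
                merged.append(_collapse_run(run))
                run = [seg]
        merged.append(_collapse_run(run))
    merged.sort(key=lambda s: (s.id_a, s.id_b, s.chrom, s.start_cM))
    return merged


def _collapse_run(run: list[IBDSegment]) -> IBDSegment:
    if len(run) == 1:
        return run[0]
    start = min(s.start_cM for s in run)
    end = max(s.end_cM for s in run)
    state = "IBD2" if all(s.state == "IBD2" for s in run) else "IBD1"
    return IBDSegment(
        id_a=run[0].id_a,
        id_b=run[0].id_b,
        chrom=run[0].chrom,
        start_cM=start,
        end_cM=end,
        length_cM=end - start,
        n_snps=sum(s.n_snps for s in run),
        state=state,
    )


def filter_segments(
    segments: Iterable[IBDSegment],
    min_len_cM: float = 12.0,
    min_density: float = 220.0,
) -> list[IBDSegment]:
    """Keep segments with length >= ``min_len_cM`` and SNP density >= ``min_density``.

    Both thresholds are inclusive; order is preserved. An empty result is
    legitimate.
    """
    return [
        s
        for s in segments
        if s.length_cM >= min_len_cM and s.n_snps / s.length_cM >= min_density
    ]


def summarize_pairs(
    segments: Iterable[IBDSegment],
) -> dict[tuple[str, str], PairIBDSummary]:
    """Total, maximum, and count of retained segment lengths per unordered pair."""
    acc: dict[tuple[str, str], list[float]] = {}
    for seg in segments:
        acc.setdefault(seg.pair, []).append(seg.length_cM)
    return {
        pair: PairIBDSummary(
            pair=pair, sum_cM=sum(lens), max_cM=max(lens), n_segments=len(lens)
        )
        for pair, lens in acc.items()
    }


@dataclass
class IBDMatrix:
    """Symmetric individuals x individuals matrix of total shared IBD (cM).

    Diagonal is fixed at zero; entries for pairs without retained segments
    are zero. ``ids`` fixes the row/column order.
    """

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in matrix") from exc

    def submatrix(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        return self.values[np.ix_(self.indices(row_ids), self.indices(col_ids))]

    @property
    def n(self) -> int:
        return len(self.ids)

    def n_possible_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def n_sharing_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.count_nonzero(self.values[iu]))

    def total_cM(self) -> float:
        """Sum of upper-triangle entries: total retained segment length."""
        iu = np.triu_indices(self.n, k=1)
        return float(self.values[iu].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "IBDMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"matrix CSV {path}: row and column ids differ")
        return cls(ids=list(df.index), values=df.to_numpy(dtype=float))


def build_matrix(
    summaries: Mapping[tuple[str, str], PairIBDSummary],
    individuals: Sequence[Individual] | Sequence[str],
) -> IBDMatrix:
    """Assemble the symmetric total-IBD matrix over the given individuals.

    Every id appearing in ``summaries`` must be listed; pairs without a
    summary get zero.
    """
    ids = [p.id if isinstance(p, Individual) else str(p) for p in individuals]
    index = {iid: i for i, iid in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for (a, b), summ in summaries.items():
        for iid in (a, b):
            if iid not in index:
                raise KeyError(f"segment references unknown individual {iid!r}")
        i, j = index[a], index[b]
        values[i, j] = values[j, i] = summ.sum_cM
    return IBDMatrix(ids=ids, values=values)
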