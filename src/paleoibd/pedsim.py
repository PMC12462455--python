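"""Pedigree IBD simulation by gene dropping with crossover modelling.

Founder haplotypes carry unique integer labels; meioses recombine them
along a genetic map with crossovers drawn from a stationary gamma-renewal
process (shape 1 = Poisson, no interference; larger shapes give crossover
interference / underdispersed counts). IBD between the target pair is the
set of intervals where their haplotypes carry the same founder label, with
state IBD1 (one shared haplotype) or IBD2 (both).

Fourteen pedigree relationships are supported, from parent-child down to
third cousins and third-great-grandparents. Raw state-resolved segments
can be merged and length/density-filtered to mimic the processing applied
to called IBD, and summarized into per-relationship (sum, count)
envelopes for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from paleoibd.kinship import RelationshipEnvelope
from paleoibd.segments import IBDSegment, filter_segments, merge_adjacent_states

# Approximate sex-averaged autosomal genetic lengths (cM), chr1..chr22.
_DEFAULT_LENGTHS = np.array(
    [
        286.3, 268.6, 223.2, 214.5, 204.1, 192.0, 187.2, 168.0,
        166.4, 181.1, 158.2, 174.7, 125.7, 120.2, 141.9, 134.0,
        128.5, 117.9, 107.9, 108.3, 62.8, 74.1,
    ]
)

#: Genetic distance between crossovers, in cM (1 Morgan).
_MORGAN_CM = 100.0

#: The supported pedigree relationships, ordered by increasing degree.
RELATIONSHIPS = [
    "parent-child",
    "siblings",
    "grandparent-grandchild",
    "avuncular",
    "half-siblings",
    "double-first-cousins",
    "first-cousins",
    "great-grandparent",
    "half-first-cousins",
    "great-great-grandparent",
    "second-cousins",
    "half-second-cousins",
    "great-great-great-grandparent",
    "third-cousins",
]

#: Expected genome fraction covered by IBD (1 or 2), used as an oracle.
EXPECTED_IBD_FRACTION = {
    "parent-child": 1.0,
    "siblings": 0.75,
    "grandparent-grandchild": 0.5,
    "avuncular": 0.5,
    "half-siblings": 0.5,
    "double-first-cousins": 7.0 / 16.0,
    "first-cousins": 0.25,
    "great-grandparent": 0.25,
    "half-first-cousins": 0.125,
    "great-great-grandparent": 0.125,
    "second-cousins": 0.0625,
    "half-second-cousins": 0.03125,
    "great-great-great-grandparent": 0.0625,
    "third-cousins": 0.015625,
}


#: Expected pmr-based kinship coefficient, (P(IBD1) + 2 P(IBD2)) / 4: the
#: expected fraction of pseudo-haploid calls that match *because of* the
#: relationship, i.e. E[1 - pmr/baseline].
EXPECTED_PMR_COEFFICIENT = {
    "parent-child": 0.25,
    "siblings": 0.25,
    "grandparent-grandchild": 0.125,
    "avuncular": 0.125,
    "half-siblings": 0.125,
    "double-first-cousins": 0.125,
    "first-cousins": 0.0625,
    "great-grandparent": 0.0625,
    "half-first-cousins": 0.03125,
    "great-great-grandparent": 0.03125,
    "second-cousins": 0.015625,
    "half-second-cousins": 0.0078125,
    "great-great-great-grandparent": 0.015625,
    "third-cousins": 0.00390625,
}


@dataclass
class GeneticMap:
    """Per-autosome genetic lengths; optionally sex-specific."""

    lengths: np.ndarray
    female_lengths: np.ndarray | None = None
    male_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("chromosome lengths must be >= 0")

    @property
    def n_chrom(self) -> int:
        return len(self.lengths)

    @property
    def total_cM(self) -> float:
        return float(self.lengths.sum())

    @property
    def sex_specific(self) -> bool:
        return self.female_lengths is not None and self.male_lengths is not None

    @classmethod
    def default(cls) -> "GeneticMap":
        return cls(lengths=_DEFAULT_LENGTHS.copy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("chrom", "length_cM"):
            if col not in df.columns:
                raise ValueError(f"map file {path} is missing column {col!r}")
        df = df.sort_values("chrom")
        female = male = None
        if "length_female_cM" in df.columns and "length_male_cM" in df.columns:
            female = df["length_female_cM"].to_numpy(dtype=float)
            male = df["length_male_cM"].to_numpy(dtype=float)
        return cls(
            lengths=df["length_cM"].to_numpy(dtype=float),
            female_lengths=female,
            male_lengths=male,
        )


@dataclass
class SimConfig:
    relationship: str
    n_rep: int = 100
    interference_nu: float = 1.0
    snp_density_per_cM: float = 300.0
    min_len_cM: float = 12.0
    min_density: float = 220.0
    apply_filter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.interference_nu <= 0:
            raise ValueError("interference_nu must be > 0")


def _crossovers(length_cM: float, nu: float, rng: np.random.Generator) -> list[float]:
    # stationary gamma-renewal process: burn in from well before the
    # chromosome so the first event is drawn from the equilibrium law
    if length_cM <= 0:
        return []
    burn_in = 10.0 * _MORGAN_CM
    scale = _MORGAN_CM / nu
    pos = -burn_in
    out: list[float] = []
    while pos < length_cM:
        pos += rng.gamma(nu, scale)
        if 0.0 < pos < length_cM:
            out.append(pos)
    return out


def simulate_meiosis(
    gmap: GeneticMap, interference_nu: float = 1.0, seed: int | np.random.Generator = 0
) -> list[list[float]]:
    """Crossover positions per chromosome for one meiosis.

    Positions follow a stationary gamma-renewal process with shape
    ``interference_nu`` and mean spacing one Morgan (100 cM): shape 1 is
    the no-interference Poisson model; larger shapes underdisperse the
    crossover count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [_crossovers(L, interference_nu, rng) for L in gmap.lengths]


# ---------------------------------------------------------------------------
# gene dropping

# A haplotype is, per chromosome, a list of (start, end, founder_label)
# covering [0, L). A person is a pair of haplotypes.
Haplotype = list[list[tuple[float, float, int]]]


class _Pedigree:
    """Founder bookkeeping plus meiosis/mating helpers for one replicate."""

    def __init__(self, gmap: GeneticMap, nu: float, rng: np.random.Generator) -> None:
        self.gmap = gmap
        self.nu = nu
        self.rng = rng
        self._next_label = 0

    def founder(self) -> tuple[Haplotype, Haplotype]:
        haps = []
        for _ in range(2):
            label = self._next_label
            self._next_label += 1
            haps.append([[(0.0, L, label)] for L in self.gmap.lengths])
        return haps[0], haps[1]

    def gamete(self, person: tuple[Haplotype, Haplotype]) -> Haplotype:
        out: Haplotype = []
        for ci, L in enumerate(self.gmap.lengths):
            xs = _crossovers(L, self.nu, self.rng)
            bounds = [0.0] + xs + [L]
            cur = int(self.rng.integers(2))
            chrom_out: list[tuple[float, float, int]] = []
            for a, b in zip(bounds[:-1], bounds[1:]):
                for s, e, lab in person[cur][ci]:
                    lo, hi = max(s, a), min(e, b)
                    if hi > lo:
                        if chrom_out and chrom_out[-1][2] == lab and chrom_out[-1][1] == lo:
                            chrom_out[-1] = (chrom_out[-1][0], hi, lab)
                        else:
                            chrom_out.append((lo, hi, lab))
                cur = 1 - cur
            out.append(chrom_out)
        return out

    def child(
        self,
        p1: tuple[Haplotype, Haplotype],
        p2: tuple[Haplotype, Haplotype],
    ) -> tuple[Haplotype, Haplotype]:
        return self.gamete(p1), self.gamete(p2)


def _label_at(chrom_hap: list[tuple[float, float, int]], pos: float) -> int:
    for s, e, lab in chrom_hap:
        if s <= pos < e:
            return lab
    raise AssertionError(f"position {pos} not covered")  # pragma: no cover


def _ibd_segments(
    x: tuple[Haplotype, Haplotype],
    y: tuple[Haplotype, Haplotype],
    gmap: GeneticMap,
    id_a: str = "SIM_A",
    id_b: str = "SIM_B",
) -> list[IBDSegment]:
    """State-resolved IBD between two persons from founder labels."""
    segments: list[IBDSegment] = []
    for ci, L in enumerate(gmap.lengths):
        if L <= 0:
            continue
        cuts = {0.0, L}
        for hap in (x[0], x[1], y[0], y[1]):
            for s, e, _ in hap[ci]:
                cuts.add(s)
                cuts.add(e)
        bounds = sorted(cuts)
        run_state = 0
        run_start = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            mid = (a + b) / 2.0
            a1 = _label_at(x[0][ci], mid)
            a2 = _label_at(x[1][ci], mid)
            b1 = _label_at(y[0][ci], mid)
            b2 = _label_at(y[1][ci], mid)
            state = max((a1 == b1) + (a2 == b2), (a1 == b2) + (a2 == b1))
            if state != run_state:
                if run_state > 0:
                    segments.append(
                        _make_segment(id_a, id_b, ci + 1, run_start, a, run_state)
                    )
                run_state = state
                run_start = a
        if run_state > 0:
            segments.append(_make_segment(id_a, id_b, ci + 1, run_start, L, run_state))
    return segments


def _make_segment(
    id_a: str, id_b: str, chrom: int, start: float, end: float, state: int
) -> IBDSegment:
    return IBDSegment(
        id_a=id_a,
        id_b=id_b,
        chrom=chrom,
        start_cM=start,
        end_cM=end,
        length_cM=end - start,
        n_snps=0,
        state="IBD2" if state == 2 else "IBD1",
    )


def _pair_builders() -> dict[str, Callable[[_Pedigree], tuple]]:
    def parent_child(ped: _Pedigree):
        p = ped.founder()
        spouse = ped.founder()
        return p, ped.child(p, spouse)

    def siblings(ped: _Pedigree):
        f, m = ped.founder(), ped.founder()
        return ped.child(f, m), ped.child(f, m)

    def grandparent_grandchild(ped: _Pedigree):
        gp = ped.founder()
        c = ped.child(gp, ped.founder())
        return gp, ped.child(c, ped.founder())

    def avuncular(ped: _Pedigree):
        f, m = ped.founder(), ped.founder()
        uncle, parent = ped.child(f, m), ped.child(f, m)
        return uncle, ped.child(parent, ped.founder())

    def half_siblings(ped: _Pedigree):
        shared = ped.founder()
        return ped.child(shared, ped.founder()), ped.child(shared, ped.founder())

    def double_first_cousins(ped: _Pedigree):
        fa, ma = ped.founder(), ped.founder()
        fb, mb = ped.founder(), ped.founder()
        a1, a2 = ped.child(fa, ma), ped.child(fa, ma)
        b1, b2 = ped.child(fb, mb), ped.child(fb, mb)
        return ped.child(a1, b1), ped.child(a2, b2)

    def _cousins(ped: _Pedigree, generations: int, half: bool):
        if half:
            shared = ped.founder()
            s1 = ped.child(shared, ped.founder())
            s2 = ped.child(shared, ped.founder())
        else:
            f, m = ped.founder(), ped.founder()
            s1, s2 = ped.child(f, m), ped.child(f, m)
        for _ in range(generations):
            s1 = ped.child(s1, ped.founder())
            s2 = ped.child(s2, ped.founder())
        return s1, s2

    def _lineal(ped: _Pedigree, extra_generations: int):
        anc = ped.founder()
        desc = ped.child(anc, ped.founder())
        for _ in range(extra_generations):
            desc = ped.child(desc, ped.founder())
        return anc, desc

    return {
        "parent-child": parent_child,
        "siblings": siblings,
        "grandparent-grandchild": grandparent_grandchild,
        "avuncular": avuncular,
        "half-siblings": half_siblings,
        "double-first-cousins": double_first_cousins,
        "first-cousins": lambda ped: _cousins(ped, 1, half=False),
        "second-cousins": lambda ped: _cousins(ped, 2, half=False),
        "third-cousins": lambda ped: _cousins(ped, 3, half=False),
        "half-first-cousins": lambda ped: _cousins(ped, 1, half=True),
        "half-second-cousins": lambda ped: _cousins(ped, 2, half=True),
        "great-grandparent": lambda ped: _lineal(ped, 2),
        "great-great-grandparent": lambda ped: _lineal(ped, 3),
        "great-great-great-grandparent": lambda ped: _lineal(ped, 4),
    }


_BUILDERS = _pair_builders()


def simulate_pair_ibd(
    relationship: str,
    gmap: GeneticMap,
    interference_nu: float = 1.0,
    rng: np.random.Generator | int = 0,
    id_a: str = "SIM_A",
    id_b: str = "SIM_B",
) -> list[IBDSegment]:
    """One replicate of raw, state-resolved IBD for the given relationship."""
    if relationship not in _BUILDERS:
        raise ValueError(
            f"unknown relationship {relationship!r}; choose from {RELATIONSHIPS}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ped = _Pedigree(gmap, interference_nu, rng)
    x, y = _BUILDERS[relationship](ped)
    return _ibd_segments(x, y, gmap, id_a=id_a, id_b=id_b)


def _assign_snps(seg: IBDSegment, density: float) -> IBDSegment:
    return IBDSegment(
        id_a=seg.id_a,
        id_b=seg.id_b,
        chrom=seg.chrom,
        start_cM=seg.start_cM,
        end_cM=seg.end_cM,
        length_cM=seg.length_cM,
        n_snps=int(round(seg.length_cM * density)),
        state=seg.state,
    )


def simulate_relationship(
    config: SimConfig, gmap: GeneticMap | None = None
) -> list[list[IBDSegment]]:
    """Per-replicate IBD segment sets for one relationship.

    Each replicate gene-drops through the minimal pedigree connecting the
    pair. With ``config.apply_filter`` the IBD1/IBD2 blocks are merged and
    the length/SNP-density filter applied (SNP counts assigned as
    length x ``snp_density_per_cM``), mirroring the processing of called
    segments; otherwise raw state-resolved segments are returned.
    """
    gmap = gmap or GeneticMap.default()
    rng = np.random.default_rng(config.seed)
    reps = []
    for _ in range(config.n_rep):
        segs = simulate_pair_ibd(config.relationship, gmap, config.interference_nu, rng)
        segs = [_assign_snps(s, config.snp_density_per_cM) for s in segs]
        if config.apply_filter:
            segs = filter_segments(
                merge_adjacent_states(segs),
                min_len_cM=config.min_len_cM,
                min_density=config.min_density,
            )
        reps.append(segs)
    return reps


def replicate_points(replicates: Sequence[Sequence[IBDSegment]]) -> np.ndarray:
    """(sum_cM, n_segments) per replicate, shape (n_rep, 2)."""
    return np.array(
        [[sum(s.length_cM for s in rep), len(rep)] for rep in replicates], dtype=float
    )


def build_envelopes(
    relationships: Sequence[str] | None = None,
    n_rep: int = 100,
    gmap: GeneticMap | None = None,
    interference_nu: float = 1.0,
    snp_density_per_cM: float = 300.0,
    min_len_cM: float = 12.0,
    min_density: float = 220.0,
    seed: int = 0,
) -> list[RelationshipEnvelope]:
    """Simulate, merge, and filter each relationship into a fitted envelope.

    Deterministic under a fixed seed: each relationship gets its own
    seeded stream so adding relationships does not disturb the others.
    """
    relationships = list(relationships) if relationships else list(RELATIONSHIPS)
    envelopes = []
    for rel in relationships:
        config = SimConfig(
            relationship=rel,
            n_rep=n_rep,
            interference_nu=interference_nu,
            snp_density_per_cM=snp_density_per_cM,
            min_len_cM=min_len_cM,
            min_density=min_density,
            apply_filter=True,
            seed=seed + 1000 * (RELATIONSHIPS.index(rel) + 1),
        )
        points = replicate_points(simulate_relationship(config, gmap))
        envelopes.append(RelationshipEnvelope.fit(rel, points))
    return envelopes


def envelopes_to_tsv(envelopes: Sequence[RelationshipEnvelope], path: str | Path) -> None:
    rows = []
    for env in envelopes:
        for sum_cM, n_seg in env.replicates:
            rows.append((env.relationship, sum_cM, int(n_seg)))
    pd.DataFrame(rows, columns=["relationship", "sum_cM", "n_segments"]).to_csv(
        path, sep="\t", index=False
    )
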